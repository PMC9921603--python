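"""EMG conditioning and muscle-activation dynamics.

Raw surface EMG of the antagonistic pair is band-passed (10--500 Hz,
Butterworth order 5), notch-filtered around the power line (48--52 Hz
band-stop, order 5) and rectified; a linear envelope (zero-phase low-pass on
the rectified signal) is then normalized by the maximum of the MVC envelope
to give the neural activation u(t) in [0, 1].  Muscle activation a(t) follows
the exponential shape map

    a = (exp(A*u) - 1) / (exp(A) - 1),   A = -20 by default,

which is monotone in u with a(0) = 0 and a(1) = 1.  All filtering is
zero-phase (forward-backward), appropriate for offline processing.

Note that with A = -20 the map is nearly saturating (a ≈ 1 - exp(-20 u));
this is the published constant and is kept as the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, InvalidSamplingRateError, ParameterError

__all__ = [
    "EMGTrial",
    "MVCReference",
    "ActivationTrace",
    "preprocess_emg",
    "envelope",
    "neural_activation",
    "muscle_activation",
    "activation_from_envelope",
    "process_trial",
]

DEFAULT_A = -20.0
DEFAULT_BANDPASS = (10.0, 500.0)
DEFAULT_NOTCH = (48.0, 52.0)
DEFAULT_ENVELOPE_CUTOFF = 6.0
FILTER_ORDER = 5
ENVELOPE_ORDER = 4


@dataclass
class EMGTrial:
    """One recorded trial of the antagonistic pair.

    ``kind`` is ``"raw"`` for unprocessed EMG (requires fs > 1000 Hz so the
    500 Hz band edge stays below Nyquist) or ``"envelope"`` when the channels
    already contain linear envelopes (any fs).
    """

    time: np.ndarray        # s, uniform
    emg_agonist: np.ndarray  # mV
    emg_antagonist: np.ndarray  # mV
    fs: float               # Hz
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.emg_agonist = np.asarray(self.emg_agonist, dtype=float)
        self.emg_antagonist = np.asarray(self.emg_antagonist, dtype=float)
        if self.kind not in ("raw", "envelope"):
            raise ParameterError(f"unknown trial kind {self.kind!r}")
        if not (len(self.time) == len(self.emg_agonist) == len(self.emg_antagonist)):
            raise DataError("all channels must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise DataError("time must be strictly increasing")
        if self.kind == "raw" and self.fs <= 1000:
            raise InvalidSamplingRateError(
                f"raw EMG requires fs > 1000 Hz (bandpass edge 500 Hz), got {self.fs}"
            )


@dataclass(frozen=True)
class MVCReference:
    """Maximum of the MVC envelope per muscle, used for normalization."""

    mvc_env_max_agonist: float    # mV
    mvc_env_max_antagonist: float  # mV

    def __post_init__(self) -> None:
        if self.mvc_env_max_agonist <= 0 or self.mvc_env_max_antagonist <= 0:
            raise ParameterError("MVC envelope maxima must be strictly positive")


@dataclass
class ActivationTrace:
    """Neural activation u(t) and muscle activation a(t) for one muscle."""

    time: np.ndarray
    u: np.ndarray
    a: np.ndarray
    A: float = DEFAULT_A

    def resample(self, new_time: np.ndarray) -> "ActivationTrace":
        """Linear interpolation onto a new time grid (e.g. the simulation grid)."""
        new_time = np.asarray(new_time, dtype=float)
        return ActivationTrace(
            time=new_time,
            u=np.interp(new_time, self.time, self.u),
            a=np.interp(new_time, self.time, self.a),
            A=self.A,
        )


def _check_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(x)):
        raise DataError("input series contains NaN or infinite samples")
    return x


def preprocess_emg(raw, fs: float, bandpass=DEFAULT_BANDPASS, notch=DEFAULT_NOTCH,
                   order: int = FILTER_ORDER):
    """Band-pass, notch and rectify a raw EMG series (zero-phase filters)."""
    if fs <= 1000:
        raise InvalidSamplingRateError(
            f"fs must exceed 1000 Hz for a {bandpass[1]:.0f} Hz band edge, got {fs}"
        )
    raw = _check_series(raw)
    if len(raw) <= 10 * order:
        raise DataError(f"series too short for order-{order} zero-phase filtering")
    sos_bp = signal.butter(order, bandpass, btype="bandpass", fs=fs, output="sos")
    sos_notch = signal.butter(order, notch, btype="bandstop", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos_bp, raw)
    x = signal.sosfiltfilt(sos_notch, x)
    return np.abs(x)


def envelope(processed, fs: float, cutoff: float = DEFAULT_ENVELOPE_CUTOFF):
    """Linear envelope: zero-phase low-pass Butterworth on the rectified signal."""
    if not 0 < cutoff < fs / 2:
        raise ParameterError(f"cutoff must lie in (0, fs/2), got {cutoff} at fs={fs}")
    processed = _check_series(processed)
    sos = signal.butter(ENVELOPE_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    env = signal.sosfiltfilt(sos, processed)
    return np.clip(env, 0.0, None)


def neural_activation(env, mvc_max: float):
    """Normalize an envelope by the MVC envelope maximum, clipped to [0, 1]."""
    if mvc_max <= 0:
        raise ParameterError(f"mvc_max must be > 0, got {mvc_max}")
    env = _check_series(env)
    return np.clip(env / mvc_max, 0.0, 1.0)


def muscle_activation(u, A: float = DEFAULT_A):
    """Exponential shape map from neural to muscle activation."""
    if A == 0:
        raise ParameterError("shape constant A must be nonzero (division by zero)")
    if A > 0:
        raise ParameterError(f"shape constant A must be negative, got {A}")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise DataError("neural activation u must lie in [0, 1]")
    a = np.expm1(A * u) / np.expm1(A)
    return a if a.ndim else float(a)


def inverse_muscle_activation(a, A: float = DEFAULT_A):
    """Inverse of :func:`muscle_activation`: u = log(1 + a*(e^A - 1)) / A."""
    if A >= 0:
        raise ParameterError(f"shape constant A must be negative, got {A}")
    a = np.asarray(a, dtype=float)
    u = np.log1p(a * np.expm1(A)) / A
    return u if u.ndim else float(u)


def activation_from_envelope(time, env, mvc_max: float, A: float = DEFAULT_A) -> ActivationTrace:
    """Build an :class:`ActivationTrace` from an envelope and its MVC reference."""
    u = neural_activation(env, mvc_max)
    return ActivationTrace(time=np.asarray(time, dtype=float), u=u,
                           a=muscle_activation(u, A), A=A)


def process_trial(trial: EMGTrial, mvc: MVCReference, *, A: float = DEFAULT_A,
                  bandpass=DEFAULT_BANDPASS, notch=DEFAULT_NOTCH,
                  envelope_cutoff: float = DEFAULT_ENVELOPE_CUTOFF,
                  ) -> tuple[ActivationTrace, ActivationTrace]:
    """Full chain from a trial to (agonist, antagonist) activation traces.

    Raw trials go through filtering, rectification and envelope extraction;
    envelope trials skip straight to MVC normalization.
    """
    traces = []
    for raw, mvc_max in (
        (trial.emg_agonist, mvc.mvc_env_max_agonist),
        (trial.emg_antagonist, mvc.mvc_env_max_antagonist),
    ):
        if trial.kind == "raw":
            env = envelope(preprocess_emg(raw, trial.fs, bandpass, notch), trial.fs,
                           envelope_cutoff)
        else:
            env = _check_series(raw)
        traces.append(activation_from_envelope(trial.time, env, mvc_max, A))
    return traces[0], traces[1]
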