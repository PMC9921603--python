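"""Hill-type musculotendon model for a single muscle.

The muscle is the classical three-element arrangement: a contractile element
(CE) whose force is the product of activation, a Gaussian force--length factor
and a hyperbolic force--velocity factor; a parallel element (PE) combining an
exponential-toe/linear spring with viscous damping; and a series element (SE),
the tendon, with the same exponential-toe/linear spring form.  Fiber state
evolves under Newton's law for the (small) muscle mass, and the tendon length
is tied to fiber length and joint angle through the joint radius.

All functions here are plain NumPy and accept scalars or arrays; the
performance-critical forward simulation re-implements the same formulas inside
a jitted kernel (see :mod:`elbowstiff._fastsim`) and is cross-checked against
these reference implementations in the test suite.

Units are SI throughout: lengths in m, forces in N, velocities in m/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .errors import ParameterError, StateError

__all__ = [
    "HillParams",
    "MuscleState",
    "force_length",
    "force_velocity",
    "contractile_force",
    "parallel_elastic_force",
    "parallel_elastic_energy",
    "parallel_damping_force",
    "tendon_force",
    "tendon_energy",
    "musculotendon_length",
    "fiber_acceleration",
    "muscle_torque",
]

#: Eccentric (lengthening) plateau of the force--velocity factor.
ECCENTRIC_LIMIT = 1.5

#: Map from attribute names to the symbols used in serialized parameter files.
_JSON_KEYS = {
    "Fmax": "F_max",
    "w": "w",
    "lmopt": "l_mopt",
    "af": "a_f",
    "vmax": "v_max",
    "kte": "k_te",
    "ktl": "k_tl",
    "kt": "k_t",
    "ltc": "l_tc",
    "lts": "l_ts",
    "kml": "k_ml",
    "kme": "k_me",
    "km": "k_m",
    "lmc": "l_mc",
    "lms": "l_ms",
    "Bm": "B_m",
    "Mm": "M_m",
}


@dataclass(frozen=True)
class HillParams:
    """The 17 musculotendon parameters (shared by both muscles of the pair).

    Attributes
    ----------
    Fmax : maximum isometric force [N]
    w : width of the force--length relationship [-]
    lmopt : optimal muscle fiber length [m]
    af : force--velocity shape parameter [-]
    vmax : maximum unloaded shortening speed [m/s]
    kte, ktl, kt : tendon exponential shape [1/m], toe stiffness scale [N/m]
        and linear-region stiffness [N/m]
    ltc, lts : tendon linear-onset length and slack length [m]
    kml, kme, km : parallel-elastic toe scale [N/m], exponential shape [1/m]
        and linear-region stiffness [N/m]
    lmc, lms : parallel-elastic linear-onset length and slack length [m]
    Bm : parallel damping constant [N·s/m]
    Mm : muscle mass [kg]
    """

    Fmax: float
    w: float
    lmopt: float
    af: float
    vmax: float
    kte: float
    ktl: float
    kt: float
    ltc: float
    lts: float
    kml: float
    kme: float
    km: float
    lmc: float
    lms: float
    Bm: float
    Mm: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ParameterError(f"HillParams.{f.name} must be finite and > 0, got {v!r}")
        if self.lms > self.lmc:
            raise ParameterError(
                f"parallel-elastic slack length lms={self.lms} exceeds linear-onset lmc={self.lmc}"
            )
        if self.lts > self.ltc:
            raise ParameterError(
                f"tendon slack length lts={self.lts} exceeds linear-onset ltc={self.ltc}"
            )

    def to_dict(self) -> dict:
        return {_JSON_KEYS[f.name]: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "HillParams":
        inv = {v: k for k, v in _JSON_KEYS.items()}
        return cls(**{inv[k]: float(v) for k, v in d.items() if k in inv})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "HillParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MuscleState:
    """Instantaneous fiber/tendon state of one musculotendon unit."""

    lm: float  # fiber length [m]
    vm: float  # fiber lengthening rate dlm/dt [m/s]
    lt: float  # tendon length [m]

    def __post_init__(self) -> None:
        if self.lm <= 0:
            raise StateError(f"fiber length must be positive, got {self.lm}")
        if self.lt < 0:
            raise StateError(f"tendon length must be non-negative, got {self.lt}")


def force_length(lm, lmopt: float, w: float):
    """Gaussian active force--length factor, 1 at ``lm == lmopt``."""
    if lmopt <= 0 or w <= 0:
        raise ParameterError("lmopt and w must be > 0")
    lm = np.asarray(lm, dtype=float)
    out = np.exp(-(((lm / lmopt) - 1.0) / w) ** 2)
    return out if out.ndim else float(out)


def force_velocity(v_short, vmax: float, af: float, ecc_limit: float = ECCENTRIC_LIMIT):
    """Hyperbolic force--velocity factor of the contractile element.

    ``v_short`` is the *shortening* rate (= -dlm/dt): the factor is 1 at zero
    velocity, falls to 0 at ``vmax`` (clamped to 0 beyond), and on the
    eccentric side (``v_short < 0``) the same hyperbola is evaluated and
    clamped to ``ecc_limit`` to avoid the pole at ``-af*vmax``.
    """
    if vmax <= 0 or af <= 0:
        raise ParameterError("vmax and af must be > 0")
    v = np.asarray(v_short, dtype=float) / vmax
    den = 1.0 + v / af
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(den > 0, (1.0 - v) / den, ecc_limit)
    g = np.clip(g, 0.0, ecc_limit)
    g = np.where(v >= 1.0, 0.0, g)
    return g if g.ndim else float(g)


def contractile_force(a, lm, v_short, p: HillParams):
    """Active CE force: ``Fmax * a * f(lm) * g(v_short)`` [N]."""
    return p.Fmax * np.asarray(a, dtype=float) * force_length(lm, p.lmopt, p.w) * force_velocity(
        v_short, p.vmax, p.af
    )


def _toe_linear_force(x, slack: float, onset: float, k_toe: float, k_shape: float, k_lin: float):
    """Exponential-toe spring turning linear past ``onset``; 0 below ``slack``.

    The toe coefficient is the ratio ``k_toe/k_shape`` so the force carries
    units of N and the slope at the slack length equals ``k_toe``.
    """
    if slack > onset:
        raise ParameterError(f"slack length {slack} exceeds linear-onset length {onset}")
    x = np.asarray(x, dtype=float)
    ratio = k_toe / k_shape
    f_onset = ratio * (np.exp(k_shape * (onset - slack)) - 1.0)
    toe = ratio * (np.exp(k_shape * np.clip(x - slack, 0.0, onset - slack)) - 1.0)
    out = np.where(x <= onset, toe, f_onset + k_lin * (x - onset))
    out = np.where(x < slack, 0.0, out)
    return out if out.ndim else float(out)


def _toe_linear_energy(x, slack: float, onset: float, k_toe: float, k_shape: float, k_lin: float):
    """Elastic energy stored in a toe/linear spring (zero at/below slack)."""
    x = np.asarray(x, dtype=float)
    ratio = k_toe / k_shape
    d = np.clip(x - slack, 0.0, onset - slack)
    u_toe = (ratio / k_shape) * (np.exp(k_shape * d) - 1.0) - ratio * d
    f_onset = ratio * (np.exp(k_shape * (onset - slack)) - 1.0)
    dl = np.clip(x - onset, 0.0, None)
    out = u_toe + f_onset * dl + 0.5 * k_lin * dl**2
    return out if out.ndim else float(out)


def parallel_elastic_force(lm, p: HillParams):
    """Passive parallel-elastic (spring) force of the muscle belly [N]."""
    return _toe_linear_force(lm, p.lms, p.lmc, p.kml, p.kme, p.km)


def parallel_elastic_energy(lm, p: HillParams):
    """Energy stored in the parallel-elastic spring [J]."""
    return _toe_linear_energy(lm, p.lms, p.lmc, p.kml, p.kme, p.km)


def parallel_damping_force(vm, Bm: float):
    """Viscous parallel damping force ``Bm * vm`` [N] (sign follows vm)."""
    out = Bm * np.asarray(vm, dtype=float)
    return out if out.ndim else float(out)


def tendon_force(lt, p: HillParams):
    """Series-element (tendon) force [N]: slack below lts, toe to ltc, then linear."""
    return _toe_linear_force(lt, p.lts, p.ltc, p.ktl, p.kte, p.kt)


def tendon_energy(lt, p: HillParams):
    """Elastic energy stored in the tendon [J]."""
    return _toe_linear_energy(lt, p.lts, p.ltc, p.ktl, p.kte, p.kt)


def musculotendon_length(q, lm, p: HillParams, rp: float, sign: int):
    """Tendon length from joint angle and fiber length [m].

    ``lt = lms + lts + sign*rp*q - lm`` with the instantaneous joint angle
    ``q`` (rad from full extension).  ``sign`` is the moment-arm sign of the
    muscle: +1 for the extensor (its musculotendon unit lengthens with
    flexion), -1 for the flexor.
    """
    if rp <= 0:
        raise ParameterError("joint radius rp must be > 0")
    if sign not in (-1, 1):
        raise ParameterError("sign must be +1 (extensor) or -1 (flexor)")
    lt = p.lms + p.lts + sign * rp * np.asarray(q, dtype=float) - np.asarray(lm, dtype=float)
    if np.any(lt < 0):
        raise StateError(
            "computed tendon length is negative; parameters and state are inconsistent"
        )
    return lt if lt.ndim else float(lt)


def fiber_acceleration(F_SE, F_CE, F_PE, Mm: float):
    """Fiber acceleration ``(F_SE - F_CE - F_PE)/Mm`` [m/s^2]."""
    if Mm <= 0:
        raise ParameterError("muscle mass Mm must be > 0")
    out = (np.asarray(F_SE, dtype=float) - np.asarray(F_CE) - np.asarray(F_PE)) / Mm
    return out if out.ndim else float(out)


def muscle_torque(F_SE, rp: float):
    """Joint torque transmitted through the tendon: ``F_SE * rp`` [N·m]."""
    out = np.asarray(F_SE, dtype=float) * rp
    return out if out.ndim else float(out)
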