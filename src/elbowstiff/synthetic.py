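"""Protocol-faithful synthetic trials from known ground-truth parameters.

The generator emulates the paced flexion/extension task: each metronome cycle
(two beats: one flexion, one extension) drives a raised-cosine agonist burst
in its first half and an antagonist burst in its second half, on top of a
constant co-contraction floor.  Burst amplitudes grow with tempo (faster
movements need larger accelerating torques) and with the pulled load.  The
"measured" goniometer angle is the forward-model trajectory plus Gaussian
noise, and the "recorded" EMG envelopes are the generating muscle activations
pushed through the inverse of the activation shape map and scaled by the MVC
reference, with multiplicative noise — so the analysis chain, run on a
noiseless synthetic trial, recovers the generating activations exactly.

The generator's default conditions mirror the experimental protocol: training
ramp at 15/30/45/60 bpm with a 0.5 kg load, tempo sweep (E1) at the same four
tempos, and load sweep (E2) at 30 bpm with 0, 0.25, 0.5, 0.75 and 1 kg.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import SegmentProperties, SimConfig, SimulationResult, simulate_forward
from .emg import DEFAULT_A, ActivationTrace, EMGTrial, MVCReference, inverse_muscle_activation
from .errors import ParameterError, StateError
from .parameters import default_ground_truth_vector, split_vector

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "SyntheticTrial",
    "synth_activations",
    "synth_trial",
    "synth_protocol",
    "TRAINING_TEMPOS",
    "E1_TEMPOS",
    "E2_LOADS",
]

TRAINING_TEMPOS = (15.0, 30.0, 45.0, 60.0)
E1_TEMPOS = (15.0, 30.0, 45.0, 60.0)
E2_LOADS = (0.0, 0.25, 0.5, 0.75, 1.0)
TRAINING_LOAD = 0.5
E2_TEMPO = 30.0

# Burst-amplitude model constants (generator design, see docs/methods.md):
# amplitude grows sublinearly with tempo and linearly with load, capped
# well below saturation of the activation map.  The extensor burst spans only
# part of the extension half-cycle: the task's hard stop at full extension
# (chest/table) is not modelled, so the return movement must hand over to the
# passive structures before the joint would hyperextend.
_FLEX_BASE = 0.40
_EXT_RATIO = 0.25
_TEMPO_EXP = 0.7
_LOAD_GAIN = 0.35
_AMP_CAP = 0.90
_EXT_SPAN = 0.4  # extensor burst length as a fraction of the half-cycle


@dataclass(frozen=True)
class ScenarioSpec:
    """One synthetic recording condition."""

    tempo: float = 30.0            # bpm; protocol uses {15, 30, 45, 60}
    load: float = 0.5              # kg; protocol uses {0, 0.25, 0.5, 0.75, 1}
    n_repetitions: int = 10        # flexion+extension cycles
    fs: float = 100.0              # Hz of the written trial
    envelope_noise: float = 0.05   # multiplicative std on the envelopes
    goniometer_noise_deg: float = 0.5  # additive angle noise std [deg]
    co_contraction: float = 0.05   # baseline activation of both muscles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repetitions < 1:
            raise ParameterError("n_repetitions must be >= 1")
        if self.envelope_noise < 0 or self.goniometer_noise_deg < 0:
            raise ParameterError("noise levels must be >= 0")
        if not 0 <= self.co_contraction < 1:
            raise ParameterError("co-contraction must lie in [0, 1)")
        if self.tempo <= 0 or self.fs <= 0 or self.load < 0:
            raise ParameterError("tempo and fs must be > 0, load >= 0")

    @property
    def cycle_period(self) -> float:
        """Seconds per flexion+extension cycle (two metronome beats)."""
        return 2.0 * 60.0 / self.tempo


@dataclass(frozen=True)
class GroundTruth:
    """Known generating parameters of a synthetic dataset."""

    vector: np.ndarray = field(default_factory=default_ground_truth_vector)
    segment: SegmentProperties = field(default_factory=SegmentProperties)
    mvc: MVCReference = field(default_factory=lambda: MVCReference(1.0, 1.0))


@dataclass
class SyntheticTrial:
    """A noisy synthetic trial plus its noiseless reference record."""

    trial: EMGTrial                 # envelope-kind channels + noise
    angle_deg: np.ndarray           # noisy goniometer angle [deg]
    spec: ScenarioSpec
    mvc: MVCReference
    # noiseless ground truth
    a_AG: ActivationTrace
    a_ANT: ActivationTrace
    reference: SimulationResult     # the generating simulation (q in rad)

    @property
    def time(self) -> np.ndarray:
        return self.trial.time

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.time,
            "emg_ag": self.trial.emg_agonist,
            "emg_ant": self.trial.emg_antagonist,
            "angle_deg": self.angle_deg,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _burst(phase: np.ndarray) -> np.ndarray:
    """Raised-cosine bump on phase in [0, 1), zero outside."""
    out = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(phase, 0.0, 1.0)))
    out[(phase < 0.0) | (phase >= 1.0)] = 0.0
    return out


def burst_amplitudes(tempo: float, load: float) -> tuple[float, float]:
    """(flexor, extensor) peak activations for a condition."""
    amp_flex = min(_AMP_CAP, _FLEX_BASE * (tempo / 30.0) ** _TEMPO_EXP * (1.0 + _LOAD_GAIN * load))
    return amp_flex, _EXT_RATIO * amp_flex


def synth_activations(spec: ScenarioSpec) -> tuple[ActivationTrace, ActivationTrace]:
    """Deterministic reciprocal burst pattern for one condition.

    The agonist (flexor) bursts during the first half of each cycle, the
    antagonist (extensor) during the second half; both carry the baseline
    co-contraction and are clipped to [0, 1].
    """
    period = spec.cycle_period
    n = int(round(spec.n_repetitions * period * spec.fs)) + 1
    time = np.arange(n) / spec.fs
    cyc_phase = (time % period) / period
    amp_flex, amp_ext = burst_amplitudes(spec.tempo, spec.load)
    a_flex = amp_flex * _burst(cyc_phase * 2.0)                       # first half-cycle
    a_ext = amp_ext * _burst((cyc_phase * 2.0 - 1.0) / _EXT_SPAN)     # early second half
    # last sample belongs to no new cycle: keep the pattern periodic
    a_flex = np.clip(a_flex + spec.co_contraction, 0.0, 1.0)
    a_ext = np.clip(a_ext + spec.co_contraction, 0.0, 1.0)
    u_flex = inverse_muscle_activation(a_flex, DEFAULT_A)
    u_ext = inverse_muscle_activation(a_ext, DEFAULT_A)
    return (
        ActivationTrace(time=time, u=u_flex, a=a_flex, A=DEFAULT_A),
        ActivationTrace(time=time, u=u_ext, a=a_ext, A=DEFAULT_A),
    )


def synth_trial(gt: GroundTruth, spec: ScenarioSpec, *,
                sim_cfg: SimConfig | None = None) -> SyntheticTrial:
    """Simulate one condition and wrap it as a noisy envelope-kind trial."""
    sim_cfg = sim_cfg or SimConfig()
    a_ag, a_ant = synth_activations(spec)
    hill_p, joint_p = split_vector(gt.vector)
    seg = gt.segment.with_load(spec.load)
    try:
        ref = simulate_forward(a_ag, a_ant, hill_p, joint_p, seg, sim_cfg)
    except StateError as exc:
        raise StateError(f"ground-truth simulation failed ({exc}); "
                         "the generating parameters are implausible") from exc

    rng = np.random.default_rng(spec.seed)
    angle_deg = np.degrees(ref.q) + rng.normal(0.0, spec.goniometer_noise_deg, len(ref.q))
    env_ag = gt.mvc.mvc_env_max_agonist * a_ag.u
    env_ant = gt.mvc.mvc_env_max_antagonist * a_ant.u
    if spec.envelope_noise > 0:
        env_ag = env_ag * (1.0 + rng.normal(0.0, spec.envelope_noise, len(env_ag)))
        env_ant = env_ant * (1.0 + rng.normal(0.0, spec.envelope_noise, len(env_ant)))
    trial = EMGTrial(time=a_ag.time, emg_agonist=np.clip(env_ag, 0.0, None),
                     emg_antagonist=np.clip(env_ant, 0.0, None), fs=spec.fs,
                     kind="envelope")
    return SyntheticTrial(trial=trial, angle_deg=angle_deg, spec=spec, mvc=gt.mvc,
                          a_AG=a_ag, a_ANT=a_ant, reference=ref)


def synth_protocol(gt: GroundTruth, seed: int = 0, out_dir: str | Path | None = None,
                   *, n_repetitions: int = 4, fs: float = 100.0) -> dict:
    """Generate the full study bundle (training + E1 + E2), optionally on disk.

    Conditions follow the protocol structure; ``n_repetitions`` scales the
    per-condition cycle count for desk-scale runs.  Returns a manifest dict;
    with ``out_dir`` set, trials are written as CSV and the manifest (with the
    generating ground truth) as JSON.
    """
    ss = np.random.SeedSequence(seed)
    seeds = iter(int(s) % (2**31) for s in ss.generate_state(64))
    conditions = (
        [("training", t, TRAINING_LOAD) for t in TRAINING_TEMPOS]
        + [("e1", t, TRAINING_LOAD) for t in E1_TEMPOS]
        + [("e2", E2_TEMPO, w) for w in E2_LOADS]
    )
    manifest: dict = {
        "seed": seed,
        "ground_truth": {"vector": [float(v) for v in gt.vector]},
        "trials": [],
    }
    trials = {}
    for phase, tempo, load in conditions:
        spec = ScenarioSpec(tempo=tempo, load=load, n_repetitions=n_repetitions,
                            fs=fs, seed=next(seeds))
        st = synth_trial(gt, spec)
        name = f"{phase}_tempo{int(tempo)}_load{load:g}"
        trials[name] = st
        entry = {"name": name, "phase": phase, "tempo": tempo, "load": load,
                 "seed": spec.seed, "file": f"{phase}/{name}.csv"}
        manifest["trials"].append(entry)
        if out_dir is not None:
            path = Path(out_dir) / phase
            path.mkdir(parents=True, exist_ok=True)
            st.to_csv(Path(out_dir) / entry["file"])
    if out_dir is not None:
        (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2))
    manifest["_trials"] = trials
    return manifest
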