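"""Desk-scale reproduction of the identification/verification study.

Bundles the canonical evaluation used by the acceptance tooling: generate a
synthetic training trial (4 flexion/extension movements at 30 bpm, 0.5 kg,
100 Hz, 0.5 deg goniometer noise) from the default ground truth, identify the
24 parameters with the GA (population 20, crossover 0.7, 2 elites, up to 100
generations), and express the DTW average angle deviation of the identified
model as a percentage of the 150 deg functional range — on the training trial
and on held-out tempo/load conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import simulate_forward
from .emg import process_trial
from .ga import GAConfig, GAResult, evolve
from .parameters import table_bounds
from .synthetic import GroundTruth, ScenarioSpec, synth_trial
from .validation import FULL_ELBOW_RANGE_DEG, dtw_avg_deviation

__all__ = ["StudyOutcome", "run_identification_study", "TRAINING_SPEC", "HELDOUT_SPECS"]

TRAINING_SPEC = dict(tempo=30.0, load=0.5, n_repetitions=4, fs=100.0)
HELDOUT_SPECS = (dict(tempo=60.0, load=0.5, n_repetitions=4, fs=100.0),
                 dict(tempo=30.0, load=1.0, n_repetitions=4, fs=100.0))


@dataclass
class StudyOutcome:
    ga: GAResult
    train_deviation_deg: float
    train_percent: float
    heldout_percents: tuple[float, ...]
    n_train_samples: int

    @property
    def worst_heldout_percent(self) -> float:
        return max(self.heldout_percents)


def _deviation_percent(trial, vector, gt: GroundTruth) -> tuple[float, float, int]:
    from .parameters import split_vector

    hill_p, joint_p = split_vector(vector)
    a_ag, a_ant = process_trial(trial.trial, trial.mvc)
    seg = gt.segment.with_load(trial.spec.load)
    sim = simulate_forward(a_ag, a_ant, hill_p, joint_p, seg)
    rep = dtw_avg_deviation(trial.angle_deg, np.degrees(sim.q),
                            full_range=FULL_ELBOW_RANGE_DEG)
    return rep.avg_deviation, rep.percent_of_range, rep.n_samples


def run_identification_study(seed: int = 1, *, max_generations: int = 100,
                             gt: GroundTruth | None = None) -> StudyOutcome:
    """Full scaled-down study; all randomness derives from ``seed``."""
    gt = gt or GroundTruth()
    ss = np.random.SeedSequence(seed)
    s_train, s_ga, *s_heldout = (int(s) % (2**31) for s in ss.generate_state(6))

    train = synth_trial(gt, ScenarioSpec(seed=s_train, **TRAINING_SPEC))
    a_ag, a_ant = process_trial(train.trial, train.mvc)
    ga = evolve(a_ag, a_ant, np.radians(train.angle_deg), train.time, table_bounds(),
                GAConfig(max_generations=max_generations, seed=s_ga),
                seg=gt.segment.with_load(train.spec.load))

    _, train_pct, n_train = _deviation_percent(train, ga.best_vector, gt)
    train_dev = train_pct / 100.0 * FULL_ELBOW_RANGE_DEG
    heldout = []
    for spec_kwargs, s in zip(HELDOUT_SPECS, s_heldout):
        trial = synth_trial(gt, ScenarioSpec(seed=s, **spec_kwargs))
        _, pct, _ = _deviation_percent(trial, ga.best_vector, gt)
        heldout.append(pct)
    return StudyOutcome(ga=ga, train_deviation_deg=train_dev, train_percent=train_pct,
                        heldout_percents=tuple(heldout), n_train_samples=n_train)
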