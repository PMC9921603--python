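"""Trajectory verification (DTW) and parameter-sensitivity analysis.

The agreement between a measured and a model-estimated series is quantified
by dynamic time warping with absolute-difference local cost and the symmetric
step pattern, normalized by the number of samples of the reference series
("average deviation", same units as the inputs).  Expressed against the
150 deg functional elbow range this gives the percent-of-range deviation used
to accept or reject an identified model.

The sensitivity analysis perturbs each identified parameter by a set of
relative steps, re-simulates, re-estimates the stiffness trace and reports
the DTW average deviation of the perturbed trace from the baseline
(N·m/rad); runs whose simulation diverges (or whose perturbed parameters are
inconsistent) are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fastsim
from .dynamics import SegmentProperties, SimConfig, simulate_forward
from .errors import DataError, ParameterError
from .parameters import PARAM_NAMES, split_vector, vector_valid
from .rls import estimate_trace

__all__ = [
    "DeviationReport",
    "dtw_avg_deviation",
    "percent_of_range",
    "sensitivity_table",
    "FULL_ELBOW_RANGE_DEG",
]

#: Functional elbow flexion range used to express deviations as percentages.
FULL_ELBOW_RANGE_DEG = 150.0


@dataclass(frozen=True)
class DeviationReport:
    """DTW average deviation between two series."""

    avg_deviation: float          # units of the input series
    n_samples: int                # length of the reference series
    percent_of_range: float | None = None  # vs a stated full range, if given


def dtw_avg_deviation(x, y, *, full_range: float | None = None,
                      normalize: str = "reference") -> DeviationReport:
    """Classic DTW cost between ``x`` (reference) and ``y``, averaged.

    ``normalize="reference"`` divides the optimal accumulated cost by
    ``len(x)`` (the default reading of "divided by the number of samples");
    ``"path"`` divides by the optimal warping-path length instead.
    """
    x = np.ascontiguousarray(x, dtype=float)
    y = np.ascontiguousarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("DTW inputs must be non-empty")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise DataError("DTW inputs must be finite")
    cost = float(_fastsim.dtw_cost(x, y))
    if normalize == "reference":
        denom = len(x)
    elif normalize == "path":
        denom = _dtw_path_length(x, y)
    else:
        raise ParameterError(f"unknown normalization {normalize!r}")
    avg = cost / denom
    pct = percent_of_range(avg, full_range) if full_range is not None else None
    return DeviationReport(avg_deviation=avg, n_samples=len(x), percent_of_range=pct)


def _dtw_path_length(x: np.ndarray, y: np.ndarray) -> int:
    """Length of one optimal warping path (full DP with backtracking)."""
    n, m = len(x), len(y)
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = abs(x[i - 1] - y[j - 1]) + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    i, j, steps = n, m, 1
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min((mv for mv in moves if mv[0] >= 1 and mv[1] >= 1), key=lambda mv: D[mv])
        steps += 1
    return steps


def percent_of_range(deviation: float, full_range: float = FULL_ELBOW_RANGE_DEG) -> float:
    """Deviation as a percentage of a stated full range."""
    if full_range <= 0:
        raise ParameterError("full_range must be > 0")
    return 100.0 * deviation / full_range


#: Column layout of the sensitivity table.
SENSITIVITY_STEPS = (-0.10, 0.10, -0.20, 0.20, -0.30, 0.30)


def sensitivity_table(vector, a_AG, a_ANT, seg: SegmentProperties,
                      cfg: SimConfig | None = None,
                      steps=SENSITIVITY_STEPS, *, rls_mode: str = "derivative",
                      ) -> pd.DataFrame:
    """Per-parameter stiffness sensitivity to relative parameter changes.

    For every identified parameter and every relative step, the model is
    re-simulated with the perturbed 24-vector, the stiffness trace is
    re-estimated, and the DTW average deviation from the baseline stiffness
    trace is tabulated (N·m/rad).  Entries whose perturbed run diverges or is
    invalid are NaN and listed in ``df.attrs["diverged"]``.
    """
    vector = np.asarray(vector, dtype=float)
    cfg = cfg or SimConfig()

    def run(vec) -> np.ndarray | None:
        if not vector_valid(vec):
            return None
        hill_p, joint_p = split_vector(vec)
        res = simulate_forward(a_AG, a_ANT, hill_p, joint_p, seg, cfg, check=False)
        if not res.ok:
            return None
        tr = estimate_trace(res.tau_J, res.q, res.time, mode=rls_mode)
        return tr.stiffness

    baseline = run(vector)
    if baseline is None:
        raise DataError("baseline simulation diverged; cannot build sensitivity table")

    cols = [f"{int(s * 100):+d}%" for s in steps]
    table = pd.DataFrame(index=list(PARAM_NAMES), columns=cols, dtype=float)
    diverged: list[tuple[str, str]] = []
    for i, name in enumerate(PARAM_NAMES):
        for s, col in zip(steps, cols):
            vec = vector.copy()
            vec[i] *= 1.0 + s
            stiff = run(vec)
            if stiff is None:
                table.loc[name, col] = np.nan
                diverged.append((name, col))
            else:
                table.loc[name, col] = dtw_avg_deviation(baseline, stiff).avg_deviation
    table.attrs["diverged"] = diverged
    return table
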