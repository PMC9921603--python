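"""The 24-parameter identification vector and its shipped bounds.

The identifiable set is the 17 musculotendon parameters (one set shared by the
flexor/extensor pair) plus the 7 passive-joint parameters.  Two bounds presets
are shipped:

* ``"table"`` -- the published min/max range of each parameter over a group of
  unimpaired adults (the default; also the source of the default synthetic
  ground truth, taken at interval midpoints).
* half/twice of a user-supplied literature value per parameter, via
  :func:`default_bounds`.

Three rows of the published range table carry mean values inconsistent with
their own min/max columns (a print misalignment); the bounds here keep the
min/max columns, which are the physically plausible ones (Bm in N·s/m of
order 1e2, Mm in kg of order 0.4, vmax in m/s of order 1).
"""

from __future__ import annotations

import numpy as np

from .errors import ParameterError
from .hill import HillParams

__all__ = [
    "PARAM_NAMES",
    "PARAM_UNITS",
    "TABLE_BOUNDS",
    "N_PARAMS",
    "table_bounds",
    "default_bounds",
    "split_vector",
    "join_params",
    "vector_valid",
    "default_ground_truth_vector",
]

#: Canonical parameter order of the identification vector.
PARAM_NAMES: tuple[str, ...] = (
    # 17 musculotendon parameters
    "F_max", "w", "l_mopt", "a_f", "v_max",
    "k_te", "k_tl", "k_t", "l_tc", "l_ts",
    "k_ml", "k_me", "k_m", "l_mc", "l_ms",
    "B_m", "M_m",
    # 7 passive-joint parameters
    "k_1", "k_2", "k_4", "k_5", "q_1", "q_2", "B_p",
)

N_PARAMS = len(PARAM_NAMES)

PARAM_UNITS: dict[str, str] = {
    "F_max": "N", "w": "-", "l_mopt": "m", "a_f": "-", "v_max": "m/s",
    "k_te": "1/m", "k_tl": "N/m", "k_t": "N/m", "l_tc": "m", "l_ts": "m",
    "k_ml": "N/m", "k_me": "1/m", "k_m": "N/m", "l_mc": "m", "l_ms": "m",
    "B_m": "N·s/m", "M_m": "kg",
    "k_1": "N·m", "k_2": "1/rad", "k_4": "N·m", "k_5": "1/rad",
    "q_1": "rad", "q_2": "rad", "B_p": "N·m·s",
}

#: Published group min/max range per parameter (see module docstring).
TABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "F_max": (1401.59, 3913.00),
    "w": (0.64, 0.96),
    "l_mopt": (0.10, 0.27),
    "a_f": (0.25, 0.75),
    "v_max": (0.54, 1.46),
    "k_te": (1511.02, 4042.59),
    "k_tl": (15570.31, 43133.01),
    "k_t": (317771.71, 923909.99),
    "l_tc": (0.23, 0.47),
    "l_ts": (0.24, 0.46),
    "k_ml": (244.96, 710.60),
    "k_me": (46.05, 113.92),
    "k_m": (2500.06, 7352.47),
    "l_mc": (0.10, 0.19),
    "l_ms": (0.10, 0.27),
    "B_m": (130.97, 342.17),
    "M_m": (0.33, 0.45),
    "k_1": (4.54, 9.05),
    "k_2": (0.25, 0.43),
    "k_4": (15.00, 60.5),
    "k_5": (0.02, 0.04),
    "q_1": (3.11, 5.49),
    "q_2": (3.22, 6.95),
    "B_p": (1.55, 4.05),
}

_HILL_ATTRS = (
    "Fmax", "w", "lmopt", "af", "vmax", "kte", "ktl", "kt", "ltc", "lts",
    "kml", "kme", "km", "lmc", "lms", "Bm", "Mm",
)


def table_bounds() -> tuple[np.ndarray, np.ndarray]:
    """Shipped bounds preset as (lower, upper) arrays in canonical order."""
    lo = np.array([TABLE_BOUNDS[n][0] for n in PARAM_NAMES])
    hi = np.array([TABLE_BOUNDS[n][1] for n in PARAM_NAMES])
    return lo, hi


def default_bounds(values) -> tuple[np.ndarray, np.ndarray]:
    """Half/twice bounds around positive literature values.

    ``values`` is either a length-24 array in canonical order or a
    ``{name: value}`` mapping.
    """
    if isinstance(values, dict):
        v = np.array([values[n] for n in PARAM_NAMES], dtype=float)
    else:
        v = np.asarray(values, dtype=float)
    if v.shape != (N_PARAMS,):
        raise ParameterError(f"expected {N_PARAMS} values, got shape {v.shape}")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ParameterError("literature values must be finite and > 0")
    return v / 2.0, v * 2.0


def split_vector(vec) -> tuple[HillParams, "PassiveJointParams"]:
    """Convert a canonical 24-vector into typed parameter objects."""
    from .dynamics import PassiveJointParams  # local import to avoid a cycle

    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,):
        raise ParameterError(f"expected a length-{N_PARAMS} vector, got shape {vec.shape}")
    hill = HillParams(**dict(zip(_HILL_ATTRS, vec[:17])))
    k1, k2, k4, k5, q1, q2, Bp = vec[17:]
    joint = PassiveJointParams(k1=k1, k2=k2, k4=k4, k5=k5, q1=q1, q2=q2, Bp=Bp)
    return hill, joint


def join_params(hill: HillParams, joint) -> np.ndarray:
    """Inverse of :func:`split_vector`."""
    head = [getattr(hill, a) for a in _HILL_ATTRS]
    tail = [joint.k1, joint.k2, joint.k4, joint.k5, joint.q1, joint.q2, joint.Bp]
    return np.array(head + tail, dtype=float)


def vector_valid(vec) -> bool:
    """Cheap validity check used on optimizer candidates.

    True iff all entries are finite and positive and the piecewise springs
    are well ordered (l_ms <= l_mc, l_ts <= l_tc).
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_PARAMS,) or not np.all(np.isfinite(vec)) or np.any(vec <= 0):
        return False
    i = {n: k for k, n in enumerate(PARAM_NAMES)}
    return bool(vec[i["l_ms"]] <= vec[i["l_mc"]] and vec[i["l_ts"]] <= vec[i["l_tc"]])


def default_ground_truth_vector() -> np.ndarray:
    """Midpoint of each shipped bound interval, made self-consistent.

    The raw midpoint of l_ms exceeds the midpoint of l_mc, which the
    parallel-elastic piecewise form forbids; l_ms is clipped down to l_mc.
    """
    lo, hi = table_bounds()
    mid = 0.5 * (lo + hi)
    i = {n: k for k, n in enumerate(PARAM_NAMES)}
    mid[i["l_ms"]] = min(mid[i["l_ms"]], mid[i["l_mc"]])
    mid[i["l_ts"]] = min(mid[i["l_ts"]], mid[i["l_tc"]])
    return mid
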