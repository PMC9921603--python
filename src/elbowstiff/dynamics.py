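"""Passive joint structures and forward dynamics of the one-DoF elbow.

The elbow is a single hinge driven by an antagonistic pair of Hill-type
muscles (flexor = biceps long head, acting as agonist of the task; extensor =
triceps long head).  The passive joint structure contributes a
double-exponential restoring torque, viscous damping and (optionally) gravity.
Net torque over the effective inertia gives the angular acceleration, which is
integrated with a fixed-step RK4 scheme together with the fiber-state
dynamics of both muscles.

Angle convention: q = 0 rad at full extension, positive in flexion
(goniometer range roughly 0--150 deg).  With the default sign convention the
flexor's tendon torque accelerates the joint toward flexion; a
``paper_literal`` convention with the opposite muscle-torque signs is kept for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import _fastsim, hill
from .errors import DataError, DivergenceError, ParameterError, StateError
from .hill import HillParams

__all__ = [
    "PassiveJointParams",
    "SegmentProperties",
    "SimConfig",
    "SimulationResult",
    "passive_torque",
    "damping_torque",
    "gravity_torque",
    "total_torque",
    "equilibrium_fiber_length",
    "simulate_forward",
    "mechanical_energy",
]


@dataclass(frozen=True)
class PassiveJointParams:
    """Double-exponential passive torque + viscous damping parameters.

    ``tau_p(q) = k1*exp(-k2*(q - q2)) - k4*exp(-k5*(q1 - q))`` with q1, q2 the
    angles where each exponential branch starts to rise, and ``tau_d = -Bp*qd``.
    """

    k1: float  # N·m
    k2: float  # 1/rad
    k4: float  # N·m
    k5: float  # 1/rad
    q1: float  # rad
    q2: float  # rad
    Bp: float  # N·m·s

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k4", "k5", "Bp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"PassiveJointParams.{name} must be > 0")
        for name in ("q1", "q2"):
            v = getattr(self, name)
            # q1/q2 are curve-shape constants, not reachable joint angles; the
            # published identified range for q2 extends slightly past 2*pi.
            if not (np.isfinite(v) and v >= 0.0):
                raise ParameterError(f"PassiveJointParams.{name} must be finite and >= 0")

    def to_dict(self) -> dict:
        return {
            "k_1": self.k1, "k_2": self.k2, "k_4": self.k4, "k_5": self.k5,
            "q_1": self.q1, "q_2": self.q2, "B_p": self.Bp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PassiveJointParams":
        return cls(k1=d["k_1"], k2=d["k_2"], k4=d["k_4"], k5=d["k_5"],
                   q1=d["q_1"], q2=d["q_2"], Bp=d["B_p"])


@dataclass(frozen=True)
class SegmentProperties:
    """Measured inertial properties of the forearm--hand segment.

    ``rp`` is the elbow joint radius, half the measured elbow width.  The
    pulled weight enters as a point mass at ``load_arm`` from the joint axis,
    adding ``load_mass * load_arm**2`` to the rotational inertia.
    """

    m: float = 1.5          # kg, forearm-hand mass
    r_cm: float = 0.18      # m, joint axis to segment center of mass
    M: float = 0.065        # kg·m², segment moment of inertia about the elbow
    rp: float = 0.035       # m, joint radius (= half elbow width)
    g: float = 9.81         # m/s²
    load_mass: float = 0.0  # kg, pulled weight
    load_arm: float = 0.26  # m, lever arm of the weight (default forearm length)

    def __post_init__(self) -> None:
        if self.M <= 0 or self.rp <= 0:
            raise ParameterError("M and rp must be > 0")
        for name in ("m", "r_cm", "g", "load_mass", "load_arm"):
            if getattr(self, name) < 0:
                raise ParameterError(f"SegmentProperties.{name} must be >= 0")

    @property
    def effective_inertia(self) -> float:
        return self.M + self.load_mass * self.load_arm**2

    def with_load(self, load_mass: float) -> "SegmentProperties":
        return SegmentProperties(m=self.m, r_cm=self.r_cm, M=self.M, rp=self.rp,
                                 g=self.g, load_mass=load_mass, load_arm=self.load_arm)

    def to_array(self) -> np.ndarray:
        return np.array([self.m, self.r_cm, self.M, self.rp, self.g,
                         self.load_mass, self.load_arm])


@dataclass(frozen=True)
class SimConfig:
    """Integration configuration for :func:`simulate_forward`."""

    dt: float = 5e-4                      # s, internal integrator step
    integrator: str = "rk4"               # "rk4" | "euler"
    gravity_mode: str = "paper"           # "paper" (include tau_G) | "horizontal" (zero)
    sign_convention: str = "flexion_positive"  # | "paper_literal"
    q_guard: float = float(np.pi)         # rad, divergence guard on |q|
    fiber_init: str = "optimal"           # "optimal" (lm0 = lmopt) | "equilibrium"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("sim.dt must be > 0")
        if self.integrator not in ("rk4", "euler"):
            raise ParameterError(f"unknown integrator {self.integrator!r}")
        if self.gravity_mode not in ("paper", "horizontal"):
            raise ParameterError(f"unknown gravity_mode {self.gravity_mode!r}")
        if self.sign_convention not in ("flexion_positive", "paper_literal"):
            raise ParameterError(f"unknown sign_convention {self.sign_convention!r}")
        if self.fiber_init not in ("optimal", "equilibrium"):
            raise ParameterError(f"unknown fiber_init {self.fiber_init!r}")


@dataclass
class SimulationResult:
    """Forward-model time series on the activation grid (angles in rad)."""

    time: np.ndarray
    q: np.ndarray
    q_dot: np.ndarray
    tau_p: np.ndarray
    tau_d: np.ndarray
    tau_G: np.ndarray
    tau_AG: np.ndarray
    tau_ANT: np.ndarray
    tau_J: np.ndarray
    muscle_states: dict = field(default_factory=dict)  # per muscle: lm, vm, lt arrays
    status: int = _fastsim.OK
    bad_index: int = -1

    @property
    def ok(self) -> bool:
        return self.status == _fastsim.OK

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.time,
            "q_deg": np.degrees(self.q),
            "qdot": self.q_dot,
            "tau_J": self.tau_J,
            "tau_p": self.tau_p,
            "tau_d": self.tau_d,
            "tau_G": self.tau_G,
            "tau_AG": self.tau_AG,
            "tau_ANT": self.tau_ANT,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def passive_torque(q, p: PassiveJointParams):
    """Double-exponential passive joint torque [N·m]."""
    q = np.asarray(q, dtype=float)
    out = p.k1 * np.exp(-p.k2 * (q - p.q2)) - p.k4 * np.exp(-p.k5 * (p.q1 - q))
    return out if out.ndim else float(out)


def damping_torque(q_dot, Bp: float):
    """Viscous joint damping torque ``-Bp*q_dot`` [N·m] (opposes motion)."""
    out = -Bp * np.asarray(q_dot, dtype=float)
    return out if out.ndim else float(out)


def gravity_torque(q, s: SegmentProperties, horizontal: bool = False):
    """Gravity torque ``m*g*r_cm*sin(pi/2 - q)`` [N·m]; 0 in horizontal mode."""
    q = np.asarray(q, dtype=float)
    if horizontal:
        out = np.zeros_like(q)
    else:
        out = s.m * s.g * s.r_cm * np.sin(np.pi / 2.0 - q)
    return out if out.ndim else float(out)


def total_torque(tau_p, tau_d, tau_G, tau_AG, tau_ANT, convention: str = "flexion_positive"):
    """Net joint torque from its components.

    ``flexion_positive`` (default): agonist (flexor) torque positive, so
    biceps activation flexes the joint.  ``paper_literal``: the antagonist
    enters positively and the agonist negatively.
    """
    if convention == "flexion_positive":
        mu = 1.0
    elif convention == "paper_literal":
        mu = -1.0
    else:
        raise ParameterError(f"unknown sign convention {convention!r}")
    return tau_p + tau_d + tau_G + mu * (np.asarray(tau_AG, dtype=float) - np.asarray(tau_ANT))


def equilibrium_fiber_length(p: HillParams, q0: float, rp: float, sign: int) -> float:
    """Fiber length solving SE/PE force balance at zero activation and rest."""

    def residual(lm: float) -> float:
        lt = p.lms + p.lts + sign * rp * q0 - lm
        return hill.tendon_force(max(lt, 0.0), p) - hill.parallel_elastic_force(lm, p)

    hi = p.lms + p.lts + sign * rp * q0 - 1e-9
    lo = 1e-6
    if residual(lo) <= 0.0:  # no tension anywhere: fiber rests at slack config
        return min(p.lmopt, hi)
    return float(brentq(residual, lo, hi, xtol=1e-12))


def simulate_forward(a_AG, a_ANT, hill_params: HillParams, joint: PassiveJointParams,
                     seg: SegmentProperties, cfg: SimConfig | None = None, *,
                     time: np.ndarray | None = None,
                     check: bool = True) -> SimulationResult:
    """Integrate the elbow model driven by the two activation traces.

    ``a_AG``/``a_ANT`` are either :class:`~elbowstiff.emg.ActivationTrace`
    objects (their common time grid is used) or plain arrays with ``time``
    given explicitly.  The grid must be uniform; the integrator takes
    ``round(grid_dt / cfg.dt)`` substeps per sample.

    With ``check=True`` a diverged or inconsistent run raises
    :class:`DivergenceError` / :class:`StateError`; with ``check=False`` the
    (partial) result is returned with its status flag set.
    """
    cfg = cfg or SimConfig()
    if hasattr(a_AG, "a"):
        if time is None:
            time = np.asarray(a_AG.time, dtype=float)
        a_ag = np.asarray(a_AG.a, dtype=float)
    else:
        a_ag = np.asarray(a_AG, dtype=float)
    a_ant = np.asarray(a_ANT.a, dtype=float) if hasattr(a_ANT, "a") else np.asarray(a_ANT, dtype=float)
    if time is None:
        raise DataError("a time grid is required (pass ActivationTrace or time=...)")
    time = np.asarray(time, dtype=float)
    if not (len(time) == len(a_ag) == len(a_ant)):
        raise DataError("activation traces and time grid must have equal length")
    if len(time) < 2:
        raise DataError("need at least two samples to integrate")
    dt_out = float(time[1] - time[0])
    if dt_out <= 0 or not np.allclose(np.diff(time), dt_out, rtol=1e-6, atol=1e-12):
        raise DataError("time grid must be uniform and increasing")

    from .parameters import join_params

    th = join_params(hill_params, joint)
    n_sub = max(1, int(round(dt_out / cfg.dt)))
    mu = 1.0 if cfg.sign_convention == "flexion_positive" else -1.0
    gravity_on = 1.0 if cfg.gravity_mode == "paper" else 0.0
    integrator = 0 if cfg.integrator == "rk4" else 1

    if cfg.fiber_init == "optimal":
        lm0_ag = lm0_ant = hill_params.lmopt
    else:
        lm0_ag = equilibrium_fiber_length(hill_params, 0.0, seg.rp, -1)
        lm0_ant = equilibrium_fiber_length(hill_params, 0.0, seg.rp, +1)

    rec, status, bad = _fastsim.simulate_kernel(
        th, seg.to_array(), mu, gravity_on, cfg.q_guard, hill.ECCENTRIC_LIMIT,
        integrator, a_ag, a_ant, dt_out, n_sub, lm0_ag, lm0_ant,
    )
    result = SimulationResult(
        time=time, q=rec[:, 0], q_dot=rec[:, 1], tau_p=rec[:, 2], tau_d=rec[:, 3],
        tau_G=rec[:, 4], tau_AG=rec[:, 5], tau_ANT=rec[:, 6], tau_J=rec[:, 7],
        muscle_states={
            "agonist": {"lm": rec[:, 8], "vm": rec[:, 9], "lt": rec[:, 10]},
            "antagonist": {"lm": rec[:, 11], "vm": rec[:, 12], "lt": rec[:, 13]},
        },
        status=int(status), bad_index=int(bad),
    )
    if check and not result.ok:
        if status == _fastsim.ANGLE_GUARD:
            raise DivergenceError(
                f"joint angle left the guard band ±{cfg.q_guard:.3f} rad at step {bad}"
            )
        if status == _fastsim.NEGATIVE_TENDON:
            raise StateError(f"tendon length became negative at step {bad}")
        raise DivergenceError(f"simulation produced non-finite state at step {bad}")
    return result


def mechanical_energy(result: SimulationResult, hill_params: HillParams,
                      joint: PassiveJointParams, seg: SegmentProperties) -> np.ndarray:
    """Total mechanical energy (kinetic + elastic potentials) over time [J].

    Gravity is excluded; with zero activations and horizontal-plane gravity
    this quantity is non-increasing because the only non-conservative terms
    are the joint and fiber viscous dampers.
    """
    ke = 0.5 * seg.effective_inertia * result.q_dot**2
    vp = (joint.k1 / joint.k2) * np.exp(-joint.k2 * (result.q - joint.q2)) \
        + (joint.k4 / joint.k5) * np.exp(-joint.k5 * (joint.q1 - result.q))
    e = ke + vp
    for muscle in result.muscle_states.values():
        e = e + 0.5 * hill_params.Mm * muscle["vm"] ** 2
        e = e + hill.parallel_elastic_energy(muscle["lm"], hill_params)
        e = e + hill.tendon_energy(muscle["lt"], hill_params)
    return e
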