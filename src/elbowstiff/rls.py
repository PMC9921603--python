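"""Recursive least-squares joint-stiffness estimation.

Joint torque is modelled as a polynomial in the joint angle,
``tau = Phi(q) . Pi`` with regressor ``Phi = (1, q, q^2)`` (three terms by
default; a cubic regressor is available).  The coefficient vector Pi is
tracked sample-by-sample with the classic covariance-form RLS recursion
initialized at ``Pi = 0`` and ``P = 0.01*I``.

Stiffness is reported, per sample, as the negative torque gradient with
respect to angle, ``-(pi2 + 2*pi3*q)`` [N·m/rad], so a restoring torque yields
positive stiffness.  A ``paper_literal`` mode returning ``-Phi.Pi`` (the
negated torque reconstruction) is kept behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, ParameterError

__all__ = [
    "RLSState",
    "StiffnessTrace",
    "torque_regressor",
    "rls_step",
    "stiffness_at",
    "estimate_trace",
]


@dataclass
class RLSState:
    """Coefficients, covariance and step counter of the RLS recursion."""

    Pi: np.ndarray
    P: np.ndarray
    k: int = 0

    @classmethod
    def initial(cls, n_terms: int = 3, p0: float = 0.01) -> "RLSState":
        if n_terms < 1:
            raise ParameterError("regressor needs at least one term")
        if p0 <= 0:
            raise ParameterError("initial covariance scale p0 must be > 0")
        return cls(Pi=np.zeros(n_terms), P=p0 * np.eye(n_terms), k=0)


@dataclass
class StiffnessTrace:
    """RLS stiffness estimate over time, with the coefficient history."""

    time: np.ndarray
    stiffness: np.ndarray       # N·m/rad
    Pi_history: np.ndarray      # (n, n_terms)
    mode: str = "derivative"

    def __len__(self) -> int:
        return len(self.time)


def torque_regressor(q, n_terms: int = 3):
    """Polynomial regressor ``(1, q, q^2, ...)`` of the joint angle."""
    q = np.asarray(q, dtype=float)
    powers = np.arange(n_terms)
    if q.ndim == 0:
        return q ** powers
    return q[..., None] ** powers


def rls_step(state: RLSState, tau: float, phi: np.ndarray) -> RLSState:
    """One covariance-form RLS update with the (tau, phi) sample.

    epsilon = tau - phi.Pi ; rho = phi' P phi ; G = P phi / (1 + rho);
    Pi <- Pi + G epsilon ; P <- P - G phi' P (symmetrized).
    """
    phi = np.asarray(phi, dtype=float)
    if not np.isfinite(tau) or np.any(~np.isfinite(phi)):
        raise DataError("non-finite torque or regressor sample")
    eps = tau - phi @ state.Pi
    Pphi = state.P @ phi
    rho = phi @ Pphi
    G = Pphi / (1.0 + rho)
    Pi = state.Pi + G * eps
    P = state.P - np.outer(G, Pphi)
    P = 0.5 * (P + P.T)
    return RLSState(Pi=Pi, P=P, k=state.k + 1)


def stiffness_at(q, Pi: np.ndarray, mode: str = "derivative"):
    """Stiffness from the current coefficients at angle(s) ``q``.

    ``derivative``: ``-d(Phi.Pi)/dq`` (N·m/rad); ``paper_literal``:
    ``-Phi.Pi`` (the negated torque reconstruction, N·m).
    """
    q = np.asarray(q, dtype=float)
    Pi = np.asarray(Pi, dtype=float)
    if mode == "derivative":
        powers = np.arange(1, len(Pi))
        out = -(Pi[1:] * powers * q[..., None] ** (powers - 1)).sum(axis=-1)
    elif mode == "paper_literal":
        out = -(Pi * q[..., None] ** np.arange(len(Pi))).sum(axis=-1)
    else:
        raise ParameterError(f"unknown stiffness mode {mode!r}")
    return out if out.ndim else float(out)


def estimate_trace(tau_J, q, time, *, n_terms: int = 3, p0: float = 0.01,
                   forgetting: float = 1.0, mode: str = "derivative") -> StiffnessTrace:
    """Run the RLS recursion over a torque/angle record and extract stiffness.

    ``forgetting`` < 1 enables an exponential-forgetting variant; the default
    1.0 is the plain recursion.
    """
    tau_J = np.asarray(tau_J, dtype=float)
    q = np.asarray(q, dtype=float)
    time = np.asarray(time, dtype=float)
    if not (len(tau_J) == len(q) == len(time)):
        raise DataError("tau_J, q and time must have equal length")
    if not 0 < forgetting <= 1:
        raise ParameterError("forgetting factor must lie in (0, 1]")
    n = len(q)
    Pi = np.zeros(n_terms)
    P = p0 * np.eye(n_terms)
    history = np.empty((n, n_terms))
    stiff = np.empty(n)
    lam = forgetting
    for k in range(n):
        phi = q[k] ** np.arange(n_terms)
        if not np.isfinite(tau_J[k]) or not np.isfinite(q[k]):
            raise DataError(f"non-finite sample at index {k}")
        Pphi = P @ phi
        rho = phi @ Pphi
        G = Pphi / (lam + rho)
        Pi = Pi + G * (tau_J[k] - phi @ Pi)
        P = (P - np.outer(G, Pphi)) / lam
        P = 0.5 * (P + P.T)
        history[k] = Pi
        stiff[k] = stiffness_at(q[k], Pi, mode)
    return StiffnessTrace(time=time, stiffness=stiff, Pi_history=history, mode=mode)
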