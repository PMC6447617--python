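"""Mean-field dynamics of the cooperative voter model.

In the infinite-community limit the relative abundances eta(t) on the
(S-1)-simplex obey

    d eta_s / dt = g_s(eta) - eta_s * sum_i g_i(eta)

with the per-species gain

    g_s = eps1 * sum_k eta_k M_ks * theta(eta_s)
        + eps2 * sum_k eta_k L_ks * eta_s
        + eps3 * sum_k eta_k H_ks * theta(eta_s)

where theta(x) = 1 for x > 0 and 0 otherwise: an extinct species receives no
mediated boost and extinction is absorbing.  The total abundance is conserved
(the rhs components sum to zero identically).

For pure cooperation (eps2 = eps3 = 0) on an irreducible M the dynamics are
solvable: the normalized matrix-exponential flow

    eta(t) = eta(0)^T exp(eps1 * M * t) / sum_s (...)_s

is the exact interior solution — differentiating the quotient reproduces both
the gain term and the fully summed loss term — and converges to the
Perron–Frobenius stationary state m = v / sum(v), with v the strictly
positive left eigenvector of M at the leading eigenvalue alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .networks import CommunityInteractions, is_irreducible, validate_cooperation

__all__ = [
    "AbundanceError",
    "IrreducibilityError",
    "StationarySolution",
    "MeanFieldTrajectory",
    "rhs",
    "integrate",
    "pf_stationary",
    "time_solution_pure_cooperation",
    "classify",
]

#: abundances below this are clamped to exactly zero so the theta gate
#: switches off as in the exact model
EXTINCTION_FLOOR = 1e-14


class AbundanceError(ValueError):
    """Initial or intermediate state off the abundance simplex."""


class IrreducibilityError(ValueError):
    """M is reducible; prune unsupported species before applying PF theory."""


def _check_simplex(eta: np.ndarray, S: int, tol: float = 1e-6) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (S,):
        raise AbundanceError(f"state must have shape ({S},), got {eta.shape}")
    if np.any(eta < -tol) or abs(eta.sum() - 1.0) > tol:
        raise AbundanceError(
            f"state must lie on the simplex (sum={eta.sum():.3g}, min={eta.min():.3g})"
        )
    return eta


def _gains(eta: np.ndarray, inter: CommunityInteractions) -> np.ndarray:
    theta = (eta > 0.0).astype(float)
    g = np.zeros_like(eta)
    if inter.eps1:
        g += inter.eps1 * (inter.M.T @ eta) * theta
    if inter.eps2:
        g += inter.eps2 * (inter.L.T @ eta) * eta
    if inter.eps3:
        g += inter.eps3 * (inter.H.T @ eta) * theta
    return g


def rhs(eta: np.ndarray, inter: CommunityInteractions) -> np.ndarray:
    """Mean-field time derivative; components sum to zero exactly."""
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (inter.S,):
        raise AbundanceError(f"state must have shape ({inter.S},), got {eta.shape}")
    g = _gains(eta, inter)
    return g - eta * g.sum()


@dataclass
class StationarySolution:
    """A stationary point of the mean-field dynamics.

    ``method`` is ``"analytic"`` (Perron–Frobenius eigenvector) or
    ``"integrated"`` (long-time ODE limit); ``residual`` is the sup-norm of
    the rhs at ``m``; ``converged`` is False when integration hit its time
    horizon before stationarity.
    """

    m: np.ndarray
    method: str
    residual: float
    converged: bool = True
    pf_alpha: float | None = None
    v: np.ndarray | None = None
    w: np.ndarray | None = None

    @property
    def S(self) -> int:
        return self.m.size

    def survivors(self, threshold: float | None = None) -> np.ndarray:
        thr = 1.0 / self.S**2 if threshold is None else threshold
        return np.flatnonzero(self.m >= thr)

    def to_dict(self) -> dict:
        """JSON-serializable summary (m, survivors, alpha, residual, flags)."""
        return {
            "m": self.m.tolist(),
            "survivors": self.survivors().tolist(),
            "method": self.method,
            "residual": self.residual,
            "converged": self.converged,
            "pf_alpha": self.pf_alpha,
        }


@dataclass
class MeanFieldTrajectory:
    t: np.ndarray
    eta: np.ndarray  # shape (len(t), S)
    clamping_events: list[tuple[float, list[int]]] = field(default_factory=list)


def integrate(
    initial: np.ndarray,
    inter: CommunityInteractions,
    t_max: float = 500.0,
    *,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    stat_tol: float = 1e-10,
    t_eval: np.ndarray | None = None,
    method: str = "LSODA",
    chunk: float = 25.0,
) -> tuple[MeanFieldTrajectory, StationarySolution]:
    """Integrate the mean field to stationarity (or ``t_max``).

    The theta gate makes the rhs piecewise smooth, so integration restarts
    whenever a species hits the extinction floor: the species is clamped to
    exactly zero (extinction is absorbing), the state renormalized, and the
    event logged.  Stationarity is declared once ``||rhs||_inf < stat_tol``
    at two consecutive chunk boundaries.
    """
    y = _check_simplex(np.asarray(initial, dtype=float).copy(), inter.S)
    y[y < EXTINCTION_FLOOR] = 0.0
    y /= y.sum()

    def f(t, y):
        return rhs(y, inter)

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    clamps: list[tuple[float, list[int]]] = []
    t = 0.0
    calm = 0
    record = t_eval is not None
    if record:
        t_eval = np.asarray(t_eval, dtype=float)
        ts.append(np.array([0.0]))
        ys.append(y[np.newaxis].copy())

    while t < t_max:
        alive = y > 0.0

        def hit_floor(tt, yy, alive=alive):
            vals = yy[alive]
            return (vals.min() - EXTINCTION_FLOOR) if vals.size else 1.0

        hit_floor.terminal = True
        hit_floor.direction = -1.0
        t_end = min(t + chunk, t_max)
        eval_pts = None
        if record:
            eval_pts = t_eval[(t_eval > t) & (t_eval <= t_end)]
            if eval_pts.size == 0:
                eval_pts = None
        sol = solve_ivp(
            f, (t, t_end), y, method=method, rtol=rtol, atol=atol,
            events=[hit_floor], t_eval=eval_pts, dense_output=False,
        )
        if not sol.success:  # pragma: no cover - integrator failure
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        if record and sol.t.size:
            ts.append(sol.t)
            ys.append(sol.y.T)
        t = sol.t[-1] if sol.t.size else t_end
        y = sol.y[:, -1].copy() if sol.t.size else y
        if sol.status == 1:  # species hit the extinction floor
            t = float(sol.t_events[0][0])
            y = sol.y_events[0][0].copy()
            # the event root is only accurate to the solver's tolerance, so
            # clamp within a safety band; the triggering species (arg-min of
            # the alive set) is clamped unconditionally
            dying = (y <= 10.0 * EXTINCTION_FLOOR) & alive
            if not dying.any():
                live_idx = np.flatnonzero(alive)
                dying[live_idx[np.argmin(y[live_idx])]] = True
            dead = np.flatnonzero(dying)
            y[dying | (y < 0)] = 0.0
            total = y.sum()
            if total <= 0:
                raise AbundanceError("all species extinct during integration")
            y /= total
            clamps.append((t, [int(i) for i in dead]))
            calm = 0
            continue
        res = float(np.max(np.abs(rhs(y, inter))))
        calm = calm + 1 if res < stat_tol else 0
        if calm >= 2:
            break

    res = float(np.max(np.abs(rhs(y, inter))))
    traj = MeanFieldTrajectory(
        t=np.concatenate(ts) if ts else np.array([t]),
        eta=np.vstack(ys) if ys else y[np.newaxis].copy(),
        clamping_events=clamps,
    )
    sol_out = StationarySolution(
        m=y, method="integrated", residual=res, converged=res < max(stat_tol, 1e-9)
    )
    return traj, sol_out


def pf_stationary(M: np.ndarray, eps1: float = 1.0) -> StationarySolution:
    """Perron–Frobenius stationary state of the pure-cooperation model.

    For irreducible M the leading eigenvalue ``alpha`` is real, positive and
    non-degenerate, its left eigenvector v and right eigenvector w are
    strictly positive, and the unique interior stationary state is
    ``m = v / sum(v)`` — independent of ``eps1 > 0``, which only sets the
    relaxation time scale.  v is normalized to sum 1 and w scaled so
    ``v . w = 1`` (w quantifies how press perturbations spread).
    """
    M = validate_cooperation(M)
    if eps1 <= 0:
        raise ValueError("eps1 must be positive")
    if not is_irreducible(M):
        raise IrreducibilityError(
            "M is reducible; run prune_unsupported and restrict to the "
            "surviving sub-community before applying Perron-Frobenius theory"
        )

    def _leading(A: np.ndarray) -> tuple[float, np.ndarray]:
        vals, vecs = np.linalg.eig(A)
        k = int(np.argmax(vals.real))
        lam, vec = vals[k], vecs[:, k]
        if abs(lam.imag) > 1e-9 * max(1.0, abs(lam.real)):
            raise IrreducibilityError("leading eigenvalue is not real")
        vec = vec.real
        if vec.sum() < 0:
            vec = -vec
        if np.any(vec <= 0):
            raise IrreducibilityError("leading eigenvector is not strictly positive")
        return float(lam.real), vec

    alpha, v = _leading(M.T)
    alpha_r, w = _leading(M)
    if abs(alpha - alpha_r) > 1e-8 * max(1.0, abs(alpha)):  # pragma: no cover
        raise RuntimeError("left/right leading eigenvalues disagree")
    v = v / v.sum()
    w = w / (v @ w)
    m = v.copy()
    inter = CommunityInteractions(
        M, np.zeros_like(M), np.zeros_like(M), eps1, 0.0, 0.0, validate=False
    )
    residual = float(np.max(np.abs(rhs(m, inter))))
    return StationarySolution(
        m=m, method="analytic", residual=residual, converged=True,
        pf_alpha=alpha, v=v, w=w,
    )


def time_solution_pure_cooperation(
    M: np.ndarray, eps1: float, initial: np.ndarray, t: float
) -> np.ndarray:
    """Closed-form abundance at time t for pure cooperation.

    ``eta(t) = eta(0)^T exp(eps1 M t) / sum_s(eta(0)^T exp(eps1 M t))_s``,
    the exact interior solution of the mean field when eps2 = eps3 = 0.
    """
    M = validate_cooperation(M)
    eta0 = _check_simplex(np.asarray(initial, dtype=float), M.shape[0])
    if np.any(eta0 <= 0):
        raise AbundanceError("closed form requires a strictly positive start")
    y = expm(eps1 * M.T * t) @ eta0
    return y / y.sum()


def classify(
    solution: StationarySolution, S: int | None = None
) -> tuple[bool, np.ndarray, float]:
    """Feasibility and extinction accounting of a stationary state.

    A species is extinct when its abundance is strictly below the threshold
    ``1 / S**2`` (ties count as survival); the state is feasible iff no
    species is extinct.  Returns ``(feasible, extinct_indices,
    fraction_extinct)``.
    """
    S = solution.S if S is None else S
    thr = 1.0 / S**2
    extinct = np.flatnonzero(solution.m < thr)
    return extinct.size == 0, extinct, extinct.size / S
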