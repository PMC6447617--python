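"""Linear-noise (Ornstein–Uhlenbeck) fluctuation theory around equilibria.

The sqrt(N)-scaled deviations x(t) = sqrt(N) (eta(t) - m) converge, as N
grows, to a Gaussian process solving dX = A X dt + Phi dB_t.  The drift A is
the mean-field Jacobian at m.  The diffusion D = Phi Phi^T follows from the
second jump moments of the replacement process: an event (die a, born b)
occurs at rate N * omega_b * eta_a and jumps eta by (e_b - e_a)/N, giving
the closed form

    D_ij = delta_ij * (omega_i + m_i * sum_k omega_k)
           - (omega_i * m_j + omega_j * m_i)

with the rates omega evaluated at m.  Rows of D sum to zero (jumps conserve
the total abundance), so the fluctuations live entirely in the sum-zero
tangent subspace — which is invariant under A — and the stationary
covariance V solves the Lyapunov equation ``A V + V A^T + D = 0``
restricted to that subspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov
from scipy.stats import spearmanr

from .meanfield import rhs
from .networks import CommunityInteractions
from .stability import jacobian, tangent_basis

__all__ = [
    "OUModel",
    "build_ou",
    "diffusion_event_sum",
    "stationary_covariance",
    "empirical_covariance",
    "proxy_comparison",
]

#: an OU model is only built at points where the rhs is this small
EQUILIBRIUM_TOL = 1e-7


@dataclass
class OUModel:
    """Drift A, diffusion D = Phi Phi^T and reference equilibrium m."""

    A: np.ndarray
    D: np.ndarray
    m: np.ndarray


def _rates_at(m: np.ndarray, inter: CommunityInteractions) -> np.ndarray:
    theta = (m > 0.0).astype(float)
    return m + (
        inter.eps1 * (inter.M.T @ m) + inter.eps3 * (inter.H.T @ m)
    ) * theta + inter.eps2 * (inter.L.T @ m) * m


def build_ou(inter: CommunityInteractions, m: np.ndarray) -> OUModel:
    """OU model of the fluctuations around a positive equilibrium m."""
    m = np.asarray(m, dtype=float)
    res = float(np.max(np.abs(rhs(m, inter))))
    if res > EQUILIBRIUM_TOL:
        raise ValueError(
            f"m is not an equilibrium (||rhs||_inf = {res:.3g} > {EQUILIBRIUM_TOL})"
        )
    A = jacobian(inter, m)
    w = _rates_at(m, inter)
    D = np.diag(w + m * w.sum()) - (np.outer(w, m) + np.outer(m, w))
    return OUModel(A=A, D=D, m=m)


def diffusion_event_sum(inter: CommunityInteractions, m: np.ndarray) -> np.ndarray:
    """Brute-force diffusion matrix: explicit sum over all S^2 elementary
    (die a, born b) events with rate ``N omega_b eta_a`` and x-jump
    ``(e_b - e_a)/sqrt(N)``.  Independent oracle for :func:`build_ou`."""
    m = np.asarray(m, dtype=float)
    S = m.size
    w = _rates_at(m, inter)
    D = np.zeros((S, S))
    for a in range(S):
        for b in range(S):
            rate = w[b] * m[a]
            jump = np.zeros(S)
            jump[b] += 1.0
            jump[a] -= 1.0
            D += rate * np.outer(jump, jump)
    return D


def stationary_covariance(model: OUModel, *, rtol: float = 1e-8) -> np.ndarray:
    """Stationary covariance V of the OU process on the tangent subspace.

    The fluctuations are confined to the sum-zero subspace (the diffusion is
    degenerate along the simplex normal), so A and D are projected onto an
    orthonormal sum-zero basis, the Lyapunov equation is solved there, and V
    is mapped back to S x S coordinates.  Raises if A is not stable on the
    tangent subspace (no stationary law exists).
    """
    S = model.A.shape[0]
    U = tangent_basis(S)
    At = U.T @ model.A @ U
    Dt = U.T @ model.D @ U
    lam = np.linalg.eigvals(At)
    if lam.real.max() >= 0:
        raise ValueError(
            "drift is not stable on the tangent subspace "
            f"(max Re = {lam.real.max():.3g}); no stationary covariance"
        )
    Vt = solve_continuous_lyapunov(At, -Dt)
    Vt = 0.5 * (Vt + Vt.T)
    resid = np.linalg.norm(At @ Vt + Vt @ At.T + Dt)
    scale = max(np.linalg.norm(Dt), 1.0)
    if resid > rtol * scale:  # pragma: no cover - solver failure
        raise RuntimeError(f"Lyapunov residual {resid:.3g} exceeds tolerance")
    return U @ Vt @ U.T


def empirical_covariance(
    trajectories: list[np.ndarray], burn_in: float = 0.2
) -> np.ndarray:
    """Pooled covariance of fluctuation samples across replicate
    trajectories, discarding an initial ``burn_in`` fraction of each."""
    rows = []
    for x in trajectories:
        k = int(burn_in * len(x))
        rows.append(x[k:])
    X = np.vstack(rows)
    return np.cov(X, rowvar=False, bias=True)


def proxy_comparison(
    V: np.ndarray,
    inter: CommunityInteractions,
    *,
    thresholds: np.ndarray | None = None,
) -> dict:
    """How well V (and its tangent pseudo-inverse) proxy the interactions.

    Computes Spearman rank correlations between the off-diagonal entries of
    each candidate proxy {V, pinv(V)} and of the direct interaction matrix
    M + L, plus binary edge-recovery precision/recall over a sweep of
    |proxy| thresholds.  The comparison is diagnostic: covariances are
    generically *not* faithful proxies of the interaction network.
    """
    V = np.asarray(V, dtype=float)
    S = V.shape[0]
    target = inter.M + inter.L
    off = ~np.eye(S, dtype=bool)
    true_edges = target[off] != 0

    U = tangent_basis(S)
    Vt = U.T @ V @ U
    cond = float(np.linalg.cond(Vt))
    Vinv = U @ np.linalg.pinv(Vt) @ U.T

    report: dict = {"condition_number": cond, "proxies": {}}
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 11)[1:-1]
    for name, P in (("V", V), ("V_inv", Vinv)):
        p_off, t_off = P[off], target[off]
        if np.std(p_off) == 0 or np.std(t_off) == 0:
            entry = {"spearman": None, "degenerate": True}
        else:
            r = spearmanr(p_off, t_off)
            entry = {"spearman": float(r.statistic), "degenerate": False}
        absp = np.abs(p_off)
        span = absp.max()
        pr = []
        for q in thresholds:
            pred = absp > q * span if span > 0 else np.zeros_like(absp, bool)
            tp = int(np.sum(pred & true_edges))
            fp = int(np.sum(pred & ~true_edges))
            fn = int(np.sum(~pred & true_edges))
            pr.append(
                {
                    "threshold": float(q),
                    "precision": tp / (tp + fp) if tp + fp else None,
                    "recall": tp / (tp + fn) if tp + fn else None,
                }
            )
        entry["precision_recall"] = pr
        report["proxies"][name] = entry
    return report
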