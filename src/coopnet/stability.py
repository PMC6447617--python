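"""Linear stability of mean-field equilibria and its random-matrix theory.

The Jacobian of the mean field at an interior equilibrium m is computed
exactly (it reproduces the printed cooperative/exploitative structure; harm
enters with the same linear, theta-gated form as cooperation).  Because the
total abundance is conserved, the sum-zero tangent subspace is invariant
under the Jacobian (every column sums to the same value -G, the negative
total gain), so the spectrum splits into S - 1 tangent eigenvalues plus one
structural mode tied to the simplex normal; stability is assessed on the
tangent subspace only.

For a random cooperative ensemble with effective off-diagonal moments
(mu_M, sigma_M, rho_M) the leading order of the Jacobian is

    J_ij = -delta_ij * S * mu_M + (M_ij - mu_M)

whose spectrum fills an ellipse centered at ``-S mu_M`` with semi-axes
``sqrt(S) sigma_M (1 +/- rho_M)``; the predicted largest eigenvalue is
``-S mu_M + sqrt(S) sigma_M (1 + rho_M)``.  The ellipse center recedes
linearly in S while its radius grows only as sqrt(S): with mediated
cooperation, stability *increases* with diversity, inverting the classical
complexity–stability bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import CommunityInteractions, MatrixStats

__all__ = [
    "jacobian",
    "formal_jacobian",
    "boundary_jacobian",
    "leading_order_jacobian",
    "pf_condition",
    "tangent_basis",
    "tangent_eigenvalues",
    "SpectrumSummary",
    "spectrum",
    "is_stable",
]

#: eigenvalue real parts above this are treated as unstable
STABILITY_TOL = -1e-10


def jacobian(inter: CommunityInteractions, m: np.ndarray) -> np.ndarray:
    """Exact Jacobian of the mean-field rhs at an interior equilibrium m.

    With g the gain vector and G = sum(g), the derivative of
    ``rhs_s = g_s - m_s G`` is

        J_sj = eps1 M_js + eps3 H_js
             + eps2 (delta_sj (L^T m)_s + m_s L_js)
             - delta_sj G - m_s dG/dm_j

    valid when every ``m_s > 0`` (the theta gates are constant there).
    Equilibria with extinct species go through :func:`boundary_jacobian`.
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError(
            "jacobian requires a strictly positive equilibrium; use "
            "formal_jacobian or boundary_jacobian for states with extinct "
            "species"
        )
    return formal_jacobian(inter, m)


def formal_jacobian(inter: CommunityInteractions, m: np.ndarray) -> np.ndarray:
    """Jacobian of the mean field with the theta gates held at 1.

    At a strictly positive state this *is* the exact Jacobian.  At a
    boundary state (extinct species present) the step gates are not
    differentiable; holding them at 1 linearizes the smooth vector field the
    community would follow if every species were nominally present, so the
    spectrum additionally probes whether extinct species would re-invade —
    a boundary state that passes this test is robust to rare reintroduction.
    """
    m = np.asarray(m, dtype=float)
    S = inter.S
    if m.shape != (S,):
        raise ValueError(f"m must have shape ({S},), got {m.shape}")
    e1, e2, e3 = inter.eps1, inter.eps2, inter.eps3
    M, L, H = inter.M, inter.L, inter.H
    Lt_m = L.T @ m
    g = e1 * (M.T @ m) + e2 * Lt_m * m + e3 * (H.T @ m)
    G = g.sum()
    # dG/dm_j = eps1 * rowsum(M)_j + eps2 * ((L^T m)_j + (L m)_j) + eps3 * rowsum(H)_j
    dG = e1 * M.sum(axis=1) + e2 * (Lt_m + L @ m) + e3 * H.sum(axis=1)
    J = e1 * M.T + e3 * H.T + e2 * (np.diag(Lt_m) + m[:, None] * L.T)
    J -= G * np.eye(S)
    J -= np.outer(m, dG)
    return J


def boundary_jacobian(
    inter: CommunityInteractions, m: np.ndarray, threshold: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stability data at a boundary equilibrium (some species extinct).

    Returns ``(J_sub, survivors, invasion_rates)``: the Jacobian of the
    surviving sub-community, the surviving indices, and for each extinct
    species its transversal re-invasion growth rate — the per-capita rate
    ``g_s/eta_s |_{eta_s -> 0+}`` it would experience if reintroduced at
    vanishing abundance (theta switched back on for the invader).
    """
    m = np.asarray(m, dtype=float)
    alive = np.flatnonzero(m > threshold)
    dead = np.flatnonzero(m <= threshold)
    sub = inter.restrict(alive)
    m_sub = m[alive] / m[alive].sum()
    J_sub = jacobian(sub, m_sub)
    # invader s at eta_s -> 0+: d eta_s/dt -> eps1 (M^T m)_s + eps3 (H^T m)_s
    # (the loss term -eta_s * G and the exploitation term vanish with eta_s)
    invasion = (
        inter.eps1 * (inter.M.T @ m)[dead]
        + inter.eps3 * (inter.H.T @ m)[dead]
    )
    return J_sub, alive, invasion


def leading_order_jacobian(
    M: np.ndarray, stats: MatrixStats, S: int | None = None
) -> np.ndarray:
    """Leading-order random-matrix Jacobian ``-S mu_M I + (M - mu_M 1 1^T)``.

    The centered perturbation ``M' = M - mu_M`` has zero-mean off-diagonal
    entries with variance ``sigma_M**2`` and pair correlation ``rho_M``.
    """
    M = np.asarray(M, dtype=float)
    S = M.shape[0] if S is None else S
    return -S * stats.mu * np.eye(S) + (M - stats.mu)


def pf_condition(stats: MatrixStats, S: int) -> bool:
    """True when ``mu_M >= sigma_M * sqrt((1 + rho_M) / S)``: the mean
    dominates the bulk and the leading eigenvalue of M is ``S mu_M`` with a
    positive, nearly uniform eigenvector."""
    return bool(stats.mu >= stats.sigma * np.sqrt((1.0 + stats.rho) / S))


def tangent_basis(S: int) -> np.ndarray:
    """Orthonormal basis (S x (S-1)) of the sum-zero tangent subspace."""
    A = np.eye(S) - np.full((S, S), 1.0 / S)
    # QR of the centering projector: first S-1 columns span the tangent space
    q, r = np.linalg.qr(A)
    return q[:, : S - 1]


def tangent_eigenvalues(J: np.ndarray) -> np.ndarray:
    """Eigenvalues of J restricted to the sum-zero subspace (the structural
    conservation mode along the simplex normal is projected out)."""
    J = np.asarray(J, dtype=float)
    U = tangent_basis(J.shape[0])
    return np.linalg.eigvals(U.T @ J @ U)


@dataclass
class SpectrumSummary:
    """Jacobian spectrum plus the random-matrix ellipse prediction."""

    eigenvalues: np.ndarray
    max_real: float
    center: float | None = None
    semi_axis_re: float | None = None
    semi_axis_im: float | None = None
    lambda_M: float | None = None

    @property
    def predicted_max_real(self) -> float | None:
        if self.center is None:
            return None
        return self.center + self.semi_axis_re

    def inside_ellipse(self, inflate: float = 1.05) -> float:
        """Fraction of eigenvalues inside the (inflated) predicted ellipse."""
        if self.center is None:
            raise ValueError("no ellipse prediction attached")
        a = max(self.semi_axis_re, 1e-300) * inflate
        b = max(self.semi_axis_im, 1e-300) * inflate
        lam = self.eigenvalues
        q = ((lam.real - self.center) / a) ** 2 + (lam.imag / b) ** 2
        return float(np.mean(q <= 1.0))


def spectrum(
    J: np.ndarray,
    stats: MatrixStats | None = None,
    *,
    eps1: float = 1.0,
    project: bool = True,
) -> SpectrumSummary:
    """Eigenvalues of a Jacobian with optional ellipse prediction.

    With ``project=True`` (default) the spectrum is taken on the sum-zero
    tangent subspace.  When ensemble ``stats`` are supplied, the prediction
    is the ellipse centered at ``-eps1 S mu_M`` with semi-axes
    ``eps1 sqrt(S) sigma_M (1 +/- rho_M)`` and ``lambda_M = S mu_M``.
    """
    J = np.asarray(J, dtype=float)
    S = J.shape[0]
    lam = tangent_eigenvalues(J) if project else np.linalg.eigvals(J)
    out = SpectrumSummary(eigenvalues=lam, max_real=float(lam.real.max()))
    if stats is not None:
        out.center = -eps1 * S * stats.mu
        out.semi_axis_re = eps1 * np.sqrt(S) * stats.sigma * (1.0 + stats.rho)
        out.semi_axis_im = eps1 * np.sqrt(S) * stats.sigma * (1.0 - stats.rho)
        out.lambda_M = S * stats.mu
    return out


def is_stable(J: np.ndarray) -> bool:
    """True iff the max real part on the tangent subspace is < -1e-10."""
    return float(tangent_eigenvalues(J).real.max()) < STABILITY_TOL
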