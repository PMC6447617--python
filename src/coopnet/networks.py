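"""Interaction networks of a cooperative ecological community.

A community of S species interacts through three directed weighted networks:

* ``M`` — mediated cooperation (+ +, + 0): ``M[i, j] >= 0`` means species j
  receives a benefit (habitat modification, secreted metabolites) proportional
  to the abundance of species i.
* ``L`` — exploitation (+ -): predator–prey pairs with antisymmetric signs,
  ``L[i, j] * L[j, i] < 0`` or both zero.
* ``H`` — harm (- 0): one-directional negative effects (e.g. antibiotics),
  ``H[i, j] < 0`` with the opposite direction zero.

Each unordered pair of species carries at most one interaction type
(``M[i, j] * L[i, j] * H[i, j] = 0`` pairwise-disjoint supports).

This module represents, validates, randomly generates, transforms and
serializes these matrices, and computes the effective first/second moments of
random ensembles (connectivity-diluted mean, standard deviation and pairwise
correlation) used by the stability theory.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "EnsembleSpec",
    "CommunityInteractions",
    "MatrixStats",
    "ConstraintViolation",
    "validate_cooperation",
    "validate_exploitation",
    "validate_harm",
    "sample_cooperation",
    "sample_exploitation",
    "sample_harm",
    "sample_community",
    "effective_stats",
    "is_irreducible",
    "prune_unsupported",
    "constant_effort_normalize",
    "read_edgelist",
    "write_edgelist",
    "read_adjacency",
    "write_adjacency",
]

FAMILIES = ("abs-normal", "gamma", "lognormal", "uniform", "constant")


class ConstraintViolation(ValueError):
    """An interaction matrix violates its structural conditions."""


# ---------------------------------------------------------------------------
# Ensemble specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSpec:
    """Random-ensemble specification for the interaction matrices.

    Parameters
    ----------
    S:
        Number of species (>= 1).
    c_M, c_L, c_H:
        Connectivities: the probability that an unordered species pair carries
        a cooperative / exploitative / harmful interaction.  Pair classes are
        mutually exclusive, so ``c_M + c_L + c_H <= 1``.
    family:
        Base entry distribution for interaction magnitudes: ``abs-normal``
        (modulus of a Normal), ``gamma``, ``lognormal``, ``uniform`` or
        ``constant``.
    dist_params:
        ``(alpha, beta)`` with family-specific meaning: Normal (mean, sd),
        Gamma (shape, scale), LogNormal (log-mean, log-sd), Uniform (low,
        high), Constant (value, ignored).
    rho:
        Target correlation between the two directed entries of a connected
        cooperative pair, in [-1, 1].
    seed:
        Seed for the generator used when no explicit RNG is passed.
    """

    S: int
    c_M: float = 0.0
    c_L: float = 0.0
    c_H: float = 0.0
    family: str = "abs-normal"
    dist_params: tuple[float, float] = (1.0, 0.0)
    rho: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError(f"S must be >= 1, got {self.S}")
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        for name in ("c_M", "c_L", "c_H"):
            c = getattr(self, name)
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {c}")
        if self.c_M + self.c_L + self.c_H > 1.0 + 1e-12:
            raise ValueError(
                "c_M + c_L + c_H must not exceed 1: interaction classes have "
                f"disjoint pair supports (got sum {self.c_M + self.c_L + self.c_H})"
            )
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")

    # -- base-distribution moments -------------------------------------------

    def _frozen(self):
        a, b = self.dist_params
        if self.family == "abs-normal":
            if b < 0:
                raise ValueError("abs-normal sd must be >= 0")
            if b == 0:
                return None  # degenerate: point mass at |a|
            return sps.foldnorm(c=abs(a) / b, scale=b)
        if self.family == "gamma":
            return sps.gamma(a, scale=b)
        if self.family == "lognormal":
            return sps.lognorm(s=b, scale=np.exp(a))
        if self.family == "uniform":
            return sps.uniform(loc=a, scale=b - a)
        return None  # constant

    @property
    def mu(self) -> float:
        """Mean of the base magnitude distribution."""
        dist = self._frozen()
        if dist is None:
            return abs(self.dist_params[0])
        return float(dist.mean())

    @property
    def sigma(self) -> float:
        """Standard deviation of the base magnitude distribution."""
        dist = self._frozen()
        if dist is None:
            return 0.0
        return float(dist.std())

    def rng(self, rng: np.random.Generator | None = None) -> np.random.Generator:
        return rng if rng is not None else np.random.default_rng(self.seed)


def _sample_magnitude_pairs(
    spec: EnsembleSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` correlated nonnegative magnitude pairs, shape (n, 2).

    The abs-normal family draws a bivariate Normal with correlation ``rho``
    and takes the modulus; the other families obtain correlation through a
    Gaussian copula, which preserves the marginal distribution exactly.
    """
    if n == 0:
        return np.empty((0, 2))
    rho = spec.rho
    z = rng.standard_normal((n, 2))
    if rho != 0.0:
        z[:, 1] = rho * z[:, 0] + np.sqrt(1.0 - rho**2) * z[:, 1]
    a, b = spec.dist_params
    if spec.family == "abs-normal":
        return np.abs(a + b * z)
    if spec.family == "constant":
        return np.full((n, 2), abs(a))
    u = sps.norm.cdf(z)
    dist = spec._frozen()
    return dist.ppf(u)


def _pair_indices(S: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(S, k=1)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_square(Q: np.ndarray, name: str) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ConstraintViolation(f"{name} must be square, got shape {Q.shape}")
    return Q


def validate_cooperation(M: np.ndarray) -> np.ndarray:
    """Check condition (i): all entries nonnegative."""
    M = _check_square(M, "M")
    if np.any(M < 0):
        bad = np.argwhere(M < 0)[:10]
        raise ConstraintViolation(f"M has negative entries at {bad.tolist()}")
    return M


def validate_exploitation(L: np.ndarray) -> np.ndarray:
    """Check condition (ii): L_ij * L_ji < 0 or both zero; zero diagonal."""
    L = _check_square(L, "L")
    if np.any(np.diag(L) != 0):
        raise ConstraintViolation("L must have a zero diagonal")
    prod = L * L.T
    iu = np.triu_indices(L.shape[0], k=1)
    bad_sign = prod[iu] > 0
    half = (prod[iu] == 0) & ((L[iu] != 0) | (L.T[iu] != 0))
    if np.any(bad_sign | half):
        idx = np.argwhere(bad_sign | half).ravel()[:10]
        pairs = [(int(iu[0][k]), int(iu[1][k])) for k in idx]
        raise ConstraintViolation(
            f"L pairs must satisfy L_ij*L_ji < 0 or both zero; violated at {pairs}"
        )
    return L


def validate_harm(H: np.ndarray) -> np.ndarray:
    """Check condition (iii): entries <= 0, at most one direction per pair."""
    H = _check_square(H, "H")
    if np.any(np.diag(H) != 0):
        raise ConstraintViolation("H must have a zero diagonal")
    if np.any(H > 0):
        bad = np.argwhere(H > 0)[:10]
        raise ConstraintViolation(f"H has positive entries at {bad.tolist()}")
    both = (H != 0) & (H.T != 0)
    iu = np.triu_indices(H.shape[0], k=1)
    if np.any(both[iu]):
        idx = np.argwhere(both[iu]).ravel()[:10]
        pairs = [(int(iu[0][k]), int(iu[1][k])) for k in idx]
        raise ConstraintViolation(
            f"H pairs must be one-directional; both directions nonzero at {pairs}"
        )
    return H


@dataclass
class CommunityInteractions:
    """The (M, L, H) interaction bundle with its intensities.

    ``eps1``, ``eps2`` and ``eps3`` are the nonnegative intensities of
    cooperation, exploitation and harm entering the replacement rates.
    """

    M: np.ndarray
    L: np.ndarray
    H: np.ndarray
    eps1: float = 1.0
    eps2: float = 1.0
    eps3: float = 1.0
    validate: bool = True

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        if not (self.M.shape == self.L.shape == self.H.shape):
            raise ConstraintViolation(
                f"M, L, H must share a shape; got {self.M.shape}, "
                f"{self.L.shape}, {self.H.shape}"
            )
        if min(self.eps1, self.eps2, self.eps3) < 0:
            raise ValueError("interaction intensities must be nonnegative")
        if self.validate:
            self.check()

    @property
    def S(self) -> int:
        return self.M.shape[0]

    def check(self) -> None:
        """Run all structural conditions; raise with an itemized report."""
        errors: list[str] = []
        for fn, Q in (
            (validate_cooperation, self.M),
            (validate_exploitation, self.L),
            (validate_harm, self.H),
        ):
            try:
                fn(Q)
            except ConstraintViolation as exc:
                errors.append(str(exc))
        overlap = ((self.M != 0).astype(int) + (self.L != 0) + (self.H != 0)) > 1
        if np.any(overlap):
            bad = np.argwhere(overlap)[:10]
            errors.append(
                "disjoint-support condition M_ij*L_ij*H_ij = 0 violated at "
                f"{bad.tolist()}"
            )
        if errors:
            raise ConstraintViolation("; ".join(errors))

    def copy(self) -> "CommunityInteractions":
        return CommunityInteractions(
            self.M.copy(), self.L.copy(), self.H.copy(),
            self.eps1, self.eps2, self.eps3, validate=False,
        )

    def restrict(self, species: np.ndarray) -> "CommunityInteractions":
        """Sub-community on a subset of species (0-based indices)."""
        idx = np.asarray(species, dtype=int)
        return CommunityInteractions(
            self.M[np.ix_(idx, idx)],
            self.L[np.ix_(idx, idx)],
            self.H[np.ix_(idx, idx)],
            self.eps1, self.eps2, self.eps3, validate=False,
        )


# ---------------------------------------------------------------------------
# Random generation
# ---------------------------------------------------------------------------


def sample_cooperation(
    spec: EnsembleSpec,
    rng: np.random.Generator | None = None,
    *,
    self_links: float | None = None,
) -> np.ndarray:
    """Sample a cooperation matrix M.

    Each unordered off-diagonal pair ``(M_ij, M_ji)`` is (0, 0) with
    probability ``1 - c_M`` and otherwise both directions carry magnitudes
    drawn from the base distribution with pair correlation ``rho``.  The
    diagonal is zero unless ``self_links`` gives an explicit self-support
    weight (used by hand-built cascade fixtures, not by the ensembles).
    """
    rng = spec.rng(rng)
    S = spec.S
    M = np.zeros((S, S))
    iu, ju = _pair_indices(S)
    present = rng.random(iu.size) < spec.c_M
    vals = _sample_magnitude_pairs(spec, int(present.sum()), rng)
    M[iu[present], ju[present]] = vals[:, 0]
    M[ju[present], iu[present]] = vals[:, 1]
    if self_links is not None:
        np.fill_diagonal(M, self_links)
    return M


def sample_exploitation(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample an exploitation matrix L.

    A connected pair carries magnitudes ``(z, z')`` from the base
    distribution with an antisymmetric sign pattern: a uniformly chosen
    direction is positive (the exploiter) and the partner negative.
    """
    rng = spec.rng(rng)
    S = spec.S
    L = np.zeros((S, S))
    iu, ju = _pair_indices(S)
    present = rng.random(iu.size) < spec.c_L
    n = int(present.sum())
    vals = _sample_magnitude_pairs(spec, n, rng)
    flip = rng.random(n) < 0.5
    sign = np.where(flip, -1.0, 1.0)
    L[iu[present], ju[present]] = sign * vals[:, 0]
    L[ju[present], iu[present]] = -sign * vals[:, 1]
    return L


def sample_harm(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sample a harm matrix H: per connected pair exactly one direction
    carries ``-|z|``, the orientation chosen uniformly."""
    rng = spec.rng(rng)
    S = spec.S
    H = np.zeros((S, S))
    iu, ju = _pair_indices(S)
    present = rng.random(iu.size) < spec.c_H
    n = int(present.sum())
    vals = _sample_magnitude_pairs(spec, n, rng)
    flip = rng.random(n) < 0.5
    src = np.where(flip, iu[present], ju[present])
    dst = np.where(flip, ju[present], iu[present])
    H[src, dst] = -vals[:, 0]
    return H


def sample_community(
    spec: EnsembleSpec, rng: np.random.Generator | None = None
) -> CommunityInteractions:
    """Sample a full (M, L, H) community with disjoint pair supports.

    Each unordered pair is assigned independently to one interaction class
    with probabilities ``(c_M, c_L, c_H, 1 - c_M - c_L - c_H)``; the class
    sub-generators then draw the weights.
    """
    rng = spec.rng(rng)
    S = spec.S
    iu, ju = _pair_indices(S)
    u = rng.random(iu.size)
    is_m = u < spec.c_M
    is_l = (u >= spec.c_M) & (u < spec.c_M + spec.c_L)
    is_h = (u >= spec.c_M + spec.c_L) & (u < spec.c_M + spec.c_L + spec.c_H)

    M = np.zeros((S, S))
    vals = _sample_magnitude_pairs(spec, int(is_m.sum()), rng)
    M[iu[is_m], ju[is_m]] = vals[:, 0]
    M[ju[is_m], iu[is_m]] = vals[:, 1]

    L = np.zeros((S, S))
    n_l = int(is_l.sum())
    vals = _sample_magnitude_pairs(spec, n_l, rng)
    sign = np.where(rng.random(n_l) < 0.5, -1.0, 1.0)
    L[iu[is_l], ju[is_l]] = sign * vals[:, 0]
    L[ju[is_l], iu[is_l]] = -sign * vals[:, 1]

    H = np.zeros((S, S))
    n_h = int(is_h.sum())
    vals = _sample_magnitude_pairs(spec, n_h, rng)
    flip = rng.random(n_h) < 0.5
    src = np.where(flip, iu[is_h], ju[is_h])
    dst = np.where(flip, ju[is_h], iu[is_h])
    H[src, dst] = -vals[:, 0]

    return CommunityInteractions(M, L, H)


# ---------------------------------------------------------------------------
# Ensemble statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatrixStats:
    """Connectivity-diluted moments of the off-diagonal entries of a matrix.

    ``mu`` and ``sigma`` are the mean and standard deviation over *all*
    off-diagonal entries (zeros of absent links included); ``rho`` the
    correlation between the (ij, ji) directed entries; ``cv`` the coefficient
    of variation ``sigma / |mu|``.
    """

    c: float
    mu: float
    sigma: float
    rho: float

    @property
    def cv(self) -> float:
        return self.sigma / abs(self.mu) if self.mu != 0 else np.inf


def effective_stats(
    Q: np.ndarray | None = None,
    *,
    spec: EnsembleSpec | None = None,
    c: float | None = None,
) -> MatrixStats:
    """Moments of off-diagonal entries, empirical or analytic.

    Empirical mode (``Q`` given): sample connectivity (fraction of nonzero
    off-diagonal entries), mean/sd over all off-diagonal entries and the
    (ij, ji) correlation.

    Analytic mode (``spec`` given): for base-entry mean ``mu``, sd ``sigma``,
    pair correlation ``rho`` and connectivity ``c``::

        mu_Q    = c * mu
        sigma_Q = sqrt(c * sigma**2 + c * (1 - c) * mu**2)
        rho_Q   = (rho * sigma**2 + (1 - c) * mu**2)
                  / (sigma**2 + (1 - c) * mu**2)

    so a diluted ensemble carries positive effective correlation even for
    independent draws.  ``c`` defaults to ``spec.c_M``.
    """
    if (Q is None) == (spec is None):
        raise ValueError("pass exactly one of Q or spec")
    if Q is not None:
        Q = _check_square(Q, "Q")
        S = Q.shape[0]
        if S < 2:
            raise ValueError("effective_stats needs S >= 2 (no off-diagonal entries)")
        off = ~np.eye(S, dtype=bool)
        x = Q[off]
        iu = np.triu_indices(S, k=1)
        a, b = Q[iu], Q.T[iu]
        if np.std(a) > 0 and np.std(b) > 0:
            rho_emp = float(np.corrcoef(a, b)[0, 1])
        else:
            rho_emp = 0.0
        return MatrixStats(
            c=float(np.count_nonzero(x)) / x.size,
            mu=float(x.mean()),
            sigma=float(x.std()),
            rho=rho_emp,
        )
    cq = spec.c_M if c is None else c
    mu, sigma = spec.mu, spec.sigma
    var_q = cq * sigma**2 + cq * (1.0 - cq) * mu**2
    denom = sigma**2 + (1.0 - cq) * mu**2
    rho_q = (spec.rho * sigma**2 + (1.0 - cq) * mu**2) / denom if denom > 0 else 0.0
    return MatrixStats(c=cq, mu=cq * mu, sigma=float(np.sqrt(var_q)), rho=rho_q)


# ---------------------------------------------------------------------------
# Topology transforms
# ---------------------------------------------------------------------------


def is_irreducible(M: np.ndarray) -> bool:
    """True iff the directed graph of strictly positive entries is strongly
    connected (the Perron–Frobenius condition for full coexistence)."""
    M = validate_cooperation(M)
    S = M.shape[0]
    if S == 1:
        return True
    n, _ = connected_components(csr_matrix(M > 0), directed=True, connection="strong")
    return n == 1


def prune_unsupported(M: np.ndarray) -> tuple[np.ndarray, list[list[int]]]:
    """Iteratively remove species with no incoming cooperative support.

    Species i is non-supported when its in-support ``sum_j M[j, i]`` over the
    remaining community is zero; at stationarity such a species has zero
    abundance, and its removal may cascade.  All currently unsupported
    species are deleted per sweep, repeated to the fixed point (which is
    deletion-order independent).

    Returns
    -------
    survivors:
        Sorted 0-based indices of the surviving species (possibly empty).
    removed:
        One sorted list of indices per sweep, in removal order.
    """
    M = validate_cooperation(M)
    S = M.shape[0]
    alive = np.ones(S, dtype=bool)
    removed: list[list[int]] = []
    while True:
        sub = M[np.ix_(alive, alive)]
        support = sub.sum(axis=0)
        dead = np.flatnonzero(alive)[support == 0]
        if dead.size == 0:
            break
        removed.append([int(i) for i in dead])
        alive[dead] = False
        if not alive.any():
            break
    return np.flatnonzero(alive), removed


def constant_effort_normalize(Q: np.ndarray) -> np.ndarray:
    """Divide each column by its receiver in-degree (count of nonzero
    entries); zero columns are untouched.  Models a constant total
    interaction effort per receiving species."""
    Q = _check_square(Q, "Q")
    indeg = np.count_nonzero(Q, axis=0).astype(float)
    indeg[indeg == 0] = 1.0
    return Q / indeg[np.newaxis, :]


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

_CLASSES = ("M", "L", "H")


def write_edgelist(inter: CommunityInteractions, path) -> None:
    """Write the community as a TSV edge list.

    Columns: ``source  target  weight  class`` with 1-based species ids;
    lines starting with ``#`` are comments.  Weights use ``repr`` so a
    write→read→write cycle is byte-identical.
    """
    buf = io.StringIO()
    buf.write(f"# coopnet edge list, S={inter.S}\n")
    buf.write("source\ttarget\tweight\tclass\n")
    for cls, Q in zip(_CLASSES, (inter.M, inter.L, inter.H)):
        src, dst = np.nonzero(Q)
        for i, j in zip(src, dst):
            buf.write(f"{i + 1}\t{j + 1}\t{float(Q[i, j])!r}\t{cls}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_edgelist(
    path, S: int, eps1: float = 1.0, eps2: float = 1.0, eps3: float = 1.0
) -> CommunityInteractions:
    """Read a TSV edge list into a validated community.

    Raises :class:`ConstraintViolation` with an itemized report on unknown
    class tokens, out-of-range ids, duplicate directed edges within a class,
    or any violated structural condition.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=0, float_precision="round_trip"
    )
    expected = ["source", "target", "weight", "class"]
    if list(df.columns) != expected:
        raise ConstraintViolation(
            f"edge list must have columns {expected}, got {list(df.columns)}"
        )
    mats = {cls: np.zeros((S, S)) for cls in _CLASSES}
    errors: list[str] = []
    seen: set[tuple[str, int, int]] = set()
    for row in df.itertuples(index=False):
        cls = str(row[3])
        if cls not in mats:
            errors.append(f"unknown interaction class {cls!r} on edge {row[:2]}")
            continue
        i, j = int(row.source) - 1, int(row.target) - 1
        if not (0 <= i < S and 0 <= j < S):
            errors.append(f"species id out of range 1..{S} on edge {row[:2]}")
            continue
        key = (cls, i, j)
        if key in seen:
            errors.append(f"duplicate directed edge {row[:2]} in class {cls}")
            continue
        seen.add(key)
        mats[cls][i, j] = float(row.weight)
    if errors:
        raise ConstraintViolation("; ".join(errors))
    return CommunityInteractions(
        mats["M"], mats["L"], mats["H"], eps1, eps2, eps3
    )


# ---------------------------------------------------------------------------
# Adjacency I/O (one CSV per matrix, S x S, no header)
# ---------------------------------------------------------------------------


def write_adjacency(Q: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(Q, dtype=float), delimiter=",")


def read_adjacency(path) -> np.ndarray:
    Q = np.loadtxt(path, delimiter=",")
    return np.atleast_2d(Q)
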