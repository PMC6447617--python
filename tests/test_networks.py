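"""Interaction-matrix generation, validation, statistics and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coopnet.networks import (
    CommunityInteractions,
    ConstraintViolation,
    EnsembleSpec,
    constant_effort_normalize,
    effective_stats,
    is_irreducible,
    prune_unsupported,
    read_edgelist,
    sample_community,
    sample_cooperation,
    sample_exploitation,
    sample_harm,
    write_edgelist,
)

FAMILY_PARAMS = {
    "abs-normal": (0.5, 0.15),
    "gamma": (4.0, 0.25),
    "lognormal": (-0.5, 0.4),
    "uniform": (0.2, 1.0),
}


# ---------------------------------------------------------------------------
# Ensemble spec validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs,match",
    [
        (dict(S=0), "S must be"),
        (dict(S=5, c_M=1.2), "c_M"),
        (dict(S=5, c_M=0.5, c_L=0.4, c_H=0.3), "disjoint"),
        (dict(S=5, rho=1.5), "rho"),
        (dict(S=5, family="zipf"), "unknown family"),
    ],
)
def test_spec_rejects_invalid(kwargs, match):
    with pytest.raises(ValueError, match=match):
        EnsembleSpec(**kwargs)


def test_spec_base_moments_match_sampling(rng):
    spec = EnsembleSpec(S=2, family="abs-normal", dist_params=(0.3, 0.5))
    z = np.abs(0.3 + 0.5 * rng.standard_normal(200_000))
    assert spec.mu == pytest.approx(z.mean(), rel=0.01)
    assert spec.sigma == pytest.approx(z.std(), rel=0.01)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------


def test_zero_connectivity_gives_zero_matrices(rng):
    spec = EnsembleSpec(S=12)
    assert not sample_cooperation(spec, rng).any()
    assert not sample_exploitation(spec, rng).any()
    assert not sample_harm(spec, rng).any()


def test_constant_family_full_connectivity(rng):
    spec = EnsembleSpec(S=7, c_M=1.0, family="constant", dist_params=(1.0, 0.0))
    M = sample_cooperation(spec, rng)
    assert (np.diag(M) == 0).all()
    off = ~np.eye(7, dtype=bool)
    assert (M[off] == 1.0).all()


@pytest.mark.parametrize("family", sorted(FAMILY_PARAMS))
def test_cooperation_matrix_invariants(family, rng):
    spec = EnsembleSpec(
        S=60, c_M=0.4, family=family, dist_params=FAMILY_PARAMS[family], rho=0.3
    )
    M = sample_cooperation(spec, rng)
    assert (M >= 0).all()
    assert (np.diag(M) == 0).all()
    # pair supports coincide: M_ij nonzero iff M_ji nonzero
    assert ((M > 0) == (M > 0).T).all()


def test_exploitation_invariants_and_connectivity(rng):
    spec = EnsembleSpec(S=100, c_L=0.3, family="uniform", dist_params=(0.0, 1.0))
    L = sample_exploitation(spec, rng)
    prod = L * L.T
    iu = np.triu_indices(100, k=1)
    ok = (prod[iu] < 0) | ((L[iu] == 0) & (L.T[iu] == 0))
    assert ok.all()
    # realized connectivity within the binomial 99% CI of c_L = 0.3
    n_pairs = iu[0].size
    k = np.count_nonzero(L[iu])
    lo, hi = 0.3 + np.array([-1, 1]) * 2.58 * np.sqrt(0.3 * 0.7 / n_pairs)
    assert lo < k / n_pairs < hi


def test_harm_invariants_and_magnitude(rng):
    mu = 0.3
    spec = EnsembleSpec(S=50, c_H=0.4, family="abs-normal", dist_params=(mu, mu / 3))
    vals = []
    for _ in range(10):
        H = sample_harm(spec, rng)
        assert (H <= 0).all()
        assert not ((H != 0) & (H.T != 0)).any()
        vals.append(-H[H != 0])
    v = np.concatenate(vals)
    se = v.std() / np.sqrt(v.size)
    spec_mean = EnsembleSpec(S=2, family="abs-normal", dist_params=(mu, mu / 3)).mu
    assert abs(v.mean() - spec_mean) < 3 * se


def test_community_disjoint_support_exhaustive(rng):
    spec = EnsembleSpec(
        S=40, c_M=0.3, c_L=0.3, c_H=0.3, family="uniform", dist_params=(0.0, 1.0)
    )
    inter = sample_community(spec, rng)
    # brute-force pair scan
    for i in range(40):
        for j in range(40):
            kinds = sum(
                Q[i, j] != 0 for Q in (inter.M, inter.L, inter.H)
            )
            assert kinds <= 1


def test_pure_cooperation_community(rng):
    spec = EnsembleSpec(S=10, c_M=1.0, family="uniform", dist_params=(0.0, 1.0))
    inter = sample_community(spec, rng)
    assert not inter.L.any() and not inter.H.any()
    off = ~np.eye(10, dtype=bool)
    assert (inter.M[off] > 0).all()


def test_harm_scan_point_complementary_connectivities(rng):
    spec = EnsembleSpec(
        S=50, c_M=0.8, c_H=0.2, family="abs-normal", dist_params=(0.3, 0.1)
    )
    inter = sample_community(spec, rng)
    inter.check()  # no pair carries two interaction types
    off = ~np.eye(50, dtype=bool)
    covered = ((inter.M != 0) | (inter.M != 0).T | (inter.H != 0) | (inter.H != 0).T)
    assert covered[off].mean() > 0.95  # fully connected up to sampling noise


# ---------------------------------------------------------------------------
# Effective moments
# ---------------------------------------------------------------------------


def test_effective_stats_collapse_at_full_connectivity():
    spec = EnsembleSpec(
        S=10, c_M=1.0, family="abs-normal", dist_params=(0.6, 0.1), rho=0.4
    )
    st_ = effective_stats(spec=spec)
    assert st_.sigma == pytest.approx(spec.sigma)
    assert st_.rho == pytest.approx(0.4)


def test_effective_stats_dilution_closed_form():
    # c = 0.5, mu = 1, sigma = 0: sigma_Q^2 = 0.25, rho_Q = 1
    spec = EnsembleSpec(S=10, c_M=0.5, family="constant", dist_params=(1.0, 0.0))
    st_ = effective_stats(spec=spec)
    assert st_.mu == pytest.approx(0.5)
    assert st_.sigma**2 == pytest.approx(0.25)
    assert st_.rho == pytest.approx(1.0)


def test_dilution_induces_positive_correlation():
    # rho = 0 but c < 1 still gives rho_Q > 0
    spec = EnsembleSpec(
        S=10, c_M=0.4, family="abs-normal", dist_params=(0.5, 0.2), rho=0.0
    )
    st_ = effective_stats(spec=spec)
    mu, s2 = spec.mu, spec.sigma**2
    assert st_.rho == pytest.approx(0.6 * mu**2 / (s2 + 0.6 * mu**2))
    assert st_.rho > 0


@pytest.mark.parametrize("family", sorted(FAMILY_PARAMS))
def test_analytic_vs_empirical_moments(family, rng):
    """Connectivity-diluted moment formulas against 20-replicate sampling."""
    spec = EnsembleSpec(
        S=120, c_M=0.5, family=family, dist_params=FAMILY_PARAMS[family]
    )
    ana = effective_stats(spec=spec)
    emp = np.array(
        [
            (e.mu, e.sigma, e.rho)
            for e in (
                effective_stats(sample_cooperation(spec, rng)) for _ in range(20)
            )
        ]
    )
    mean, se = emp.mean(0), emp.std(0, ddof=1) / np.sqrt(len(emp))
    for got, want, s in zip(mean, (ana.mu, ana.sigma, ana.rho), se):
        assert abs(got - want) < 4 * s


def test_effective_stats_requires_offdiagonal():
    with pytest.raises(ValueError, match="S >= 2"):
        effective_stats(np.zeros((1, 1)))


# ---------------------------------------------------------------------------
# Topology: irreducibility and pruning
# ---------------------------------------------------------------------------


def test_cycle_is_irreducible_chain_is_not(cycle7, cascade7):
    assert is_irreducible(cycle7)
    chain = np.triu(cascade7)  # drop the self-link: pure chain
    chain[6, 6] = 0
    assert not is_irreducible(chain)


def test_irreducibility_matches_closure_oracle(rng):
    for _ in range(30):
        A = (rng.random((12, 12)) < 0.12).astype(float)
        np.fill_diagonal(A, 0)
        # Warshall closure including trivial self-reachability
        R = (A > 0) | np.eye(12, dtype=bool)
        for k in range(12):
            R = R | (R[:, k : k + 1] & R[k : k + 1, :])
        assert is_irreducible(A) == bool(R.all())


def test_prune_cycle_keeps_all(cycle7):
    survivors, removed = prune_unsupported(cycle7)
    assert survivors.tolist() == list(range(7))
    assert removed == []


def test_prune_cascade_single_survivor(cascade7):
    survivors, removed = prune_unsupported(cascade7)
    assert survivors.tolist() == [6]
    assert [s for sweep in removed for s in sweep] == [0, 1, 2, 3, 4, 5]


def _prune_random_order(M, order_rng):
    """Asynchronous one-at-a-time pruning in random order (oracle)."""
    alive = list(range(M.shape[0]))
    while True:
        sub = M[np.ix_(alive, alive)]
        unsupported = [alive[i] for i in np.flatnonzero(sub.sum(0) == 0)]
        if not unsupported:
            return sorted(alive)
        alive.remove(unsupported[order_rng.integers(len(unsupported))])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_prune_is_order_independent_and_idempotent(seed):
    g = np.random.default_rng(seed)
    M = (g.random((15, 15)) < 0.1).astype(float) * g.random((15, 15))
    np.fill_diagonal(M, 0)
    survivors, _ = prune_unsupported(M)
    for k in range(3):
        oracle = _prune_random_order(M, np.random.default_rng(seed + k))
        assert survivors.tolist() == oracle
    again, removed = prune_unsupported(M[np.ix_(survivors, survivors)])
    assert again.tolist() == list(range(len(survivors))) and removed == []


def test_irreducible_matrix_survives_pruning_whole(cycle7):
    assert is_irreducible(cycle7)
    assert prune_unsupported(cycle7)[0].size == 7


# ---------------------------------------------------------------------------
# Constant-effort normalization
# ---------------------------------------------------------------------------


def test_constant_effort_normalize(rng):
    Q = np.zeros((4, 4))
    Q[0, 1] = Q[2, 1] = 1.0  # column 1 has in-degree 2
    Q[1, 2] = 3.0  # column 2 has in-degree 1
    out = constant_effort_normalize(Q)
    assert out[0, 1] == out[2, 1] == 0.5
    assert out[1, 2] == 3.0
    R = rng.random((9, 9)) * (rng.random((9, 9)) < 0.4)
    out = constant_effort_normalize(R)
    assert ((out != 0) == (R != 0)).all()
    indeg = np.count_nonzero(R, axis=0)
    for j in np.flatnonzero(indeg):
        assert np.allclose(out[:, j], R[:, j] / indeg[j])


# ---------------------------------------------------------------------------
# Structural validation
# ---------------------------------------------------------------------------


def test_validation_rejects_bad_matrices():
    M = np.zeros((3, 3))
    L = np.zeros((3, 3))
    H = np.zeros((3, 3))
    M_bad = M.copy()
    M_bad[0, 1] = -1.0
    with pytest.raises(ConstraintViolation, match="negative"):
        CommunityInteractions(M_bad, L, H)
    L_bad = L.copy()
    L_bad[0, 1] = 1.0
    L_bad[1, 0] = 2.0  # same sign
    with pytest.raises(ConstraintViolation, match="L_ij"):
        CommunityInteractions(M, L_bad, H)
    H_bad = H.copy()
    H_bad[0, 1] = -1.0
    H_bad[1, 0] = -1.0  # both directions
    with pytest.raises(ConstraintViolation, match="one-directional"):
        CommunityInteractions(M, L, H_bad)
    M2, L2 = M.copy(), L.copy()
    M2[0, 1] = 1.0
    L2[0, 1], L2[1, 0] = 1.0, -1.0  # overlapping pair support
    with pytest.raises(ConstraintViolation, match="disjoint"):
        CommunityInteractions(M2, L2, H)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------


def test_empty_edgelist(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("source\ttarget\tweight\tclass\n")
    inter = read_edgelist(p, S=3)
    assert not inter.M.any() and not inter.L.any() and not inter.H.any()


def test_cycle_edgelist_roundtrip(tmp_path, cycle7):
    lines = ["source\ttarget\tweight\tclass"]
    for i in range(7):
        lines.append(f"{i + 1}\t{(i + 1) % 7 + 1}\t1.0\tM")
    p = tmp_path / "cycle.tsv"
    p.write_text("\n".join(lines) + "\n")
    inter = read_edgelist(p, S=7)
    assert np.array_equal(inter.M, cycle7)


def test_write_read_write_byte_identical(tmp_path, rng):
    spec = EnsembleSpec(
        S=15, c_M=0.3, c_L=0.2, c_H=0.2, family="uniform", dist_params=(0.0, 1.0)
    )
    inter = sample_community(spec, rng)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_edgelist(inter, p1)
    loaded = read_edgelist(p1, S=15)
    assert np.array_equal(loaded.M, inter.M)
    assert np.array_equal(loaded.L, inter.L)
    assert np.array_equal(loaded.H, inter.H)
    write_edgelist(loaded, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_edgelist_errors_are_itemized(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text(
        "source\ttarget\tweight\tclass\n"
        "1\t2\t1.0\tX\n"
        "1\t2\t1.0\tM\n"
        "1\t2\t2.0\tM\n"
        "9\t1\t1.0\tM\n"
    )
    with pytest.raises(ConstraintViolation) as err:
        read_edgelist(p, S=3)
    msg = str(err.value)
    assert "unknown interaction class" in msg
    assert "duplicate directed edge" in msg
    assert "out of range" in msg


def test_adjacency_roundtrip(tmp_path, rng):
    from coopnet.networks import read_adjacency, write_adjacency

    Q = rng.random((6, 6)) * (rng.random((6, 6)) < 0.5)
    p = tmp_path / "M.csv"
    write_adjacency(Q, p)
    assert np.allclose(read_adjacency(p), Q)
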