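"""Reproducible in-silico experiments of the cooperative voter model.

Each driver returns a plain dict of results and, given an output directory,
writes tabular TSV/CSV outputs plus a JSON manifest (resolved configuration,
seed, package version) sufficient to re-run identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .meanfield import classify, integrate, pf_stationary
from .networks import (
    CommunityInteractions,
    EnsembleSpec,
    effective_stats,
    prune_unsupported,
    sample_community,
    sample_cooperation,
    sample_exploitation,
)
from .patterns import rsa_experiment
from .stability import formal_jacobian, is_stable, jacobian, spectrum

__all__ = [
    "cycle_matrix",
    "cascade_matrix",
    "run_motif",
    "run_harm_scan",
    "run_spectrum",
    "run_rsa",
]


# ---------------------------------------------------------------------------
# Built-in fixtures
# ---------------------------------------------------------------------------


def cycle_matrix(S: int = 7, weight: float = 1.0) -> np.ndarray:
    """Directed cooperation cycle 1 -> 2 -> ... -> S -> 1: every species has
    exactly one mutualistic partner, the network is irreducible, and the
    stationary state is uniform by symmetry."""
    M = np.zeros((S, S))
    for i in range(S):
        M[i, (i + 1) % S] = weight
    return M


def cascade_matrix(S: int = 7, weight: float = 1.0) -> np.ndarray:
    """Directed support chain 1 -> 2 -> ... -> S with a terminal self-link:
    species 1 is unsupported, and its extinction propagates down the chain
    until only the self-sustaining terminal species survives."""
    M = np.zeros((S, S))
    for i in range(S - 1):
        M[i, i + 1] = weight
    M[S - 1, S - 1] = weight
    return M


def _write_manifest(out: Path, name: str, config: dict) -> None:
    manifest = {"experiment": name, "coopnet_version": __version__, **config}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


# ---------------------------------------------------------------------------
# Motif experiment (coexistence cycle vs extinction cascade)
# ---------------------------------------------------------------------------


def run_motif(
    *,
    S: int = 7,
    eps1: float = 1.0,
    t_max: float = 300.0,
    M: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Mean-field integration + pruning on the built-in 7-species motifs
    (or a user matrix): reports survivor counts from both routes."""
    fixtures = (
        {"cycle": cycle_matrix(S), "cascade": cascade_matrix(S)}
        if M is None
        else {"user": np.asarray(M, dtype=float)}
    )
    results = {}
    for name, Mfix in fixtures.items():
        zero = np.zeros_like(Mfix)
        inter = CommunityInteractions(Mfix, zero, zero, eps1, 0.0, 0.0)
        m0 = np.full(S, 1.0 / S)
        traj, sol = integrate(
            m0, inter, t_max=t_max,
            t_eval=np.linspace(0.0, min(t_max, 60.0), 121),
        )
        feasible, extinct, frac = classify(sol)
        pruned, removed = prune_unsupported(Mfix)
        results[name] = {
            "survivors_integration": sol.survivors().tolist(),
            "survivors_pruning": pruned.tolist(),
            "fraction_extinct": frac,
            "feasible": feasible,
            "m": sol.m.tolist(),
            "trajectory": traj,
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, res in results.items():
            traj = res["trajectory"]
            df = pd.DataFrame(
                traj.eta, columns=[f"species_{i + 1}" for i in range(S)]
            )
            df.insert(0, "time", traj.t)
            df.to_csv(out / f"motif_{name}_trajectory.tsv", sep="\t", index=False)
        summary = {
            k: {kk: vv for kk, vv in v.items() if kk != "trajectory"}
            for k, v in results.items()
        }
        (out / "motif_summary.json").write_text(json.dumps(summary, indent=2))
        _write_manifest(out, "motif", {"S": S, "eps1": eps1, "t_max": t_max})
    return results


# ---------------------------------------------------------------------------
# Harm scan (extinction fraction vs harmful connectivity)
# ---------------------------------------------------------------------------


def run_harm_scan(
    *,
    S: int = 50,
    mus: tuple[float, ...] = (0.05, 0.1, 0.3, 1.0),
    c_H_grid: np.ndarray | None = None,
    replicates: int = 10,
    eps1: float = 1.0,
    eps3: float = 1.0,
    seed: int | None = None,
    t_max: float = 400.0,
    rtol: float = 1e-8,
    out_dir: str | Path | None = None,
) -> dict:
    """Extinction-fraction scan over harmful connectivity.

    For each grid point c_H (cooperative connectivity c_M = 1 - c_H, so the
    community is fully connected) and each mean interaction magnitude mu,
    sample M entries as |z| and H entries as -|z| with z ~ Normal(mu, mu/3),
    integrate the harm-extended mean field from uniform abundances to its
    stationary state (a feasible, i.e. nonnegative, solution whenever the
    integration converges) and classify extinctions (abundance below 1/S^2).
    Stability is judged by the formal Jacobian at that state, which includes
    the re-invasion modes of extinct species: beyond a critical c_H the only
    feasible solutions fail this test.  Reports the per-cell mean extinction
    fraction over stable realizations, flags cells with no stable feasible
    realization, and the largest grid c_H that still has one.
    """
    if c_H_grid is None:
        c_H_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10)
    rng = np.random.default_rng(seed)
    rows = []
    for mu in mus:
        for c_H in c_H_grid:
            c_M = 1.0 - c_H
            for rep in range(replicates):
                spec = EnsembleSpec(
                    S=S, c_M=c_M, c_H=c_H, family="abs-normal",
                    dist_params=(mu, mu / 3.0),
                )
                inter = sample_community(spec, rng)
                inter.eps1, inter.eps2, inter.eps3 = eps1, 0.0, eps3
                m0 = np.full(S, 1.0 / S)
                _, sol = integrate(
                    m0, inter, t_max=t_max, rtol=rtol, atol=1e-12,
                    stat_tol=1e-9,
                )
                _, extinct, frac = classify(sol)
                stable = is_stable(formal_jacobian(inter, sol.m))
                rows.append(
                    {
                        "mu": mu,
                        "c_H": float(c_H),
                        "replicate": rep,
                        "fraction_extinct": frac,
                        "feasible": bool(sol.converged),
                        "coexisting": extinct.size == 0,
                        "stable": bool(stable),
                    }
                )
    table = pd.DataFrame(rows)
    fs = table[table.feasible & table.stable]
    max_feasible_stable_cH = float(fs.c_H.max()) if len(fs) else float("nan")
    result = {
        "table": table,
        "max_feasible_stable_cH": max_feasible_stable_cH,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "harm_scan.tsv", sep="\t", index=False)
        (out / "harm_scan_summary.json").write_text(
            json.dumps({"max_feasible_stable_cH": max_feasible_stable_cH})
        )
        _write_manifest(
            out, "harm_scan",
            {"S": S, "mus": mus, "replicates": replicates, "seed": seed,
             "eps1": eps1, "eps3": eps3, "c_H_grid": list(map(float, c_H_grid))},
        )
    return result


# ---------------------------------------------------------------------------
# Spectrum experiment (complexity-stability ellipse)
# ---------------------------------------------------------------------------


def run_spectrum(
    panel: str = "B",
    *,
    S: int = 400,
    eps1: float = 0.75,
    eps2: float = 1.0,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Jacobian eigenvalue cloud for the two reference regimes.

    Panel A: pure exploitation (c_L = 1, eps1 = 0) — the Jacobian at the
    uniform reference abundances has near-imaginary spectrum and a positive
    max real part at large S (classical instability).  Panel B: mixed
    cooperation + exploitation (c_L = c_M = 0.5, eps1 = 0.75, eps2 = 1) —
    the ellipse is centered at -eps1 S mu_M and the community is stable.
    Magnitudes are U(0, 1) in both panels.
    """
    rng = np.random.default_rng(seed)
    if panel not in ("A", "B"):
        raise ValueError("panel must be 'A' or 'B'")
    if panel == "A":
        spec = EnsembleSpec(S=S, c_L=1.0, family="uniform", dist_params=(0.0, 1.0))
        L = sample_exploitation(spec, rng)
        M = np.zeros_like(L)
        inter = CommunityInteractions(M, L, np.zeros_like(L), 0.0, eps2, 0.0)
        m = np.full(S, 1.0 / S)  # xi -> 0 reference point (no feasible interior
        # equilibrium exists for a zero-sum exploitative web)
        stats = None
    else:
        spec = EnsembleSpec(
            S=S, c_M=0.5, c_L=0.5, family="uniform", dist_params=(0.0, 1.0)
        )
        inter = sample_community(spec, rng)
        inter.eps1, inter.eps2, inter.eps3 = eps1, eps2, 0.0
        # start from the pure-cooperation PF state and polish to the full
        # (exploitation-perturbed) equilibrium
        m0 = pf_stationary(inter.M, eps1).m
        _, sol = integrate(m0, inter, t_max=50.0, rtol=1e-10, stat_tol=1e-10)
        m = sol.m
        stats = effective_stats(inter.M)
    J = jacobian(inter, m)
    summ = spectrum(J, stats, eps1=eps1 if panel == "B" else 1.0)
    result = {
        "panel": panel,
        "eigenvalues": summ.eigenvalues,
        "max_real": summ.max_real,
        "stable": summ.max_real < -1e-10,
        "center": summ.center,
        "semi_axis_re": summ.semi_axis_re,
        "semi_axis_im": summ.semi_axis_im,
        "predicted_max_real": summ.predicted_max_real,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"re": summ.eigenvalues.real, "im": summ.eigenvalues.imag}
        ).to_csv(out / f"spectrum_{panel}.csv", index=False)
        (out / f"spectrum_{panel}_summary.json").write_text(
            json.dumps({k: v for k, v in result.items() if k != "eigenvalues"})
        )
        _write_manifest(
            out, "spectrum",
            {"panel": panel, "S": S, "eps1": eps1, "eps2": eps2, "seed": seed},
        )
    return result


# ---------------------------------------------------------------------------
# RSA experiment wrapper
# ---------------------------------------------------------------------------


def run_rsa(
    *,
    S: int = 100,
    replicates: int = 20,
    families: tuple[str, ...] = ("abs-normal", "gamma", "lognormal"),
    cv_targets: tuple[float, ...] = (2.0, 3.0, 4.0),
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """CV-invariance RSA experiment (see :func:`coopnet.patterns.rsa_experiment`)."""
    res = rsa_experiment(
        families, cv_targets, S=S, replicates=replicates, seed=seed
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (family, cv), p in res["curves"].items():
            pd.DataFrame({"n": res["grid"], "p_greater": p}).to_csv(
                out / f"rsa_{family}_cv{cv:g}.tsv", sep="\t", index=False
            )
        (out / "rsa_summary.json").write_text(
            json.dumps(
                {
                    "params": res["params"],
                    "skipped": res["skipped"],
                    "median_within_cv": float(np.median(res["within_cv_distances"]))
                    if len(res["within_cv_distances"]) else None,
                    "median_across_cv": float(np.median(res["across_cv_distances"]))
                    if len(res["across_cv_distances"]) else None,
                },
                indent=2,
            )
        )
        _write_manifest(
            out, "rsa",
            {"S": S, "replicates": replicates, "families": families,
             "cv_targets": cv_targets, "seed": seed},
        )
    return res
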