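"""Exact finite-N stochastic simulation of the interacting voter model.

The community holds exactly N individuals over S species (hard carrying
capacity: every birth displaces a death).  A replacement inserting an
individual of species j occurs at total rate ``N * omega_j`` where

    omega_j = eta_j + eps1 * sum_k eta_k M_kj * theta(eta_j)
            + eps2 * sum_k eta_k L_kj * eta_j
            + eps3 * sum_k eta_k H_kj * theta(eta_j)

and the displaced individual is chosen uniformly among the N present.  This
is the unique time scale whose N -> infinity drift is the mean field
term-for-term: the expected change of eta_s per unit time is
``omega_s - eta_s * sum_i omega_i`` (gain from insertions of s, loss from s
individuals displaced by all insertions).  Self-replacement is permitted; it
changes nothing and contributes no drift.

theta(0) = 0, so an extinct species has rate exactly zero and extinction is
absorbing.  Harm can in principle drive a rate negative; that violates the
premise of the mean-field limit, so it raises :class:`NegativeRateError`
rather than being clipped.

The event loop is JIT-compiled with numba; states are recorded on a fixed
time grid (an opt-in event log is available for small runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

from .networks import CommunityInteractions

__all__ = [
    "NegativeRateError",
    "CommunityState",
    "Trajectory",
    "replacement_rates",
    "gillespie_step",
    "simulate",
    "fluctuations",
    "save_trajectory",
]


class NegativeRateError(RuntimeError):
    """A replacement rate went negative (harm too strong for the model)."""

    def __init__(self, species: int, rate: float, t: float):
        self.species, self.rate, self.t = species, rate, t
        super().__init__(
            f"rate of species {species} is {rate:.3g} < 0 at t={t:.4g}; "
            "the process (and its mean-field limit) requires nonnegative rates"
        )


@dataclass
class CommunityState:
    """Integer counts of N individuals over S species."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() < 1:
            raise ValueError("community must contain at least one individual")

    @property
    def N(self) -> int:
        return int(self.counts.sum())

    @property
    def S(self) -> int:
        return self.counts.size

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.N

    @classmethod
    def from_fractions(cls, eta: np.ndarray, N: int) -> "CommunityState":
        """Largest-remainder rounding of target fractions to integer counts."""
        eta = np.asarray(eta, dtype=float)
        raw = eta * N
        counts = np.floor(raw).astype(np.int64)
        short = N - counts.sum()
        order = np.argsort(raw - np.floor(raw))[::-1]
        counts[order[:short]] += 1
        return cls(counts)


@dataclass
class Trajectory:
    """States sampled on a time grid (counts[i] is the state at times[i])."""

    times: np.ndarray
    counts: np.ndarray  # shape (len(times), S)
    N: int
    seed: int | None = None
    absorbed: bool = False
    events: list[tuple[float, int, int]] = field(default_factory=list)

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.N


def replacement_rates(
    state: CommunityState, inter: CommunityInteractions
) -> np.ndarray:
    """Per-species insertion rates omega (to be multiplied by N).

    Raises :class:`NegativeRateError` if any component is negative.
    """
    eta = state.fractions
    theta = (eta > 0.0).astype(float)
    w = eta + (
        inter.eps1 * (inter.M.T @ eta)
        + inter.eps3 * (inter.H.T @ eta)
    ) * theta + inter.eps2 * (inter.L.T @ eta) * eta
    if np.any(w < 0):
        j = int(np.argmin(w))
        raise NegativeRateError(j, float(w[j]), 0.0)
    return w


def gillespie_step(
    state: CommunityState,
    inter: CommunityInteractions,
    rng: np.random.Generator,
) -> tuple[float, int, int]:
    """One exact event: returns (waiting time, dying species, born species)
    and updates the state in place.

    The waiting time is Exponential(N * sum(omega)); the born species is
    chosen proportionally to omega and the victim uniformly among the N
    individuals.
    """
    w = replacement_rates(state, inter)
    total = w.sum() * state.N
    if total <= 0:
        raise RuntimeError("all rates zero: absorbing state")
    dt = rng.exponential(1.0 / total)
    born = int(rng.choice(state.S, p=w / w.sum()))
    die = int(rng.choice(state.S, p=state.counts / state.N))
    state.counts[die] -= 1
    state.counts[born] += 1
    return dt, die, born


@numba.njit(cache=True)
def _run(counts, M, L, H, e1, e2, e3, t0, t_grid, out, gi0, u):  # pragma: no cover - jit
    """Grid-recording event loop starting at absolute time ``t0``.

    ``u`` is a (n_events, 3) block of uniforms (waiting time, born, victim);
    ``out`` is the (n_grid, S) record buffer, filled from row ``gi0`` on.
    Returns (status, t_reached, next_grid_row).  status 0 = grid complete,
    1 = uniform budget exhausted, -1 = negative rate, 2 = frozen
    (monodominance: the state can never change again).
    """
    S = counts.size
    N = 0
    for s in range(S):
        N += counts[s]
    n_grid = t_grid.size
    w = np.empty(S)
    t = t0
    gi = gi0
    k = 0
    n_u = u.shape[0]
    while gi < n_grid:
        # rates at the current state
        tot = 0.0
        alive = 0
        for j in range(S):
            eta_j = counts[j] / N
            acc = eta_j
            if eta_j > 0.0:
                alive += 1
                mh = 0.0
                for i in range(S):
                    if counts[i] > 0:
                        mh += (e1 * M[i, j] + e3 * H[i, j]) * counts[i]
                acc += mh / N
            if e2 != 0.0 and eta_j > 0.0:
                lsum = 0.0
                for i in range(S):
                    if counts[i] > 0:
                        lsum += L[i, j] * counts[i]
                acc += e2 * (lsum / N) * eta_j
            if acc < 0.0:
                return -1, t, gi
            w[j] = acc
            tot += acc
        if alive <= 1:
            # monodominance: every event replaces like with like
            while gi < n_grid:
                for s in range(S):
                    out[gi, s] = counts[s]
                gi += 1
            return 2, t, gi
        if k >= n_u:
            return 1, t, gi
        dt = -np.log(u[k, 0]) / (tot * N)
        t_new = t + dt
        while gi < n_grid and t_grid[gi] <= t_new:
            for s in range(S):
                out[gi, s] = counts[s]
            gi += 1
        t = t_new
        # born species proportional to w
        r = u[k, 1] * tot
        born = 0
        acc = w[0]
        while acc < r and born < S - 1:
            born += 1
            acc += w[born]
        # victim uniform among N individuals
        rv = u[k, 2] * N
        die = 0
        accv = float(counts[0])
        while accv <= rv and die < S - 1:
            die += 1
            accv += counts[die]
        counts[die] -= 1
        counts[born] += 1
        k += 1
    return 0, t, gi


def simulate(
    initial: CommunityState,
    inter: CommunityInteractions,
    t_max: float,
    rng: np.random.Generator | int | None = None,
    *,
    n_record: int = 200,
    t_grid: np.ndarray | None = None,
    log_events: bool = False,
    _batch: int = 1 << 16,
) -> Trajectory:
    """Simulate the community to ``t_max``, recording on a time grid.

    The state recorded at grid time ``g`` is the state just before the first
    event with time > g (right-continuous sampling).  With ``log_events``
    every (time, die, born) triple is kept — use only for short runs.
    """
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if t_grid is None:
        t_grid = np.linspace(0.0, t_max, n_record)
    t_grid = np.asarray(t_grid, dtype=float)

    if log_events:
        return _simulate_logged(initial, inter, t_max, rng, t_grid, seed)

    counts = initial.counts.copy()
    M = np.ascontiguousarray(inter.M, dtype=np.float64)
    L = np.ascontiguousarray(inter.L, dtype=np.float64)
    H = np.ascontiguousarray(inter.H, dtype=np.float64)
    out = np.empty((t_grid.size, counts.size), dtype=np.int64)
    gi = 0
    t = 0.0
    absorbed = False
    while gi < t_grid.size:
        u = rng.random((_batch, 3))
        np.clip(u[:, 0], 1e-300, None, out=u[:, 0])  # guard log(0)
        status, t, gi = _run(
            counts, M, L, H, inter.eps1, inter.eps2, inter.eps3,
            t, t_grid, out, gi, u,
        )
        if status == -1:
            raise NegativeRateError(-1, np.nan, t)
        if status == 2:
            absorbed = True
            break
    return Trajectory(
        times=t_grid, counts=out, N=initial.N, seed=seed, absorbed=absorbed
    )


def _simulate_logged(initial, inter, t_max, rng, t_grid, seed) -> Trajectory:
    state = CommunityState(initial.counts.copy())
    t = 0.0
    events: list[tuple[float, int, int]] = []
    recorded = []
    gi = 0
    absorbed = False
    while t < t_max:
        eta = state.fractions
        if np.count_nonzero(eta) <= 1:
            absorbed = True
            break
        try:
            dt, die, born = gillespie_step(state, inter, rng)
        except NegativeRateError as exc:
            raise NegativeRateError(exc.species, exc.rate, t) from None
        while gi < t_grid.size and t_grid[gi] <= t + dt:
            recorded.append(state.counts.copy())
            # record the pre-event state at grid times inside (t, t+dt]
            recorded[-1][die] += 1
            recorded[-1][born] -= 1
            gi += 1
        t += dt
        events.append((t, die, born))
    while gi < t_grid.size:
        recorded.append(state.counts.copy())
        gi += 1
    return Trajectory(
        times=t_grid,
        counts=np.asarray(recorded, dtype=np.int64),
        N=initial.N,
        seed=seed,
        absorbed=absorbed,
        events=events,
    )


def save_trajectory(traj: Trajectory, path, metadata: dict | None = None) -> None:
    """Write a trajectory as TSV (``time  species_1 ... species_S`` counts)
    with a JSON metadata sidecar (``<path>.meta.json``: N, seed, t_max and
    any caller-supplied entries)."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    S = traj.counts.shape[1]
    df = pd.DataFrame(traj.counts, columns=[f"species_{i + 1}" for i in range(S)])
    df.insert(0, "time", traj.times)
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "N": traj.N,
        "seed": traj.seed,
        "t_max": float(traj.times[-1]),
        "absorbed": traj.absorbed,
        **(metadata or {}),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2)
    )


def fluctuations(traj: Trajectory, m: np.ndarray) -> np.ndarray:
    """Scaled deviations ``x_i(t) = sqrt(N) (eta_i(t) - m_i)`` against a
    reference equilibrium m; rows sum to zero when sum(m) = 1."""
    m = np.asarray(m, dtype=float)
    if m.shape != (traj.counts.shape[1],):
        raise ValueError(
            f"m has shape {m.shape}, trajectory has S={traj.counts.shape[1]}"
        )
    return np.sqrt(traj.N) * (traj.fractions - m)
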