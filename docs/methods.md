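# Methods

## Model

The community is a continuous-time Markov chain on integer counts
`(n_1, ..., n_S)` with `Σ n_k = N` fixed: every birth displaces a uniformly
chosen victim. The event "insert an individual of species `j`" occurs at
total rate `N·omega_j` with

    omega_j = eta_j + eps1 (M^T eta)_j theta(eta_j)
            + eps2 (L^T eta)_j eta_j
            + eps3 (H^T eta)_j theta(eta_j),

`eta = n/N`. The `N·omega_j` time scale with a uniform victim is the unique
choice whose `N → ∞` drift is `omega_s − eta_s Σ_i omega_i` term for term:
the expected change of `eta_s` per unit time is (gain from insertions of
`s`) minus (loss of `s` individuals displaced by all insertions), i.e.
`(1/N)·N·omega_s·(1 − eta_s) − (1/N)·Σ_{i≠s} N·omega_i·eta_s`.
Self-replacement (victim and newborn of the same species) is allowed; it
changes nothing and contributes no drift.

Interaction structure: `M_ij ≥ 0` (zero diagonal for ensembles; explicit
self-links allowed for hand-built cascade fixtures), `L_ij L_ji < 0` or both
zero, `H_ij < 0` with `H_ji = 0` (or both zero), and each unordered pair
carries at most one interaction type. Validators enforce all four conditions
with itemized reports.

`theta(0) = 0` exactly: an extinct species has rate identically zero, so
extinction is absorbing in both the stochastic process and the mean field.
Harm can drive a rate negative; because the hydrodynamic limit is only
meaningful for nonnegative rates, this raises an error rather than being
clipped.

## Mean field, closed form, pruning

The mean-field rhs uses the fully summed loss term
`eta_s Σ_{i} [gain_i]`, the only reading that conserves `Σ eta = 1`
(verified to machine precision). For pure cooperation on the interior of
the simplex the flow linearizes exactly: with `y(t) = exp(eps1 M^T t) eta(0)`,
the normalized trajectory `eta = y / Σy` satisfies the mean field
identically — differentiating the quotient regenerates the nonlinear loss
term. The matrix-exponential solution is therefore *exact* at every finite
`t`, not only in the limit; tests assert agreement with the ODE integrator
to `1e-8`. Its `t → ∞` limit is the normalized left Perron–Frobenius
eigenvector of `M`, independent of `eps1 > 0`.

Species with zero in-support (`Σ_j M_ji = 0` over the remaining community)
have `m_i = 0` at stationarity; deleting them can cascade. `prune_unsupported`
deletes the whole unsupported set each sweep and iterates to the fixed
point; order-independence is a tested property (random one-at-a-time
deletion oracles reach the same survivor set).

## Numerical integration

`solve_ivp` (LSODA, `rtol 1e-9`, `atol 1e-12` by default) in chunks of 25
time units. The `theta` gate makes the rhs piecewise smooth, so a terminal
event fires when the smallest living abundance reaches the extinction floor
`1e-14`; the species is clamped to exactly zero (switching its gate off, as
in the exact model), the state renormalized, the event logged, and
integration restarts. Because the event root is only solver-accurate, the
clamp uses a 10x safety band and always clamps the triggering arg-min
species. Stationarity is declared when `‖rhs‖_∞ < 1e-10` at two consecutive
chunk boundaries; hitting `t_max` first returns the best state flagged
non-converged. The harm scan uses `rtol 1e-8` and stationarity `1e-9` —
at `S = 50` this resolves abundances ~`1/S^2 = 4e-4` with three orders of
margin.

## Stability

The exact Jacobian of the mean field is used at interior states (it matches
central finite differences entrywise to `1e-6` in tests); the printed
leading-order diagonal `-eps1 S mu_M` is recovered as the dominant term.
Simplex conservation makes every column of `J` sum to the same value `-G`
(minus the total gain), so the sum-zero tangent subspace is invariant;
spectra and stability verdicts are computed after projecting onto an
orthonormal tangent basis, which removes the structural mode tied to the
simplex normal. `is_stable` requires max real part `< -1e-10`.

For random cooperative ensembles the Jacobian is, to leading order,
`-S mu_M I + (M - mu_M)`, whose spectrum fills an ellipse centred at
`-S mu_M` with semi-axes `sqrt(S) sigma_M (1 ± rho_M)`; here
`(mu_M, sigma_M, rho_M)` are the connectivity-diluted moments

    mu_Q    = c mu,
    sigma_Q^2 = c sigma^2 + c(1-c) mu^2,
    rho_Q   = (rho sigma^2 + (1-c) mu^2) / (sigma^2 + (1-c) mu^2),

so dilution induces positive pair correlation even for independent draws.
"Inside the ellipse" tests inflate the predicted ellipse by 5%, a standard
allowance for finite-`S` edge fluctuations.

Boundary states (extinct species present) are analyzed two ways, and both
are reported: (a) the surviving sub-community's Jacobian plus the
transversal re-invasion influx `eps1 (M^T m)_s + eps3 (H^T m)_s` of each
extinct species; (b) the *formal* Jacobian, which holds the theta gates at 1
— exactly the structure of the interior Jacobian formula, which contains no
gate factors — and thereby probes whether extinct species would re-invade
under rare reintroduction. The harm scan uses (b): a state reached by the
extinction cascade counts as stable only if it is robust in this sense.
This is the definition under which the scan reproduces a sharp feasibility
boundary: extinctions start only beyond a critical harmful connectivity,
and past `c_H = 0.6` no sampled community retains a feasible stable state.

The pure-exploitation reference spectrum is evaluated at uniform abundances
`m_i = 1/S`: an exactly antisymmetric `L` is a zero-sum (replicator-like)
web with no generically feasible interior equilibrium, and the uniform state
is the reference point of the small-deviation expansion `m_i = (1+xi_i)/S`.

## Linear noise

Around a positive equilibrium the scaled fluctuations
`x = sqrt(N)(eta - m)` are an OU process `dX = AX dt + Phi dB`. `A` is the
mean-field Jacobian at `m`. The diffusion `D = Phi Phi^T` is derived here by
the standard jump-moment (Kramers–Moyal) expansion of the replacement
process — an event `(die a, born b)` has rate `N omega_b eta_a` and
`x`-jump `(e_b - e_a)/sqrt(N)` — giving the closed form

    D_ij = delta_ij (omega_i + m_i Σ_k omega_k) - (omega_i m_j + omega_j m_i).

An exhaustive `S^2` event-sum oracle confirms the closed form exactly, and
the resulting Lyapunov covariance matches simulated covariances within
Monte-Carlo error (the authoritative validation of this construction).
Because jumps conserve `Σ eta`, `D` is degenerate along the simplex normal
and fluctuations live in the sum-zero subspace; the Lyapunov equation is
solved there in an orthonormal basis (residual `< 1e-8` enforced) and `V`
mapped back to `S×S` coordinates. Empirical covariances discard the first
20% of each trajectory as burn-in. The comparison of `V` and its tangent
pseudo-inverse against `M + L` (rank correlations, threshold
precision/recall sweeps) is diagnostic: covariance matrices are generically
poor proxies of the interaction network.

## RSA and CV targeting

Populations are normalized so the rarest coexisting species has population
exactly 1 (`pop = m / min m`; extinct species excluded with a logged count),
and the curve reports `P_>(n)`, the fraction of species with population
strictly *greater* than `n` — the decreasing cumulative, which is what the
verbal definition of the statistic describes (a formula transcribed with the
opposite step-function argument would count species *below* `n`; we follow
the words and note the discrepancy here).

The CV-invariance experiment drives the effective off-diagonal CV of `M`
to targets 2, 3, 4 per entry family. Two dials exist: distribution
parameters at fixed connectivity, or connectivity at fixed parameters
(`c = (1 + cv_z^2)/(1 + cv_target^2)` in closed form, since dilution only
adds variance). The default is the connectivity dial, for a structural
reason: the |Normal| family's base CV is bounded by
`sqrt(pi/2 - 1) ≈ 0.756` (folded-normal limit) and the uniform family's by
`1/sqrt(3)`, so large CVs are reachable for *every* family only by making
the network sparse. In this regime the Bernoulli dilution dominates the
entry variance and the averaged curves cluster tightly by CV rather than by
family; parameter-dial mode is retained (`mode="params"`), where
unreachable (family, CV) cells are skipped with a log entry. Each cell
averages the curves of independent matrix draws pointwise on a common log
grid (initial conditions are irrelevant for the PF-dominated stationary
state); curve distances are sup-norm (Kolmogorov-type). Default base
parameters give every family a moderate base CV (~1/3 to 1/2, the same
`mu/3` width convention as the harm ensemble).

## Ensembles and reproducibility

Cooperative pairs are present with probability `c_M` and both directions
drawn jointly: bivariate Gaussian then modulus for the |Normal| family
(pair correlation `rho` applies to the underlying Gaussian); a Gaussian
copula imposes `rho` for gamma/lognormal/uniform without altering the
marginals. Exploitation pairs draw two magnitudes and a uniformly random
orientation of the +/− signs; harm pairs place `-|z|` on one uniformly
chosen direction. Joint community generation assigns each unordered pair to
one class by a single categorical draw with probabilities
`(c_M, c_L, c_H, remainder)`, so disjoint support holds by construction.
Every stochastic routine takes an explicit `numpy` `Generator` (or seed);
experiment drivers write a JSON manifest (resolved config, seed, package
version) sufficient to re-run identically. The Gillespie inner loop is
JIT-compiled (numba) and consumes pre-drawn uniform blocks from the same
generator, so trajectories are reproducible given the seed.

## Problem sizes and study conditions

The packaged experiments use: the 7-species cycle and chain motifs; harm
scans at `S = 50`, 10 realizations per `(c_H, mu)` cell over the 0.1 grid
with `mu ∈ {0.05, 0.1, 0.3, 1}` and `|N(mu, mu/3)|` magnitudes; spectra at
`S = 400` (reduced CLI default 200); Kurtz convergence over
`N ∈ {10^2, 10^3, 10^4}` with 50 replicates; covariance validation at
`S = 10`, `N = 10^4`, 60 replicates; RSA panels at `S = 100` with 20
realizations by default and `S = 300` with 100 realizations under `--full`.

## What the generators do and do not emulate

The random ensembles capture connectivity, interaction-strength
heterogeneity, pair correlation, and the sign structure of the three
interaction classes. They do not emulate degree heterogeneity beyond
Bernoulli (no scale-free or nested topologies except through user-supplied
edge lists), environmental (extrinsic) noise, immigration/speciation, or
time-varying interactions. Passing tests therefore certify the internal
consistency of the theory (simulation ↔ mean field ↔ spectra ↔
fluctuations) under these idealized conditions, not the fit of any
particular natural community.

## Known limitations

* The linear cooperative gain with the hard `theta` gate makes the rhs
  discontinuous in its derivatives at extinction events; the integrator
  handles this by event-restart, but extremely stiff harm-dominated systems
  near multiple simultaneous extinctions can require many restarts.
* `pf_stationary` uses dense eigendecomposition (`O(S^3)`); fine to a few
  thousand species, not designed for very large sparse webs.
* The formal-Jacobian stability notion at boundary states is a modeling
  choice (re-invasion robustness); the gated dynamics alone would call any
  cascade endpoint stable.
* Boundary-state OU theory is not provided: `build_ou` requires a strictly
  positive equilibrium.
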