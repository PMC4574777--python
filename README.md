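# pafit

Nonparametric maximum-likelihood estimation of the preferential-attachment
kernel in growing temporal networks.

## The problem

Many real-world networks — citation graphs, social networks, the web — grow
by *preferential attachment* (PA): new edges attach to an existing node `v`
with probability proportional to a weight that depends only on `v`'s current
in-degree `k`,

    Pr(v acquires a new edge) ∝ A_k .

The function `A_k` is the **attachment kernel**. Its shape decides the
network's fate: the log-linear family `A_k = k^α` gives scale-free networks
at `α = 1`, stretched-exponential degree distributions for `α < 1`, and
winner-take-all condensation for `α > 1`. Whether PA operates at all in a
given system — and whether its kernel is really log-linear — is an empirical
question that must be answered from data: a recorded growth process
`G_0, G_1, …, G_T` of time-stamped edges.

`pafit` estimates `A_k` **without assuming any functional form**, one value
per degree (or per logarithmic degree bin). Writing `m_k(t)` for the number
of new edges of step `t` that land on a node of onset in-degree `k`, and
`n_k(t)` for the number of such nodes, the counts `m_0(t), …, m_K(t)` are
multinomial given the step's edge total `m(t)`, with cell probabilities
`p_k(t) = n_k(t) A_k / Σ_j n_j(t) A_j`. The log-likelihood

    l(A) = Σ_t Σ_k m_k(t) log A_k − Σ_t m(t) log Σ_j n_j(t) A_j

is maximised by the minorize-maximization (MM) fixed-point iteration

    A_k ← Σ_t m_k(t) / Σ_t [ m(t) n_k(t) / Σ_j n_j(t) A_j ] ,

which never decreases `l` and, because `l` is concave in `log A`, converges
to a *global* maximiser. The kernel is identifiable only up to scale; the
estimate is reported with `A_1 = 1`.

The package also provides:

* a simulator for the general temporal (GT) growth model under arbitrary
  kernels (`power`, `saturated_power`, `log_poly`, `constant`, `tabulated`);
* the two classical histogram estimators — Jeong's single-window histogram
  and Newman's multi-histogram — plus the *corrected* Newman estimator whose
  per-degree normaliser removes the "waterfall" artifact (the spurious
  high-degree fall-off caused by normalising every degree by the same
  constant even though large degrees exist only late in the growth);
* logarithmic binning and an optional roughness penalty on the curvature of
  `log A` vs `log k` that shrinks the fit toward log-linearity;
* fast variance approximations for the fitted kernel (dense information
  inverse, Woodbury identity, or the O(K) diagonal approximation
  `v_k = Â_k² / Σ_t m_k(t)`), log-scale confidence intervals, and
  attachment-exponent fits (weighted least squares on `(log k, log Â_k)`,
  or the cumulative-kernel slope);
* a Monte Carlo benchmark harness comparing all estimators by the average
  relative error `e_A = (1/K) Σ_k (A_k − Â_k)² / A_k²`.

## Worked example

```python
import numpy as np
from pafit import (SimConfig, make_kernel, simulate_gt, compute_suff_stats,
                   FitConfig, fit_pafit, approx_variances, fit_exponent_wls,
                   relative_error)

# grow a 2000-node network under linear preferential attachment (A_k = k)
kernel = make_kernel("power", alpha=1.0)
net = simulate_gt(kernel, SimConfig(seed_nodes=20, m_per_step=5,
                                    n_per_step=1, stop_nodes=2000, rng_seed=1))

stats = compute_suff_stats(net)            # m_k(t), n_k(t), m(t), N(t)
fit = fit_pafit(stats, FitConfig(B=20))    # 20 log bins, no penalty
var = approx_variances(fit, stats, "B_only")
exponent = fit_exponent_wls(fit.estimate, var)

print(f"converged in {fit.iterations} iterations")
print(f"A_hat at k = 2, 8, 32: "
      f"{np.round(fit.estimate.A_hat[[2, 8, 32]], 2)}")
print(f"alpha_hat = {exponent.alpha:.3f} +/- {exponent.se_alpha:.3f}")
print(f"e_A = {relative_error(kernel, fit.estimate, K=stats.K):.4f}")
```

Output:

```
converged in 3 iterations
A_hat at k = 2, 8, 32: [ 1.96  9.13 26.7 ]
alpha_hat = 0.999 +/- 0.004
e_A = 0.0103
```

The fitted kernel tracks `A_k = k` (value ≈ 2 at degree 2, ≈ 9 at degree 8,
≈ 27 at degree 32 on the `A_1 = 1` scale — degree 32 reports its log-bin's
shared value), the recovered attachment exponent is within one standard
error of the true `α = 1`, and the average relative error across all
degrees is about 1%.

The same pipeline is available from the shell:

```sh
pafit simulate --kernel power --alpha 1.0 --stop-nodes 2000 --rng 1 --out net.tsv
pafit fit net.tsv --bins 20 --out fit.tsv
pafit exponent --method wls fit.tsv
pafit estimate --method newman-corrected --bins 20 net.tsv
pafit benchmark --kernels power:1.0,log_poly:2 --replicates 10 --out errors.tsv
```

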