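# mnlnet

Binary structural covariance network estimation for ROI-by-subject brain
measurement tables, by **maximisation of the network likelihood (MNL)**.

## The problem

Structural covariance networks summarise which brain regions of interest
(ROIs) co-vary across participants — e.g. in cortical-thickness studies,
where coordinated atrophy traces neurodegeneration pathways. The common
estimators are not consistent and hinge on a tuning parameter: thresholding
absolute Pearson correlations (PPC) at a cut-off τ, or binarising the
support of an L1-penalised precision matrix (graphical lasso) at a sparsity
penalty λ. Small changes in τ or λ swing the estimated network between
nearly complete and empty.

MNL instead treats the binary adjacency matrix `W` itself as the parameter
of a proper likelihood. Each participant's vector of K standardised ROI
residuals is modelled with a Leroux-type multivariate conditional
autoregressive (CAR) prior:

    b_i ~ MVN(0, σ²_s Q),    Q⁻¹ = γ(Ŵ − W) + (1 − γ) I

where `W` is symmetric and binary with zero diagonal, `Ŵ` is the diagonal
matrix of its row sums (so `Ŵ − W` is the graph Laplacian), γ ∈ [0, 1) is a
fixed spatial-dependence strength (0.9 by convention; recovery is robust to
it), and σ²_s > 0 is a spatial scale variance. `Q⁻¹` is positive definite
for every `W` and every γ < 1, so the likelihood

    p(B | W, σ²_s) = ∏ᵢ |2π σ²_s Q|^{-1/2} exp(−bᵢᵀ Q⁻¹ bᵢ / 2σ²_s)

is well defined, and its maximiser over `W` is a consistent network
estimator: as the sample size N grows, the estimate converges to the truth.
The search is greedy coordinate ascent — sweep all K(K−1)/2 candidate
edges in fixed order, toggle any edge that strictly increases the
log-likelihood, re-estimate σ²_s by bounded quasi-Newton after each sweep,
and repeat from multiple starting networks, returning the best final
likelihood. Edge flips are rank-one perturbations of `Q⁻¹`, so each
candidate flip is scored in O(1) via the matrix-determinant lemma; a full
K = 68 fit takes seconds.

## Worked example

```python
import numpy as np
from mnlnet import (MNLNetwork, generate_solution_network,
                    network_to_covariance, sample_data, score_network)

truth = generate_solution_network(K=20, p_extra=0.1, seed=0)
omega = network_to_covariance(truth, offdiag_const=6.0)
B = sample_data(omega, n_samples=500, seed=1)
B = (B - B.mean(0)) / B.std(0, ddof=1)

est = MNLNetwork(gamma=0.9, restarts=10, random_state=0).fit(B)
s = score_network(est.adjacency_, truth)
print(f"links={int(est.adjacency_.sum() // 2)} "
      f"sensitivity={s.sensitivity:.2f} specificity={s.specificity:.2f} "
      f"sigma2={est.sigma2_:.3f}")
```

prints

```
links=49 sensitivity=0.87 specificity=0.99 sigma2=3.243
```

i.e. from 500 simulated participants the estimator recovers 87% of the 55
true links while inventing links in only 1% of the 135 empty pairs;
`sigma2` is the fitted spatial scale on the standardised-residual scale.

The same pipeline is available from the shell:

```bash
mnlnet preprocess roi.csv --covariates cov.csv --out resid.csv
mnlnet fit resid.csv --gamma 0.9 --restarts 10 --seed 0 --out-prefix run1
mnlnet simulate study.yaml --out-dir results/
mnlnet compare resid.csv --method ppc --grid 0.1,0.2,0.3 --truth net.csv --out grid.csv
```

`preprocess` regresses each ROI column on the covariates (age, sex, carrier
status, …) and standardises the residuals; `fit` writes the estimated
adjacency matrix (as a labelled 0/1 matrix and an edge list), the
log-likelihood trace and a run manifest; `simulate` runs a configurable
recovery study; `compare` sweeps a comparator's tuning grid.

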