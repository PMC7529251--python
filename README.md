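# censnet

Partial-correlation network estimation for multivariate right-censored
time-to-event data.

## The problem

Longitudinal studies often record, per subject, the times to several related
events — first diagnoses of different diseases, failures of coupled
components — and many of those times are right-censored: for a subject `n`
and event `j` only the pair `(x_nj, δ_nj)` is observed, where
`x_nj = min(t_nj, c_nj)` and `δ_nj = I(t_nj ≤ c_nj)` for a true event time
`t_nj` and a censoring time `c_nj`.  Edges of the event network are the
non-zero off-diagonal entries of the precision matrix `Θ = Σ⁻¹` of the true
times: `Θ_ij ≠ 0` means events `i` and `j` are conditionally dependent given
all other events.  Censoring biases every naive covariance estimate, which
wrecks the precision estimate downstream.

`censnet` estimates the network from censored data in four stages:

1. **Pairwise bivariate densities.**  For each event pair, each sample's
   probability mass is laid out per axis by Kaplan–Meier mass
   redistribution (uncensored → point mass; censored at `x` → KM survival
   increments beyond `x`, renormalized by `S(x)`).  The plane is then
   recursively partitioned, with an optional Pólya tree (OPT) marginal
   likelihood
   `Φ(A) = ½Φ₀(A) + ¼ Σ_m [B(N(A_m1)+½, N(A_m2)+½)/B(½,½)] Φ(A_m1)Φ(A_m2)`
   deciding whether a region stays one uniform block (density
   `N(A)/(N·|A|)`) or is split along the axis with the larger weighted
   child likelihood.
2. **Imputation.**  A censored time is replaced by the conditional tail
   expectation `E[T_j | T_j > x_nj]`, averaged over the J−1 pairwise marginal
   densities `f̂_j^(k)`, computed in closed form from the piecewise-constant
   estimates.
3. **Covariance.**  `M̂ = (1/N)(T̂ − 1μ̂′)′(T̂ − 1μ̂′)` — a Gram form, hence
   positive semidefinite by construction.
4. **Edge selection.**  Graphical lasso maximizes
   `log det Θ − tr(M̂Θ) − ρ‖Θ‖₁` along a descending penalty path; each edge
   is scored by the largest ρ at which its precision entry becomes non-zero,
   and a single network is produced at a fixed ρ or a cross-validated one.

A simulation bench (network-structured log-normal times, independent
exponential censoring) and ROC-based edge-recovery evaluation are included.

## Worked example

Simulate 300 subjects × 10 events on a scale-free truth with exponential
censoring (`λ = 1`, about 60 % censored), then estimate the network:

```bash
censnet simulate --kind scale_free -j 10 -n 300 --lam 1.0 --seed 42 -o demo/sim
# wrote 300x10 survival table with 9 true edges to demo/sim
censnet estimate -i demo/sim/survival.csv --rho 0.05 -o demo/est
# estimated 18 edges at rho=0.05
```

`demo/est/edge_scores.tsv` ranks event pairs by their penalty-entry score
(larger = the edge enters the path earlier = stronger conditional
dependence):

```text
event_a  event_b  score
event_0  event_1  0.1610314327
event_0  event_2  0.04527831419
event_0  event_3  0.1214679431
...
```

Scoring these edges against the simulated truth:

```python
import numpy as np, censnet as cn
truth  = np.loadtxt("demo/sim/truth_adjacency.csv", delimiter=",", skiprows=1, usecols=range(1, 11))
scores = np.loadtxt("demo/est/score_matrix.csv",   delimiter=",", skiprows=1, usecols=range(1, 11))
roc = cn.roc_curve(scores, truth.astype(int))
print(round(roc.auc, 3))   # 0.901
```

so despite ~60 % of the observations being censored, the penalty-entry
ranking separates true from false edges with AUC 0.90 here.  The same
pipeline is available as a library (`censnet.estimate_network`,
`censnet.run_experiment`, `censnet.lambda_sweep`).

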