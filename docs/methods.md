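# Methods

`idopnet` reconstructs informative (signed, weighted, bidirectional),
dynamic (expression-index-varying), omnidirectional, personalized gene
regulatory networks from a single static expression matrix with binary
risk labels, and tests whether two risk groups' networks differ. This
note records the model, the estimation choices, the synthetic-data
design, and the limits of what the validation shows.

## The part–whole model

Each sample (patient) is treated as an ecosystem of m interacting
genes. Its expression index (EI) is the total expression of all
analyzed genes, E_i = Σ_j g_ij. Because every gene is a part of this
whole, g_ij can be read as a function g_j(E) across samples, and the EI
replaces time as the ordering coordinate of a dynamical system.

**Allometric scaling.** The independent behavior of a gene (or module)
is the power law g_j(E) = α_j E^{β_j}. Fits minimize squared error on
the original scale (the downstream likelihood assumes additive Gaussian
noise on observed expression); ordinary least squares on log–log scale
supplies the initializer, refined by a damped Gauss–Newton step on
(log α, β) with E rescaled by its geometric mean for conditioning.
Convergence: relative objective change < 1e-8, at most 500 iterations;
the accepted step never increases the objective, so the returned fit is
never worse than the log-OLS start. Genes with fewer than three
positive values are flagged unfittable and excluded. A `scale="log"`
option keeps the log-OLS estimate as final.

**Functional clustering.** Genes are grouped into L modules by a
Gaussian mixture whose component l has a group-specific pair of mean
power curves α_{l,k} E^{β_{l,k}} (k = high/low risk) and one residual
variance per module (per-group variances behind a flag). EM alternates
responsibilities with responsibility-weighted power refits; because the
inner curve solver restarts from log-OLS, the previous curve is kept
whenever the refit would be worse, preserving EM monotonicity.
Initialization is k-means on per-gene (log α̂, β̂) features per group,
with seeded restarts (default 10; the separated synthetic cohorts used
in validation converge identically from one). L is chosen by BIC
(default; AIC available) with parameter count
L·(2 curves × groups + 1 variance) + (L − 1) mixing weights, sample
unit = gene. Module-level expression is the **sum** of member genes, so
module profiles and gene profiles obey the same part–whole identity
with the EI.

**Quasi-dynamic ODE decomposition.** Observed expression of target j in
group k is decomposed as

    y_jk(E_i) = P_jk(E_i) + Σ_{j'} P_jj'k(E_i) + e_jk(E_i),

the independent component P_jk being the target's own power curve and
each dependent component P_jj'k a degree-4 Legendre expansion in the
regulator's expression (no intercept, so a null regulator contributes
exactly zero). Residuals are iid Gaussian per node, Σ = σ² I. The rate
functions of the underlying ODE system — derivatives with respect to
EI rather than time — are recovered from the fitted P curves; an RK4
forward solve of the rates is provided as a cross-check of the
integral/derivative bookkeeping.

Two parameterizations of P_jj'k exist, chosen per granularity:

* **level** (default for gene-level systems): the basis reads the
  regulator's *observed* expression. The sample-wise co-fluctuation
  between a target and its regulator's realized level is the only
  signal that can distinguish *which* candidate regulates a target —
  every candidate's smoothed curve is a smooth monotone function of E,
  nearly collinear with the target's own free power curve and with
  every other candidate, so smooth shape alone cannot identify edges.
* **integrated** (default for module-level systems): the cumulative
  trapezoid along the EI grid of a basis in the regulator's smoothed
  (power-fitted) expression, anchored at zero at the smallest EI.
  Module systems are *closed* — the module sums are exactly the EI —
  and then the adding-up identity makes a target's detrended residual
  equal minus the sum of the other nodes' residuals; raw-value bases
  would fit target noise through that identity and corrupt the
  residual variance. Deterministic smooth columns keep the likelihood
  honest, at the price of edge-identity resolution (module-level
  networks are shape-based summaries, as in the coarse-grained
  reading).

Edge weight and sign come from the dependent curve evaluated through
the regulator's smoothed expression and anchored at zero at the
smallest EI, so that "more regulator, more target" is a positive edge
in both designs; the grid-mean gives the summary network and the value
at a sample's EI the personalized network.

**Regulator selection.** Candidates are screened per target by group
LASSO followed by adaptive group LASSO (penalty reweighted by inverse
first-stage norms). The penalized groups are varying-coefficient
co-fluctuation features — the candidate's power-fit residual times a
smooth basis of the index coordinate — because smooth-in-E structure is
non-identifying and belongs to the unpenalized block: the target's own
power prediction plus a degree-4 Legendre basis of the log index. For
closed systems the index coordinate is a pooled latent index (per
sample, the GLS solution of all nodes' curves), because the realized EI
itself carries every node's noise; for embedded systems the provided EI
is used directly. λ is tuned along a 12-point geometric path by BIC
with OLS-refit residuals per visited active set, plus the extended-BIC
model-space term 2γ log C(G, k) with γ = 0.5; admissible sets respect
the in-link cap (default 5, a Dunbar-style limit on incoming links —
the cap side is configurable) and must leave at least half the samples
as residual degrees of freedom. Coordinate descent, the refits and the
scoring run on the Gram matrix of the block-orthonormalized design in
compiled (numba) kernels; this is what makes per-permutation
re-selection in the divergence test affordable.

**Divergence test.** L1 fits every node separately per risk group
(selection included); L0 fits the pooled samples once. LR =
−2 log(L0/L1) with profile Gaussian likelihoods
−(n/2)(log 2πσ̂² + 1) per node (variances floored at 1e-12). The null
distribution comes from reshuffling risk labels with group sizes
preserved (1000 permutations by default) and rerunning the full grouped
pipeline per permutation; the threshold is the ⌈0.95·n_perm⌉-th order
statistic. The pooled model is label-invariant and computed once — an
exact saving, not an approximation. With unconstrained selection the
observed LR can be slightly negative (reported with a flag);
`nest_regulators=True` forces grouped regulator sets to contain the
pooled sets, which guarantees LR ≥ 0. No χ² calibration is offered:
model selection inside the statistic invalidates it.

**Networks.** Fitted systems become directed graphs: node value = P_ind
at the chosen EI (or grid mean), edge weight = dependent curve at the
same context, edges below 1e-6 × mean node value dropped, and a
"sign-unstable" flag set when a dependent curve's sign disagrees with
its mean over more than 20% of the grid. Pair interaction types follow
from the two directed signed effects: (+,+) synergism, (−,−)
antagonism, one-sided effects directional synergism/antagonism, (+,−)
altruism/aggression. Hubness is the summed absolute edge weight,
split into outgoing (regulator role) and incoming (regulated role)
strength; the scalar ranking uses outgoing strength. The scale-free
check is a descriptive log-log regression of degree frequency on total
degree (these networks have tens of nodes — far too few for
maximum-likelihood tail estimation), reporting "may be scale-free" when
r² ≥ 0.8 and an inconclusive flag below five distinct degrees.

## Synthetic cohorts

The generator mirrors the fitted model class so every stage has a
recoverable truth. Genes belong to modules with per-module, per-group
(α, β); per-sample target EIs are uniform over the EI window; module
αs are rescaled so the summed expectations match the target EI at
mid-range (the part–whole premise); per-gene Gaussian noise has a
coefficient of variation of 5–20% of the gene's mid-range level.
Samples are analyzed by their realized EI — the sum of the generated
genes — and the target EI is only a generation device; the gap between
the two is pure aggregate noise when exponents are 1 and shrinks as
genes are added.

Regulations are sparse signed gene-to-gene links, at most 3 incoming
per target. The effect on a target is sign × strength × s(x), where x
is the regulator's *realized intrinsic* level (a gene responds to the
abundance actually present in the sample; a two-stage draw keeps
cycles well-defined) and s blends a linear rise with a saturating
logistic switch (transition width 0.12 of the regulator's normalized
range; switch-like dose response is the biologically typical,
cooperative-binding case). The response is standardized to zero mean
and unit variance over the EI window, so `strength = k × noise sd`
means a k-fold signal-to-noise ratio by construction. Default cohorts:
6 modules of 10–40 genes, groups of 60 and 30 samples, EI window
600–1400 (per-gene intensities of order 1–10, matching normalized
microarray scales).

What the generator does **not** emulate: count-data noise, batch
effects, missingness, curve families other than power laws, and
regulation mediated by anything but a single regulator's level.
Passing tests therefore show that the estimator recovers the model
class it assumes at realistic noise — not that real cohorts satisfy
those assumptions.

## Validation scales and what they show

* Power recovery: n = 200 samples, 10% CV; estimates within 3 SE,
  optimum cross-checked against a dense grid search.
* Module-count selection: 3 well-separated modules, 300 genes, 90
  samples, 20 seeds, BIC over L = 1..6.
* Regulator selection and sign fidelity: 10-node systems at 5× SNR
  *embedded* in 100-gene cohorts whose full EI is the regression axis
  — the fine-grained regime, where edge identity is actually
  identifiable. Closed systems are validated through the divergence
  test instead.
* Divergence test: 5 modules × 8 genes, 40 + 20 samples, 200
  permutations; 100 null cohorts for type-I error, 100 sign-flip
  cohorts (one module-level edge, realized as a hub-gene-to-module
  bundle with summed signal sd = 5 × module sd) for power.

These sizes keep the full validation within minutes-scale runtimes
while preserving the statistical structure of the full-size problem;
the pipeline itself runs unchanged at larger scales (a 300-gene,
L ≤ 10 clustering completes in a few minutes single-core).

## Known limitations

* Edge identity in closed (module-level) systems is weakly identified
  in principle; module networks should be read as shape-based
  summaries, with the permutation test carrying the inferential
  weight.
* The decomposition of a smooth trend between independent and
  dependent components is pinned by co-fluctuation; in the noiseless
  limit the split is ambiguous and the reported dependent share is
  conservative.
* Gaussian residuals only; count-based likelihoods are out of scope.
* The EI is computed over the retained (analyzed) gene set, and module
  subsets keep the full analyzed EI as their axis; both conventions
  are configurable but changing them changes the meaning of every
  downstream curve.
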