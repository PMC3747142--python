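# Methods

## Statistical model

The data are a cohort of n subjects, each with a symmetric non-negative
node×node connectivity matrix (node count d, m = d(d−1)/2 undirected edges),
a behavioral measure of interest y, and covariates Z (age, gender by
default).  The per-edge statistic is the partial Spearman correlation: edge
weights, y and each covariate are converted to average-tie ranks, the edge
ranks and y ranks are residualized on [1, Z-ranks] by least squares, and the
residuals are Pearson-correlated.  Spearman is the default because
streamline counts and clinical scores are typically non-normal and tie-prone;
a Pearson mode is available.  Under permutation only y is reordered —
covariates and weights keep their subject order — so exchangeability of y
given Z is the null hypothesis actually tested.

Inference is by permutation.  N orderings of y are drawn (N−1 uniform
shuffles plus the observed order, which is always the last entry), giving
the m×N field r_k^(i).  Because permuting raw values and re-ranking equals
permuting ranks, and because weights/covariates never change, the whole
field reduces to one n×m rank-residual matrix times an n×N matrix of
reordered residualized y-ranks — a single BLAS call, which is what makes
N = 10000 at m = 4005 cheap.

**Cluster statistic.**  Given a signed cluster-forming threshold τ_init,
the supra-threshold edge set is {k : r_k < τ} (negative side) or
{k : r_k > τ} (positive side), strict inequalities.  Clusters are connected
components of the graph formed by exactly those edges (edges adjacent when
they share an endpoint node), computed by union-find with deterministic
output order (decreasing size, ties by smallest edge index).  The null
statistic is the maximum cluster extent M_i per ordering (0 when no edge is
supra-threshold); each observed cluster of size s_j gets

p_j = #{i : M_i ≥ s_j} / N.

The count is non-strict and includes the observed ordering, so the test is
exact (p_j ≥ 1/N) and p_j is non-increasing in s_j.  The corrected level is
valid for any τ_init; the identified sub-network is not invariant to it,
hence the threshold sweep.

**Per-edge p-values** are directional (proportion of orderings with r at
least as extreme on the analysis side; two-sided mode available) and serve
two roles: the uncorrected column of the edge report, and the input to the
Bonferroni/FDR comparators.  They agree closely with the analytic
approximation via t = r√(df/(1−r²)), df = n−2−#covariates (rank correlation
of the two p vectors > 0.99 on null data; recomputed by
`scripts/acceptance.py`).  The t map is monotone and super-linear in r, so
τ_init needs finer control at large |r| and large n.

**Comparators.**  All three run within one sign family (edges with negative,
resp. positive, observed correlation; m_eff = family size), which is already
less conservative than pooling: (a) Bonferroni rejects p < α/m_eff (strict);
(b) BH-FDR applies the step-up rule — largest p_(k) ≤ qk/m, everything at or
below it rejected; (c) extreme statistics uses the per-ordering extreme
correlation over all testable edges (min for the negative side, max for the
positive) as the null representative; the global threshold τ_ext is the
⌈αN⌉-th order statistic of that null, and per-edge corrected p counts
orderings whose representative is at least as extreme as the observed r
(non-strict, mirroring the cluster p).  With m = 1 this collapses to the
one-sided single-edge permutation test.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `tau_init` | −0.39 | cluster-forming threshold on r (signed; sign selects the analysis side). The default matches a typical negative-side analysis; always sweep. |
| `n_permutations` | 10000 | permutation-p resolution 1/N = 1e−4; use ≥ 100 for any reported result |
| `method` | spearman | rank-based; `pearson` available |
| `min_count` | 3 | per-subject streamline floor: entries strictly below are zeroed (boundary kept); reduces tracking artifact |
| `alpha` | 0.05 | cluster-level FWER level |
| sweep grid | −0.5…0.5, step 0.01 | 100 thresholds, τ = 0 excluded as degenerate (it would merge the analysis sides); one permutation draw shared across the grid for comparability |
| stability | drop 10%, B = 20 | plain random subject subsets, no demographic matching |

Degenerate inputs: a constant behavioral measure (after residualization) is
an error; constant edges (zero weight variance) are flagged, carry r = 0 and
p = 1, are excluded from the extreme-statistics representative and reduce
the m_eff used by Bonferroni/FDR.  τ = 0 requires an explicit side.
Matrices must be symmetric within max|A−Aᵀ| ≤ 1e−8·max|A| (then symmetrized
as (A+Aᵀ)/2, diagonal zeroed); the streamline filter is applied per subject
— the alternative (a group-level mask) is equally defensible, and the choice
is documented rather than asserted.

## Synthetic cohorts

`SyntheticSpec` emulates the shape of a DTI streamline-count study: default
90 nodes, 40 subjects; background edges present per subject with probability
0.3 and log-normal counts (log-mean 3, log-sd 1, rounded to integers); a
half-normal severity score (scale 3) rounded to 0.5 steps and capped at 18,
deliberately skewed and tie-prone to exercise the rank machinery (a
continuous-score mode exists for calibration studies); age ~ N(72.5, 6.7²),
gender ~ Bernoulli(0.4).  Planted effects: a connected k-edge sub-network
grown by a seeded random walk; its edge weights share the score's Gaussian
copula latent at Pearson level ρ_P = 2·sin(πρ_S/6), the exact conversion
making the *continuous* weights' population Spearman correlation equal the
requested ρ_target.  Rounding weights and score attenuates the realized rank
correlation slightly; the suite measures the residual bias (≤ 0.05 at
n = 2000) rather than assuming it away.

What the generator does **not** emulate: spatial topology (small-world or
modular structure), the strong inter-edge dependence of real tractography
(shared acquisition quality, global streamline yield), consistent
edge-presence patterns across subjects, or demographically matched subsets.
Passing tests therefore demonstrate error control and relative sensitivity
under near-independent edges — real data's positive dependence makes the
max-statistic procedures *less* conservative, not more, so FWER control
transfers, but absolute power numbers do not.

## Simulation suites and problem sizes

Validation runs use shrunk shapes chosen once: 30-node networks (m = 435),
n = 40.  FWER control: 200 null cohorts, N = 1000, τ = −0.35 — the
empirical fraction with any cluster p ≤ 0.05 must sit in the binomial 95%
band 0.05 ± 2√(0.05·0.95/200) ≈ [0.019, 0.081].  Sensitivity ordering:
20 planted-effect cohorts (k = 20, ρ_target = −0.5), τ = −0.35, N = 1000,
requiring cluster ≥ extreme ≥ Bonferroni true-positive edges in ≥ 18/20
runs.  N = 1000 here preserves the structural regime of full-scale
correlational connectomics, where the Bonferroni level α/m_eff lies *below*
the permutation-p floor 1/N (at full scale: 0.05/1356 < 1/10000): under
that regime Bonferroni cannot assert single edges, which is precisely the
motivation for cluster-based correction.  At N large enough to invert that
inequality, sign-family Bonferroni (m/2 tests) can overtake whole-family
extreme statistics under independent edges — a Šidák-vs-Bonferroni effect
absent in dependent real data — so the shrunk suite keeps the inequality.

## Design choices that were genuinely open

- **Cluster-p inequality**: non-strict (M_i ≥ s_j), observed ordering
  included — guarantees exactness and p ≥ 1/N.
- **Per-edge p directionality**: directional by analysis side (the sign
  families are corrected separately); two-sided offered.
- **Partial Spearman construction**: partial Pearson on average-tie ranks
  (the standard definition; reproducible and oracle-checkable).
- **Extreme-statistics quantile**: τ_ext is the ⌈αN⌉-th order statistic of
  the representative null; per-edge extremeness non-strict.
- **RNG**: a single numpy `default_rng` seed per operation; permutations by
  successive Fisher–Yates shuffles; every stochastic output is
  bit-reproducible from (inputs, seed).

## Known limitations

- A monotone (rank-linear) edge–behavior relationship is assumed; quadratic
  or threshold relationships need a different per-edge statistic.
- The identified sub-network depends on τ_init (only its p-value is
  τ-robust); the sweep plus stability utilities mitigate, not remove, this.
- Analytic tie-corrected Spearman p-values are not implemented; the
  permutation p is primary and the t approximation is a cross-check.
- Threshold-free cluster enhancement is deliberately out of scope.
- Subset stability does not match demographics across subsets.
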