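# netclust

Cluster-based permutation statistics for identifying sub-networks of a brain
connectivity graph whose edge weights correlate with a behavioral measure.

## The problem

In edge-wise correlational connectomics one asks, for every connection of a
brain network (e.g. the 90×89/2 = 4005 edges of an AAL90 streamline-count
network), whether its weight correlates with a score of interest — disease
severity, IQ, age.  Correcting 4005 weakly-powered tests with Bonferroni
pushes the per-edge level to ≈0.00001, which biomedical effect sizes rarely
reach.  `netclust` implements a less conservative family-wise error (FWER)
correction built on the insight that *sets of neighboring connections*, not
single edges, carry behavioral effects — the correlational analogue of the
network-based statistic (NBS) used for group comparisons.

## The method

For each edge *k* and each of *N* reorderings *PV_i* of the behavioral
measure (the last being the observed order), compute the partial Spearman
correlation r_k^(i) between edge weight and the reordered measure,
controlling covariates such as age and gender (only the measure is
reordered; covariates keep their subject order).  Given a signed
cluster-forming threshold τ_init, edges with r < τ_init (negative side; r >
τ_init positive side) are grouped into connected clusters; the edge count of
the largest cluster under reordering *i* is the representative statistic
M_i.  Each observed cluster C_j of size s_j gets the corrected p-value

    p_j = #{ i : M_i ≥ s_j } / N ,

which controls the FWER for any choice of τ_init.  The three standard
comparators — Bonferroni, Benjamini–Hochberg FDR, and extreme statistics
(permutation null of the most extreme correlation across edges) — are
included, run within the negative/positive sign families separately.  A
synthetic-connectome generator with Gaussian-copula planted effects provides
ground truth for validating error control, sensitivity, and calibration.

## Worked example

```python
from netclust import NetworkCorrelation, SyntheticSpec, generate_cohort

cohort, behavior, planted = generate_cohort(
    SyntheticSpec(n_subjects=40, n_nodes=30, planted_k=20,
                  rho_target=-0.5, seed=7))
model = NetworkCorrelation(cohort, behavior)          # covariates: age, gender
res = model.fit(tau_init=-0.35, n_permutations=10000, seed=8)
print(res.summary())
```

```
Cluster-based network-behavior correlation
==========================================================
subjects: 40    nodes: 30    edges tested: 435 (+0 constant)
method: spearman partial correlation | covariates: age, gender
permutations: 10000    seed: 8
initial threshold tau = -0.350 (negative side)    alpha = 0.05
----------------------------------------------------------
 cluster  edges  nodes  corrected p
       0     22     21       0.0001 *
       1      1      2       0.9987
----------------------------------------------------------
null max extent: median 2, 95th pct 6, max 22
```

The fitted cohort carries a 20-edge planted sub-network whose weights
rank-correlate at −0.5 with the severity score.  The analysis recovers it as
a 22-edge cluster at the smallest attainable corrected p (1/N = 0.0001),
while a typical null reordering's largest cluster has only ~2 edges.  The
comparators on the same fit assert far less:

```python
print(res.bonferroni(alpha=0.05).one_line_summary())
print(res.fdr(q=0.05).one_line_summary())
print(res.extreme(alpha=0.05).one_line_summary())
```

```
bonferroni: level=0.05, m_effective=239, threshold=0.000209205, significant=2
fdr_bh: level=0.05, m_effective=239, threshold=0.0008, significant=5
extreme: level=0.05, m_effective=435, threshold=-0.563755, significant=1
```

`res.report()` emits the clinical-style edge table ("connection, r,
uncorrected p", sorted by |r|, cluster-level corrected p in the header);
`model.threshold_sweep()` scans τ_init over −0.5…0.5 (step 0.01, 0
excluded) with one shared permutation draw, and
`model.subsample_stability()` reruns the analysis on random subject subsets.

The same pipeline is scriptable from the shell:

```bash
netclust simulate --out sim --n-subjects 40 --n-nodes 30 \
    --planted-k 20 --rho -0.5 --seed 7
netclust run --matrices 'sim/S*.csv' --behavior sim/behavior.csv \
    --measure severity --covariates age,gender --tau -0.35 \
    --n-perm 10000 --seed 8 --out out
```

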