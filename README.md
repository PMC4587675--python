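# betanova

Robust and efficient one-way ANOVA for differential gene expression.

Bulk microarray and expression studies routinely test each of thousands of
genes for a mean difference across two or more conditions with a one-way
ANOVA F-test.  A single corrupted intensity — a hybridisation artefact, a
scanning spike, a bad array — inflates a group's variance estimate and can
silence a genuinely differential gene (or, after partial correction,
manufacture a false one).  Fully robust alternatives pay for their safety
with lost efficiency on the clean majority of genes.

`betanova` implements a *hybrid* of the two regimes for analysts running
gene-level condition comparisons.  Each group's Gaussian parameters
θ_j = (μ_j, σ²_j) are estimated twice: by maximum likelihood, and by the
minimum β-divergence method — an iteratively reweighted fit

    μ'  = Σ_k W_β(x_k) x_k / Σ_k W_β(x_k)
    σ²' = (β + 1) Σ_k W_β(x_k) (x_k − μ)² / Σ_k W_β(x_k)

whose weight function W_β(x | θ) = exp{−β (x − μ)² / (2σ²)} ∈ (0, 1]
suppresses observations far from the bulk (β = 0 recovers the MLE exactly).
Because −(2/β) log W_β is a χ²₁ pivot under the fitted Gaussian, the p-th
null quantile of the weight has the closed form
δ = exp{−(β/2) χ²₁,₁₋ₚ}, and an observation with W_β ≤ δ is declared an
outlier.  The hybrid rule keeps the efficient MLE for every group with no
flagged observation and switches to the robust fit otherwise.  The
resulting estimates drive:

* **F_β** — the one-way ANOVA F-statistic with hybrid plug-ins,
  F_β = [Σ_j n_j (μ̂_j,β − μ̂_β)² / (m−1)] / [Σ_j n_j σ̂²_j,β / (n−m)],
  with parametric p-values from F(m−1, n−m) or per-gene permutation
  p-values;
* **LSD_β** — a robustified Fisher least-significant-difference test,
  LSD_β = t_{α/2,n−m} √(MSE_β (1/n_i + 1/n_j)), for the m(m−1)/2 pairwise
  comparisons after a significant omnibus test, aggregated into an
  expression pattern (the partition of conditions into equal-mean classes)
  plus 2-fold up/down-regulation calls;
* a seeded **simulation and benchmark layer** that regenerates the
  synthetic studies used to characterise the method (Gaussian one-way
  layouts, DE/EE gene mixtures, additive outliers x* = d + max(gene), with
  d ~ U(5, 10)) and scores methods by TPR/FPR/FDR/MER, full-ranking AUC and
  partial AUC at FPR ≤ 0.2.

## Worked example

Simulate a small two-condition study (2,000 genes, 60 DE, 10% of genes
carrying one additive outlier) and test it:

```bash
betanova simulate -o demo/study --genes 2000 --de 60 --outlier-fraction 0.1 --seed 42
betanova test -i demo/study_matrix.tsv -g demo/study_groups.tsv \
              -o demo/results.tsv --outlier-report demo/outliers.tsv --adjust bh
```

The top of `demo/results.tsv`, sorted by F_β:

```
   gene_id   f_stat      p_value  p_adjusted  n_outliers source_g1 source_g2
gene_01502 2657.950 8.471660e-07    0.001694           0       mle       mle
gene_00249  645.103 1.426980e-05    0.011097           0       mle       mle
gene_00043  451.939 2.894760e-05    0.011097           0       mle       mle
```

`f_stat` is F_β with (df1, df2) = (1, 4) here; `source_g1`/`source_g2`
record, per condition, whether the efficient MLE or the robust β-divergence
estimate was used.  At BH-adjusted p ≤ 0.05 this run declares 45 genes
differential, 42 of them truly DE.  The outlier report lists each flagged
observation with its β-weight and the threshold δ:

```
   gene_id sample_id    value       weight    delta
gene_00014     g1_s2  8.27919 5.312980e-19 0.142112
gene_00017     g1_s2 12.63850 0.000000e+00 0.142112
```

All 200 injected outliers are flagged (weight ≤ δ = 0.142 at β = 0.2,
tail probability 10⁻⁵), and no clean observation is.

For m > 2 conditions, `betanova pairwise` expands significant genes into
per-pair LSD_β decisions, p-values, 2-fold direction calls and the inferred
expression pattern (e.g. `{1,2}|{3,4}`); `betanova weights` reports the
β-weight of every observation; `betanova benchmark` scores methods on
replicate synthetic studies from a YAML scenario.

The same functionality is available as a library:

```python
from betanova import BetaConfig, SimulationSpec, generate_dataset, hybrid_f_batch

spec = SimulationSpec(m=2, sizes=(3, 3), n_genes=5000, n_de=75, seed=0)
data = generate_dataset(spec)
res = hybrid_f_batch(data.values, data.group_labels, BetaConfig())
```

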