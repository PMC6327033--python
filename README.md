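# rumengwas

Metagenome-wide association and cross-population phenotype prediction for
rumen microbiome abundance data.

Dairy cattle differ substantially in how efficiently they convert feed into
milk, and part of that variation is carried by the rumen microbiota. Given
whole-metagenome contig abundances (counts per million, CPM) for a herd of
cows phenotyped for feed efficiency (FE = milk yield / dry matter intake) and
intake (DMI), this package answers three questions:

1. **Which contigs are associated with the phenotype?** An agnostic funnel:
   prevalence filtering → information-gain pre-selection → per-contig
   logistic regression (a *metaGWAS* over contigs).
2. **Do the associated contigs separate high- from low-efficiency animals?**
   Hierarchical clustering of animals with multiscale-bootstrap cluster
   support (BP and approximately-unbiased AU p-values), plus PCA and nested
   intake-within-efficiency clustering.
3. **Do they predict the phenotype in an independent herd?** An L1-penalized
   linear model fitted on the reference herd, scored by Pearson correlation
   in a validation herd, and benchmarked against a null distribution from
   random contig subsets of the same size.

A fully synthetic data generator emulates the paired reference/validation
study design (30 + 31 animals, compositional overdispersed counts, planted
contig–phenotype signal with partial cross-population sharing), so the whole
pipeline is testable without any sequencing data. It is aimed at
quantitative-genetics and microbiome researchers who want a transparent,
seeded, end-to-end reimplementation of this analysis style.

## The statistics at the core

**Information gain.** For contig *k* with CPM vector *x* over animals in
groups HIGH/LOW, with maximum-likelihood standard deviations σ (pooled) and
σ_H, σ_L (within-group):

    H(σ)  = log2(σ · √(2πγ))                         (Gaussian entropy, bits)
    IG_k  = H(σ) − [N_H·H(σ_H) + N_L·H(σ_L)] / (N_H + N_L)

The constant γ cancels exactly between the two terms; with ML (divide-by-N)
SDs, IG ≥ 0. Contigs in the top 95th percentile of IG (⌈0.05·p⌉ of them) are
pre-selected — for the assembled universe of 175,969 contigs that is 8,799.

**metaGWAS.** Per contig, logistic regression of group (HIGH=1, LOW=0) on the
(z-standardized) CPM; Wald test on the slope; significant at raw α = 0.05.
Complete separation is detected and reported, not silently fitted.

**Cluster support.** Animals are clustered on log2(CPM+1) of the significant
contigs (correlation distance, UPGMA). Contigs are resampled with replacement
at scales r ∈ {0.5, …, 1.4}; each edge's bootstrap probability BP_r is the
fraction of replicates containing its exact leaf set, and the AU p-value
comes from the probit extrapolation ψ(r) = Φ⁻¹(1−BP_r) ≈ v√r + c/√r, with
AU = 1 − Φ(v − c).

**Prediction.** β̂ = argmin ½‖y − Xβ‖² + nλ‖β‖₁ by cyclic coordinate descent
(soft-thresholding, warm-started penalty path, λ chosen by 5-fold CV);
validation accuracy r = cor(ŷ*, y*) with ŷ* = y₀ + x*β̂; the null refits the
model on random same-size contig subsets (1,000 replicates by default).

## Worked example

```python
import rumengwas as rg

cfg = rg.PipelineConfig(rng_seed=0, n_null_replicates=200)
res = rg.run_pipeline(cfg, n_boot_per_scale=300)
print(res.manifest.results)
```

prints (seed 0, default synthetic conditions):

```
{'trait': 'fe', 'cluster_accuracy': 1.0,
 'top_cluster_au': [0.9953, 0.9973],
 'validation_pearson_r': 0.4350, 'lambda': 0.0201,
 'n_active_coefficients': 8,
 'null': {'n_replicates': 200, 'n_undefined': 82, 'subset_size': 47,
          'mean': 0.1373, 'sd': 0.2297, 'q2.5': -0.3397, 'q97.5': 0.5685,
          'observed': 0.4350, 'observed_percentile': 88.98}}
```

Reading this: the 47 contigs surviving the funnel cluster the 30 reference
animals into their HIGH/LOW efficiency groups perfectly (accuracy 1.0), and
both top clusters have AU ≈ 0.995–0.997, i.e. strong bootstrap support. The
model fitted on those contigs predicts FE in the independent 31-animal herd
with r = 0.44, while random 47-contig subsets average r = 0.14 (95% of the
defined replicates between −0.34 and 0.57; 82 of 200 shrank to the intercept
and have no defined correlation) — the selected contigs sit at the 89th
percentile of that null, so they carry information beyond what a random
slice of the metagenome provides.

The same stages are available from the shell:

```bash
rumengwas simulate --seed 4 --out-dir sim/
rumengwas run-all --seed 1 --out-dir run/        # full pipeline + manifest
rumengwas infogain sim/cpm.tsv sim/reference_phenotypes.csv --out ig.tsv
```

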