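# cotwin

Co-twin control screening of gut-microbiome and plasma-metabolome data.

Cross-sectional microbiome case/control comparisons are dominated by
inter-individual variability and confounding (diet, BMI, antibiotics,
host genetics). The co-twin control design suppresses most of it: the
healthy co-twin of a disease-discordant twin pair shares genetic
background, early-life environment, and household with the affected twin,
so within-pair contrasts isolate disease-linked differences. `cotwin`
implements a layered ("pyramid") version of this design for cohorts of
monozygotic (MZ) and dizygotic (DZ) twins with a binary mental-disorder
(MD) phenotype, together with a synthetic twin-cohort generator with
recorded ground truth, so the whole analysis is testable without access
to restricted registry data.

The five analysis layers are:

* **a** — MZ discordant pairs, per-feature two-sided Wilcoxon signed-rank
  tests on within-pair differences (MD − healthy co-twin);
* **b** — the same for DZ discordant pairs;
* **c** — all discordant pairs combined;
* **d** — healthy co-twins vs *all* MD twins, per-feature linear mixed
  model adjusting for individual-level confounders;
* **e** — all healthy twins vs all MD twins, same model.

Layers d/e use a zygosity-stratified random-intercept Gaussian model:

    Y_i = α_{Z, j[i]} + X_i β + ε_i,      ε_i ~ N(0, σ²)
    α_{MZ,j} ~ N(0, σ²_MZ),   α_{DZ,j} ~ N(0, σ²_DZ)

so twin relatedness is estimated separately per zygosity; MD status is
the fixed effect of interest and age, sex, BMI, antibiotics use, and
vegetable/fruit intake are covariates. Per-feature p-values are
Benjamini–Hochberg adjusted within each feature family. A feature that is
significant in every layer where it was tested is flagged *consistent* —
the design's candidate-biomarker notion. Differential genera and
differential predicted pathways are then linked by a Spearman correlation
network (edges at |ρ| > 0.2, FDR < 0.05).

Supporting stages implement the field-standard preprocessing: sequencing
depth and rare-taxon filters, genus agglomeration, centered log-ratio
(CLR) transform for compositional counts; log(1+x) + z-scaling with a 25%
missingness rule and median imputation for metabolites; Bray–Curtis /
Euclidean within-pair vs outside-pair dissimilarity comparisons with a
Shapiro–Wilk-gated t / rank-sum test.

## Worked example

Simulate a default cohort (97 MZ + 122 DZ pairs, 41 genera of which 3
carry true MD effects, 60 metabolites, 30 predicted pathways) and run the
full pipeline:

```python
import cotwin
from cotwin.config import PipelineConfig

cohort = cotwin.simulate_cohort(cotwin.SimConfig(seed=3))
results = cotwin.run_all(PipelineConfig(outdir="out", seed=3), cohort=cohort)
print(cohort.truth.affected_genera)
# {'g014': 1.0, 'g024': -1.0, 'g031': 1.0}
```

`out/report.md` then contains (abridged):

```
- MZ prevalence: 35.1%; proband-wise concordance: 68%
- DZ prevalence: 36.9%; proband-wise concordance: 38%
- microbiome within_vs_outside: wilcoxon_rank_sum p=2.52e-46 (means 0.3988 vs 0.4953)
- microbiome mz_vs_dz_within: t p=6.54e-08 (means 0.3639 vs 0.4265)
- layer a (genus): 8 / 41
- layer d (genus): 4 FDR-significant, 5 at raw p<0.05, n=41
- genus: 11 features ticked anywhere; consistent across all tested layers:
  ['g014', 'g024', 'g031']
- retained edges: 5
```

Reading this: the simulated MZ pairs are more phenotypically concordant
(68% vs 38%) and compositionally more similar (within-pair Bray–Curtis
0.364 vs 0.427) than DZ pairs, mirroring the structure twin cohorts show;
the three spiked genera — and only they — survive every layer of the
pyramid, and the network recovers each genus's dedicated pathway (e.g.
`g024–ko001`, ρ = 0.90). The same pipeline is scriptable from the shell:

```bash
cotwin simulate --seed 3 --out sim/
cotwin cohort --metadata sim/metadata.tsv
cotwin pyramid --features prep/genus_clr.tsv --metadata sim/metadata.tsv \
       --layers a,b,c --out pyr/
cotwin lmm --features prep/genus_clr.tsv --metadata sim/metadata.tsv \
       --setup d --fdr 0.2 --out layer_d.tsv
```

The built-in 219-pair example cohort reproduces the familiar twin-study
summary statistics exactly from its pair counts: proband-wise concordance
2C/(2C+D) of 61% (MZ) and 36% (DZ), individual prevalences 37.1% and
29.5%:

```python
from cotwin.datasets import example_pair_counts, metadata_from_pair_counts
from cotwin.cohort import cohort_summary
s = cohort_summary(metadata_from_pair_counts(example_pair_counts()))
```

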