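# cimpscan

Genome-wide DNA methylation analysis of matched tumour/normal cohorts on
Illumina-450K-style arrays, centred on the CpG island methylator phenotype
(CIMP) in colorectal cancer. The package takes probe-level methylated (M)
and unmethylated (U) intensities, classifies tumours into CIMP-H / CIMP-L /
CIMP-N subtypes by unsupervised clustering, calls gene-level CpG-island
hypermethylation in every tumour/normal pair, and scores genes by how
consistently they are hypermethylated within each subtype — the route to a
"core hypermethylome" shared by all CIMP-H tumours against a stochastic
background of sporadic events.

It is written for methylation-array analysts who want the full chain —
probe QC through core-gene discovery — as tested, scriptable library code,
with a synthetic-cohort generator so every stage can be exercised and
validated without any external download.

## The analysis

1. **Preprocessing.** Beta values are computed as
   `β = M / (M + U + 100)` ∈ [0, 1). Probes failing detection
   (p > 0.05 against negative controls), sex-chromosome probes and
   cross-reactive probes are removed; intensities are rescaled per sample
   so internal control probes share a common mean; chip (batch) effects
   are removed with a parametric empirical-Bayes location–scale
   adjustment.
2. **Differential CpGs (SAM).** Each probe gets a modified t-statistic
   `d = (x̄_tumour − x̄_normal) / (s + s₀)` with an exchangeability
   constant s₀ chosen to minimise the coefficient of variation of d
   across the spread of per-probe errors; significance comes from
   permutation of group labels (q values). The top-K probes by |d| feed
   the clustering.
3. **Subtyping.** Samples are clustered with Euclidean distance and
   complete linkage. The dendrogram is cut into a tumour-like and a
   normal-like branch; tumours in the normal branch are CIMP-N, and the
   tumour branch is cut into three subclusters ranked by mean methylation:
   CIMP-H > CIMP-L > CIMP-N.
4. **Island calling.** For every gene, its CpG-island and island-shore
   probes are pooled and each tumour/normal pair is tested with the
   Wilcoxon signed-rank test. A gene is *hyper* in a tumour when the
   Benjamini–Hochberg adjusted p < 0.005 **and** the tumour-minus-normal
   mean beta difference Δβ ≥ 0.1. The Δβ threshold can be selected by
   scanning a grid for the value that maximises the difference in mean
   per-tumour hyper counts between CIMP-H and CIMP-N.
5. **Frequency scoring.** Genes are scored per subtype by the fraction of
   tumours calling them hyper; core sets are the genes above a frequency
   threshold (strictly above below 100%, exactly all tumours at 100%).
6. **Clinical statistics.** Two-sided Fisher exact tests (binary
   variables), Welch t tests from group summaries (continuous), the
   five-gene marker panel classifier (CACNA1G, NEUROG1, RUNX3, SOCS1,
   IGF2: >3/5 methylated → CIMP-H, 1–3/5 → CIMP-L, 0/5 → CIMP-N), and
   cluster-vs-panel concordance.

## Worked example

```python
from cimpscan.pipeline import PipelineConfig, run_pipeline
from cimpscan.synthetic_cohort import generate_default_cohort

cfg, manifest, ds, truth = generate_default_cohort(seed=1)
result = run_pipeline(PipelineConfig.default_synthetic(sam_seed=1),
                      ds=ds, manifest=manifest)

print(result.cimp.group_sizes())
print("delta threshold:", result.chosen_delta)
print(result.group_summary[["group", "n_tumours", "mean"]])
print("core genes (100% of CIMP-H):", len(result.core_sets[("CIMP-H", 1.0)]))
```

prints

```
{'CIMP-N': 20, 'CIMP-H': 14, 'CIMP-L': 6}
delta threshold: 0.1
    group  n_tumours    mean
0  CIMP-H         14  188.00
1  CIMP-L          6  155.50
2  CIMP-N         20    5.05
core genes (100% of CIMP-H): 132
```

The cohort is the generator's standard one: 40 matched pairs (14/6/20
planted CIMP-H/L/N tumours, two of the CIMP-N generated with
normal-tissue parameters), 2,000 genes with a planted core set of 132.
The pipeline recovers the planted subtypes exactly, selects Δβ = 0.1 from
the scan grid as the threshold maximising CIMP-H vs CIMP-N separation,
and the 132 genes hypermethylated in 100% of CIMP-H tumours are exactly
the planted core. Per-tumour hyper counts fall on a continuum — high in
CIMP-H, intermediate in CIMP-L, low in CIMP-N — with the subtype means
ordered as shown.

The same run is available from the shell:

```bash
cimpscan synth-cohort --seed 1 --out cohort/
cimpscan run --config run.yaml          # run.yaml points input_dir at cohort/
```

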