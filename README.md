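# itrap

Denoising of single-cell TCR-pMHC immune profiling data.

Single-cell platforms that pair TCR αβ sequencing with DNA-barcoded pMHC
multimers promise direct, high-throughput readout of T cell specificity, but
the raw droplet (GEM) data is dominated by ambient multimer capture and
barcode leakage: most GEMs report several pMHCs, and UMI counts mix real
binding with noise. This package identifies reliable TCR-pMHC pairs by
analysing GEMs in clonotype ensembles instead of individually, for
immunologists and ML practitioners who need clean TCR-specificity pairs out
of 10x-style immune profiling runs.

The core steps, each usable on its own:

1. **Clonotype redefinition** at the amino-acid level
   (Vα Jα CDR3α / Vβ Jβ CDR3β), with UMI-based chain-multiplet resolution and
   unambiguous missing-chain imputation.
2. **Expected-binder annotation**: within each clonotype of ≥ 10 GEMs, the
   candidate pMHC (highest mean UMI) is accepted iff its UMI distribution is
   significantly higher than every competitor's (one-sided rank-sum,
   α = 0.05; exact under ties for small samples).
3. **Data-driven UMI thresholds**: an exhaustive grid search for the cutoffs
   (minimum pMHC UMI, top/second UMI ratio, minimum TCR chain UMI) that
   maximize accuracy on the annotated clonotypes; the optimum is then applied
   globally and each surviving GEM is assigned its top-UMI pMHC.
4. **Specificity filters**: HLA-haplotype match (recommended minimum together
   with the thresholds), paired-chain requirement, specificity-singlet
   removal, and the platform's `is_cell` call.
5. **Benchmark metrics**: GEM retention, accuracy, binding concordance
   (fraction of a clonotype's GEMs supporting a pMHC), and the intra- vs
   inter-specificity AUC of BLOSUM k-mer kernel CDR3 similarities — plus a
   classifier for low-concordance outlier GEMs.
6. **A ground-truth simulator** of noisy GEM tables (ambient captures, chain
   dropout/multiplets, donor-restricted HLA, per-specificity CDR3 motifs) so
   every stage is testable without external data.

The main stages are sklearn-style estimators (`ClonotypeAssigner`,
`ExpectedBinderAnnotator`, `UmiThresholdFilter`, the filter transformers and
the composite `ItrapDenoiser`), with plain functions underneath and a thin
`itrap` command-line interface on top.

## Worked example

```python
from itrap import SimConfig, simulate_dataset, evaluate_recovery
from itrap.pipeline import ItrapDenoiser
from itrap.metrics import metrics_report

# a noisy four-donor screen with known ground truth
table, truth = simulate_dataset(SimConfig(seed=1))       # 1,694 GEMs, 500 clonotypes

den = ItrapDenoiser(steps=("threshold", "hla"), haplotypes=truth["haplotypes"])
clean = den.fit_transform(table)

print(den.threshold_filter_.thresholds_)
# ThresholdSet(umi_min_pmhc=6, ratio_min=2.3, umi_min_tcr=0)

rep = metrics_report(clean, len(table), den.annotator_.annotations_, seed=1)
print(round(rep.retention_pct, 1), round(rep.accuracy_pct, 1),
      round(rep.avg_concordance_pct, 1), round(rep.similarity_auc_pct, 1))
# 77.6 100.0 99.9 99.3

print(evaluate_recovery(clean, truth)["precision"])
# 0.9992395437262357
```

Read: the searched UMI thresholds keep 77.6% of the GEMs; every retained GEM
in an annotated clonotype shows its expected binder on top (accuracy 100%);
clonotypes are nearly unanimous about their target (average binding
concordance 99.9%); TCRs annotated to the same pMHC are far more similar to
each other than to other specificities (similarity AUC 99.3 of 100); and
99.9% of retained GEM→pMHC assignments match the simulated ground truth.

The same cascade runs from the shell:

```bash
itrap simulate --seed 1 --outdir data/
itrap ingest --run d1,data/contigs_d1.csv,data/pmhc_d1.csv ... --panel data/panel.csv --out gems.csv
itrap clonotype --table gems.csv --out clonotyped.csv
itrap filter --table clonotyped.csv --preset recommended --hla data/hla.csv --outdir out/
```

On real data, point `itrap run --config run.yaml` at Cellranger-style VDJ
contig CSVs, a pMHC count matrix (wide CSV or MTX), a pMHC panel table and a
donor haplotype table; staged tables (`01_curated.csv` … `06_is_cell.csv`),
per-stage metrics and a reproducibility manifest are written to the output
directory.

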