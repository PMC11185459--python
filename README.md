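# mzpipe

A post-preprocessing pipeline for untargeted LC-MS metabolomics. `mzpipe`
picks up where peak-picking tools leave off: it takes a feature table (one
row per aligned m/z–retention-time feature, one intensity column per
acquisition) plus a sample-metadata CSV, and carries the data through
curation, pre-annotation, multi-level annotation, quality control and
standardized reporting. It is written for mass-spectrometry cores and
bioinformaticians who need a scriptable, reproducible path from a raw
feature table to an annotated, analysis-ready dataset.

## What it does

**Curation.** The recommended order is blank masking → outlier-sample
removal → TIC normalization → infrequent-feature removal → imputation:

- *Blank masking*: a feature is kept iff its mean study intensity is ≥ r
  times its mean blank intensity (default r = 3).
- *Outlier samples*: per-sample feature-count Z-scores,
  Z = (x − mean) / σ (population σ); samples with |Z| > 2.5 are dropped.
  Failed injections show up as anomalously **low** Z.
- *TIC normalization*: with per-sample TIC taken over conserved features
  (present in ≥ 90% of samples), one-pass scales every sample to the median
  TIC; two-pass first equalizes within batches, then scales batches to the
  global median — removing a pure per-batch scale factor exactly.
- *Imputation*: zeros (the missing-value encoding) become 0.5 × the
  feature's minimum observed intensity.
- *Batch correction*: delegated to ComBat (Bioconductor `sva` via `Rscript`)
  on log2 intensities, after imputation.

**Pre-annotation.** Isotopologues and adducts of one compound appear as
separate co-eluting features at fixed m/z offsets (+1.003355 Da per ¹³C;
21.981942 Da between M+H⁺ and M+Na⁺, ...). `mzpipe` links feature pairs whose
m/z difference matches such an offset within a ppm tolerance (default 5 ppm,
evaluated on the heavier m/z) while co-eluting (default 2 s), lays connected
components onto an isotope × adduct grid, and emits one *empirical compound*
per grid with an inferred neutral mass
M = m/z·|z| − (isotope offset + adduct offset). Downstream database searches
then query compounds, not redundant features.

**Annotation** (Schymanski-style confidence levels, all hits retained and
chained, never overwritten):

| level | evidence |
|-------|----------|
| 1a | MS² match to an authentic-standards library |
| 1b | m/z + RT match to authentic standards (both gates required) |
| 2  | MS² match to a public spectral library |
| 4  | neutral-mass match to a compound database |

MS² spectra are extracted from centroided mzML, mapped to empirical
compounds through an interval-tree precursor index (query-identical to a
linear ppm scan), and scored with a greedy one-to-one cosine on raw
intensities: pairs within 0.01 Da taken in descending intensity-product
order, score = Σ IqIr / (‖Iq‖‖Ir‖). Identical spectra score exactly 1.

**Outputs.** A three-table set — feature table (m/z, RT, intensities),
annotation table (one row per feature × annotation, so multiple candidate
identities coexist), metadata table (acquisitions + experiment) — plus a PDF
QC report (PCA, log TICs, Pearson correlation clustermap, missing-feature
Z-scores, annotation accounting, timestamp, and the full command timeline)
and empirical compounds as a versioned JSON document that independent
annotation tools can chain.

**Synthetic fixtures.** `mzpipe.synthetic` generates complete experiments
with planted ground truth (compounds with known masses, adduct/isotope
grids, batch factors, blank contamination, failed injections, MS² spectra),
so every stage is testable without any instrument data.

## Worked example

```bash
mzpipe make-fixture --preset combined --out demo --seed 5
mzpipe assemble -e demo/exp --metadata demo/metadata.csv --feature-table demo/feature_table.tsv
mzpipe blank_masking -e demo/exp -i raw -o masked
mzpipe drop_outliers -e demo/exp -i masked -o kept
mzpipe normalize     -e demo/exp -i kept -o normed --mode two_pass
mzpipe drop_infrequent -e demo/exp -i normed -o common
mzpipe impute        -e demo/exp -i common -o full
mzpipe build_empcpds -e demo/exp -i full --empcpd-moniker ec
mzpipe l4_annotate   -e demo/exp --empcpd-moniker ec --db demo/compounds.tsv
mzpipe l1b_annotate  -e demo/exp --empcpd-moniker ec -i full --standards demo/standards.csv
mzpipe l2_annotate   -e demo/exp --empcpd-moniker ec -i full --library demo/library.msp --mzml demo/ms2_scans.mzML
mzpipe report        -e demo/exp --out demo/report.pdf
mzpipe finish        -e demo/exp -i full --empcpd-moniker ec --out-dir demo/results
```

which prints, stage by stage:

```
wrote fixture to demo: 200 features, 23 samples
assembled experiment with 23 acquisitions
retained 180/200 features
dropped samples: ['S020']
normalized 19 samples (two_pass)
retained 180/180 features
imputed missing values
45 empirical compounds (45 multi-feature)
45 empirical compounds with level-4 annotations
10 empirical compounds with level-1b annotations
10 empirical compounds with level-2 annotations
report written to demo/report.pdf (7 sections)
demo/results/feature_table.tsv
demo/results/annotation_table.tsv
demo/results/metadata_table.tsv
```

Reading: the fixture planted 50 compounds × 4 ions in 20 study samples + 3
blanks; blank masking removed the 20 features of the 5 planted contaminant
compounds; the one planted failed injection (`S020`) was dropped at
|Z| > 2.5; pre-annotation recovered each of the 45 remaining planted grids
as one empirical compound; every one of them got a level-4 (mass)
annotation, the 10 with planted authentic standards got level 1b, and the 10
with planted MS² spectra got level 2.

The same pipeline is available as a library:

```python
import mzpipe as mp

table = mp.read_feature_table("demo/feature_table.tsv")
empcpds = mp.build_empirical_compounds(table, mz_tol_ppm=5, rt_tol_s=2)
mp.annotate_level4(empcpds, mp.read_compound_db("demo/compounds.tsv"), mz_tol_ppm=5)
```

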