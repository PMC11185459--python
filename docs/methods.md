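# Methods

This note documents the models and procedures implemented in `mzpipe`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the package's numerical conventions and limitations.

## Data model and conventions

The pipeline operates on features: m/z–retention-time signals aligned across
the acquisitions of one experiment, with one intensity per acquisition.
Conventions fixed once and applied everywhere:

- **Retention time is in seconds.** Inputs declaring minutes are converted at
  the reader boundary (`TableDialect(rtime_unit="min")`); nothing downstream
  carries a unit. This removes a whole class of 60× tolerance bugs.
- **Intensity 0 encodes a missing value**, matching the output convention of
  the upstream preprocessor the default TSV dialect targets. No NaN/sentinel
  coexists with it; every stage interprets 0 as "not observed". Zeros are
  written to disk as `0`, never as blank cells.
- **Registry + command log.** An `Experiment` stores every intermediate
  feature table and empirical-compound set on disk under a moniker and
  appends each operation to a timestamped, append-only command log, so a
  chained analysis is fully reconstructable from `experiment.json`.
- **Serialization is bit-faithful.** Floats are written with `repr` (shortest
  round-trip form) and parsed with Python's correctly rounded `float()`;
  pandas' own TSV float parser can be one ulp off, so numeric columns bypass
  it. Empirical compounds serialize to a versioned JSON document keyed by
  empcpd id; `to_json(from_json(x)) == x` exactly.

## Pre-annotation (grouping degenerate features)

Electrospray produces several ions per compound; the grouping model assumes
(i) isotopologues and adducts co-elute, (ii) their m/z offsets are the exact
ion-mass constants, and (iii) a heavier isotopologue is not grossly more
abundant than its monoisotopic peak.

1. **Pair linking.** Features i, j (m/z_i ≤ m/z_j) are linked when
   |rt_i − rt_j| ≤ rt_tol (default 2 s) and m/z_j − m/z_i matches an isotope
   step (1.003355, 2.006710 Da) or an adduct-pair difference (from the
   configured ion table; positive-mode defaults M+H⁺ +1.007276,
   M+NH₄⁺ +18.033823, M+Na⁺ +22.989218; negative-mode M−H⁻, M+Cl⁻,
   M+formate⁻) within mz_tol (default 5 ppm). The tolerance is evaluated
   against the heavier member's m/z — the convention must be fixed somewhere
   for results to be reproducible, and the heavier m/z is the conservative
   choice. Isotope links must also pass an abundance gate: the sample-wise
   median ratio M+1/M0 over co-observed samples must be ≤ 1.5 (configurable);
   this blocks accidental 1.0034-spaced pairs that are abundance-implausible.
2. **Grid layout.** Each connected component is laid onto an isotope × adduct
   grid. Every member is hypothesized in turn as the M0 ion of each adduct;
   the implied neutral mass predicts every cell's m/z, members are assigned
   to their best-fitting cell within tolerance, and the hypothesis assigning
   the most members wins (ties: smaller total |ppm error|, then lower mass —
   fully deterministic). If two features claim one cell, the smaller
   |ppm error| wins and the loser becomes a singleton. The anchor is the
   M0 row at the lowest-offset adduct.
3. **Output.** Each laid-out grid becomes one empirical compound with per-
   member ion relations; ungrouped features become singletons with unknown
   ion species. The result is a partition: every feature appears exactly
   once. Neutral mass is the mean over members of m/z·|z| − total ion offset;
   if members disagree by more than the m/z tolerance the compound is flagged
   `inconsistent_neutral_mass` but the mean is kept. Singletons get no
   neutral mass (their ion species is unknowable from MS¹ alone).

Only singly charged ions are considered by default (appropriate for small
molecules); `charge_states=(1, 2)` also tries doubly charged grids using the
1.003355/z isotope spacing and an assumed M+zH adduct. Full ring-topology
grouping and in-source fragments are out of scope.

## Curation

Defaults (all in `CurationParams`): blank ratio 3, Z cutoff 2.5, conserved
fraction 0.9, minimum presence fraction 0.5, imputation scalar 0.5.
The Z cutoff of 2.5 on the per-sample feature count is the one
externally anchored default; the blank-masking ratio-of-means rule and the
other fractions are this package's definitions, chosen to be monotone in
their thresholds (so a stricter setting can only remove more) and hence
property-testable.

- **Blank masking** keeps a feature iff mean study intensity (over samples
  where it is observed) ≥ ratio × mean blank intensity (over all blanks,
  missing as 0); features absent from every blank are always kept. Blank
  columns are dropped from the output.
- **Z-scores** use the population σ (n divisor), so small worked examples
  are exact; a constant metric yields all-zero Z. Correlation Z-scores use
  Pearson on log10(intensity + 1) — the offset keeps zeros finite and the
  log stabilizes the correlation against the intensity scale.
- **Outlier removal** computes Z on the input table once (not iteratively);
  removal is two-sided at |Z| > 2.5. Failed-injection *detection* (QC) is
  one-sided low, since failures lose features; a sample with anomalously
  many features is suspicious but not a failed injection.
- **TIC normalization**: TICs are sums over conserved features only, so rare
  features cannot steer the scale. Two-pass: scale samples to their batch
  median TIC, then scale batches to the global median of the pass-1 TICs.
  A pure per-batch scale factor is removed exactly (to float round-off);
  post-normalization conserved TICs agree to a relative 1e-9. A zero-TIC
  sample is an error naming the sample — it should have been dropped as a
  failed injection.
- **Imputation** replaces zeros by scalar × the feature's minimum observed
  intensity; it touches only zeros and is therefore idempotent. A feature
  with no observed value is an error (remove it first).
- **Batch correction** delegates to ComBat from Bioconductor `sva`, run via
  `Rscript` on log2 intensities (parametric empirical Bayes), after
  imputation — batch correction is sensitive to missing values. Features
  with (near-)zero variance are passed through unchanged because ComBat
  cannot standardize them. Residual between-batch differences after
  correction are dominated by EB shrinkage across features and shrink with
  sample count; on exact global-scale batch effects the reduction exceeds
  90% at ≥ 20 samples per batch.

## Annotation

Level assignment is a pure function of evidence type: neutral mass → 4,
m/z + RT vs authentic standards (both gates required) → 1b, MS² vs public
library → 2, MS² vs authentic library → 1a. All qualifying hits are appended
— isomers at equal mass legitimately produce multiple level-4 records — and
ranking (level precedence 1a > 1b > 2 > 4, then score) happens only at
read-out. Because searches run per empirical compound, the database sees one
query per compound rather than one per degenerate feature.

**Precursor index.** Member m/z windows [mz(1−tol), mz(1+tol)] live in an
interval tree; a stabbing query prefilters candidates and the exact ppm test
is re-applied, so results are *identical* to a linear scan by construction
(the tree is pure optimization, never a semantics change). MS² spectra
attach to every empirical compound owning a member whose window contains the
precursor m/z and whose RT is within 30 s (default); unmatched spectra are
returned as an unassigned pool rather than discarded.

**MS² similarity** is a greedy one-to-one cosine on raw intensities:
candidate peak pairs within 0.01 Da sorted by descending intensity product,
each peak used once; score = Σ IqIr / (‖Iq‖₂‖Ir‖₂). Raw (unweighted)
intensities with greedy pairing are the simplest defensible default; the
implementation agrees with the established spectral-matching library's
greedy cosine to 1e-6 over random spectrum pairs (a dev-time cross-check in
the test suite, not a runtime dependency). Defaults: score cutoff 0.7,
minimum 3 matched peaks (matches below the minimum are reported but flagged,
never silently promoted), fragment tolerance 0.01 Da.

mzML is read directly (XML + base64/zlib binary-array decoding, 32/64-bit
floats), accepting only centroided spectra; profile-mode MS² raises an error
that points to centroiding. MSP is parsed by a small line-oriented reader;
MGF goes through pyteomics. Library spectra must carry reference provenance
(`reference_public` or `reference_authentic`); it determines level 2 vs 1a.

## Reporting

The PDF report renders a JSON template of sections; the default template has
seven: timestamp, PCA, log TICs, Pearson correlation clustermap,
missing-feature Z-scores, annotation accounting (empirical compounds and
features per level per set), and the command timeline. PCA runs on
log10(intensity + 1), feature-centered, with the deterministic full-SVD
solver, so coordinates are bit-reproducible. t-SNE is optional and
seed-pinned; being a stochastic embedding it is excluded from acceptance
checks. TIC bar plots subsample to 50 acquisitions with a fixed seed.
Missing-feature Z plots show signed Z as computed. Unknown template sections
raise an error listing the valid names.

## Synthetic data generator

`make_experiment` emulates the post-preprocessing view of an LC-MS run:

- Compounds get neutral masses ~9.4 Da apart with sub-Da jitter and
  retention times spread evenly (≥ 10 s apart for 50 compounds) — distinct
  planted compounds never co-elute, so the planted partition is
  unambiguous. Member RTs jitter ±0.4 s within a compound.
- Each compound contributes its full adduct × isotope grid (defaults
  {M+H⁺, M+Na⁺} × {M0, M+1}) at exact ion-offset m/z values with
  **bounded uniform** ppm noise in [−noise, +noise] (default 2 ppm). Bounded
  noise means a 5 ppm pairwise tolerance can never be violated by a planted
  pair (worst-case difference error ≈ 4 ppm of the heavier m/z), which is
  what makes exact-recovery statements meaningful; Gaussian noise would make
  every recovery bound probabilistic.
- Intensities are log-normal (CV default 0.3) around a per-compound,
  per-sample abundance shared by the compound's ions, times adduct/isotope
  fractions (M+Na 0.4, M+NH₄ 0.3, M+1 0.25 — so the isotope abundance gate is
  exercised realistically), times the per-batch scale factor.
- Optional design elements: missing values at a given rate (each feature is
  kept observed in ≥ 1 sample), blanks with contaminant compounds planted at
  ≥ study level (so blank masking must remove them), failed injections
  retaining < 10% of features at 1% intensity, authentic standards
  (theoretical M+H m/z + true RT), and MS² spectra (8–14 random fragments;
  the library holds the clean spectrum, the "experimental" copies get ±5%
  intensity noise and are written to a minimal centroided mzML file that the
  package's own reader ingests).
- Identical (parameters, seed) produce bit-identical output; all randomness
  flows through one `numpy` generator.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: chromatographic peak shapes and RT drift,
co-eluting isomers and in-source fragments, correlated (electrospray
competition) adduct patterns, realistic fragmentation chemistry, detector
saturation, and heavy-tailed m/z error. Results on fixtures bound the
pipeline's bookkeeping and numerics, not instrument physics.

`score_recovery` counts a feature as correctly assigned only when its
empirical compound's member set *equals* its planted group (restricted to
features the grouping saw), a deliberately strict criterion; group recovery
and per-group neutral-mass ppm errors are reported alongside.

## Numerical choices and degenerate inputs

- Tolerance comparisons are inclusive (≤) everywhere; presence fractions are
  inclusive too (a feature in exactly half the samples survives a 0.5
  minimum).
- Median over an even count is the midpoint average (numpy convention); the
  two-pass worked example (batch TICs [1000, 2000 | 4000, 4000] → all 2750)
  depends on it.
- Grid-layout ties break deterministically (assigned count, total |ppm|,
  neutral mass), so grouping output is stable across runs and platforms.
- Degenerate tables: an empty feature list groups to an empty list; a table
  whose features are all non-conserved falls back to all-feature TICs;
  constant QC metrics give all-zero Z rather than a division error.
- The interval tree pads window ends by 2 parts per 10⁹ and re-applies the
  exact test, so boundary queries cannot differ from the linear scan.

## Problem sizes

The test suite and the acceptance script run on synthetic experiments of
50 compounds × 4 ions × ~20 samples (the reference condition), 100
twelve-feature instances for oracle equivalence, and 1000 members × 1000
queries for index equivalence — sizes chosen so the full battery executes in
a few minutes on a single CPU while still exercising every code path; all
statistics quoted in the README were produced by these runs.

## Known limitations

- Grouping fidelity is khipu-*style*, not a full reimplementation: no ring
  topology, no extended isotope patterns beyond M+2, no in-source fragment
  annotation.
- ComBat runs out of process via R; there is no pure-Python fallback, and a
  missing `sva` installation surfaces as a runtime error from `Rscript`.
- Vendor raw files are not parsed; the CLI accepts a pre-conversion hook
  command instead.
- The empirical-compound JSON schema is semantically complete for this
  pipeline but not byte-compatible with any other tool's on-disk format.
- RT-drift and QC-pool-based signal-drift correction are out of scope.
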