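"""Feature-table curation: blank masking, outlier-sample removal, TIC
normalization, infrequent-feature removal, imputation and batch correction.

The recommended order is blank masking -> outlier sample removal ->
normalization -> infrequent-feature removal -> imputation (-> batch
correction), each stage mapping a valid feature table to a valid feature
table so stages chain in any user-chosen order.
"""

from __future__ import annotations

import os
import subprocess
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import FeatureTable


@dataclass
class CurationParams:
    """Tunable thresholds of the curation stages.

    blank_ratio_threshold: minimum study/blank mean-intensity ratio to keep
        a feature during blank masking.
    zscore_cutoff: |Z| above which a sample's feature count marks it an
        outlier (2.5 by default).
    conserved_fraction: fraction of samples a feature must be present in to
        count toward the TIC used for normalization.
    min_feature_fraction: presence fraction below which a feature is dropped
        as infrequent.
    imputation_scalar: multiple of a feature's minimum observed intensity
        used to fill its missing values.
    """

    blank_ratio_threshold: float = 3.0
    blank_presence_fraction: float = 0.8
    zscore_cutoff: float = 2.5
    conserved_fraction: float = 0.9
    min_feature_fraction: float = 0.5
    imputation_scalar: float = 0.5

    def __post_init__(self) -> None:
        if self.blank_ratio_threshold <= 0:
            raise ValueError("blank_ratio_threshold must be positive")
        if self.zscore_cutoff <= 0:
            raise ValueError("zscore_cutoff must be positive")
        if self.imputation_scalar <= 0:
            raise ValueError("imputation_scalar must be positive")
        for name in ("blank_presence_fraction", "conserved_fraction", "min_feature_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


DEFAULT_PARAMS = CurationParams()


def blank_mask(
    table: FeatureTable,
    blank_names: list[str],
    study_names: list[str],
    params: CurationParams = DEFAULT_PARAMS,
) -> FeatureTable:
    """Drop features whose blank signal indicates contamination.

    A feature is retained iff its mean study intensity (over samples where it
    is observed) is at least ``blank_ratio_threshold`` times its mean blank
    intensity (over all blanks, missing counted as 0). Features absent from
    every blank are always retained. Blank columns are removed from the
    output table.
    """
    if not blank_names:
        raise ValueError(
            "no blank acquisitions given; skip the blank-masking stage instead"
        )
    overlap = set(blank_names) & set(study_names)
    if overlap:
        raise ValueError(f"samples listed as both blank and study: {sorted(overlap)}")
    for name in (*blank_names, *study_names):
        if name not in table.sample_columns:
            raise ValueError(f"sample {name!r} not in table")

    blanks = table.frame[blank_names].to_numpy(dtype=float)
    study = table.frame[study_names].to_numpy(dtype=float)
    blank_mean = blanks.mean(axis=1)
    with np.errstate(invalid="ignore"):
        study_sum = study.sum(axis=1)
        study_n = (study > 0).sum(axis=1)
        study_mean = np.where(study_n > 0, study_sum / np.maximum(study_n, 1), 0.0)
    keep = (blank_mean == 0) | (study_mean >= params.blank_ratio_threshold * blank_mean)

    out_samples = [c for c in table.sample_columns if c not in blank_names]
    out_cols = [c for c in table.frame.columns if c not in blank_names]
    frame = table.frame.loc[keep, out_cols].copy()
    return table.with_frame(frame, sample_columns=out_samples)


def sample_zscores(table: FeatureTable, metric: str = "feature_count") -> pd.Series:
    """Per-sample Z-scores of a QC metric.

    Metrics: ``feature_count`` (features observed, intensity > 0),
    ``missing_count`` (features at 0), ``median_correlation`` (median over
    the other samples of the Pearson correlation of log10(intensity + 1)).
    Z uses the population standard deviation; a constant metric gives all 0.
    """
    if table.n_samples < 3:
        raise ValueError("Z-scores need at least 3 samples")
    intens = table.intensities.to_numpy(dtype=float)
    if metric == "feature_count":
        x = (intens > 0).sum(axis=0).astype(float)
    elif metric == "missing_count":
        x = (intens == 0).sum(axis=0).astype(float)
    elif metric == "median_correlation":
        import warnings

        log = np.log10(intens + 1.0)
        # single-feature tables give 0-dof correlations; treat them as 0
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(log.T)
        corr = np.nan_to_num(corr, nan=0.0)
        n = corr.shape[0]
        x = np.array([np.median(np.delete(corr[i], i)) for i in range(n)])
    else:
        raise ValueError(
            "metric must be one of feature_count, missing_count, median_correlation"
        )
    sigma = float(np.std(x))  # population sigma
    if sigma == 0:
        z = np.zeros_like(x)
    else:
        z = (x - x.mean()) / sigma
    return pd.Series(z, index=table.sample_columns, name=f"z_{metric}")


def drop_outlier_samples(
    table: FeatureTable, params: CurationParams = DEFAULT_PARAMS
) -> FeatureTable:
    """Remove samples whose feature-count |Z| exceeds the cutoff.

    Z-scores are computed once on the input table (not iteratively), so the
    result does not depend on removal order.
    """
    z = sample_zscores(table, "feature_count")
    keep = [s for s in table.sample_columns if abs(z[s]) <= params.zscore_cutoff]
    drop = [s for s in table.sample_columns if s not in keep]
    frame = table.frame[[c for c in table.frame.columns if c not in drop]].copy()
    return table.with_frame(frame, sample_columns=keep)


def conserved_feature_mask(
    table: FeatureTable, params: CurationParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Features present (intensity > 0) in >= conserved_fraction of samples."""
    intens = table.intensities.to_numpy(dtype=float)
    presence = (intens > 0).mean(axis=1)
    mask = presence >= params.conserved_fraction
    if not mask.any():
        # degenerate table: fall back to all features so TICs stay defined
        mask = np.ones(table.n_features, dtype=bool)
    return mask


def normalize_tic(
    table: FeatureTable,
    mode: str = "two_pass",
    batches: dict[str, str] | None = None,
    params: CurationParams = DEFAULT_PARAMS,
) -> FeatureTable:
    """Scale samples so conserved-feature TICs agree.

    The TIC of a sample is the summed intensity of the conserved features
    (present in >= ``conserved_fraction`` of samples). ``one_pass`` scales
    every sample to the global median TIC. ``two_pass`` first equalizes TICs
    within each batch to the batch median, then scales whole batches to the
    global median of the pass-1 TICs — removing a pure per-batch scale factor
    exactly. Non-conserved features are scaled by the same per-sample factor.
    """
    if mode not in ("one_pass", "two_pass"):
        raise ValueError("mode must be 'one_pass' or 'two_pass'")
    mask = conserved_feature_mask(table, params)
    intens = table.intensities.to_numpy(dtype=float)
    tic = intens[mask].sum(axis=0)
    zero = [s for s, t in zip(table.sample_columns, tic) if t == 0]
    if zero:
        raise ValueError(
            f"samples with zero TIC (likely failed injections, drop them first): {zero}"
        )

    if mode == "one_pass":
        factors = np.median(tic) / tic
    else:
        if batches is None:
            raise ValueError("two_pass normalization requires batch labels")
        missing = [s for s in table.sample_columns if s not in batches]
        if missing:
            raise ValueError(f"samples without batch labels: {missing}")
        labels = np.array([batches[s] for s in table.sample_columns])
        factors = np.ones_like(tic)
        pass1 = np.empty_like(tic)
        for b in np.unique(labels):
            sel = labels == b
            med = np.median(tic[sel])
            factors[sel] = med / tic[sel]
            pass1[sel] = med
        global_median = np.median(pass1)
        for b in np.unique(labels):
            sel = labels == b
            factors[sel] *= global_median / pass1[sel]

    frame = table.frame.copy()
    frame[table.sample_columns] = intens * factors[np.newaxis, :]
    return table.with_frame(frame)


def drop_infrequent_features(
    table: FeatureTable, params: CurationParams = DEFAULT_PARAMS
) -> FeatureTable:
    """Keep features present in >= min_feature_fraction of samples (inclusive)."""
    intens = table.intensities.to_numpy(dtype=float)
    presence = (intens > 0).mean(axis=1)
    keep = presence >= params.min_feature_fraction
    return table.with_frame(table.frame.loc[keep].copy())


def impute_missing(
    table: FeatureTable, params: CurationParams = DEFAULT_PARAMS
) -> FeatureTable:
    """Fill zeros with ``imputation_scalar`` x the feature's minimum observed
    intensity. Nonzero cells are untouched, so the operation is idempotent."""
    intens = table.intensities.to_numpy(dtype=float)
    all_zero = ~(intens > 0).any(axis=1)
    if all_zero.any():
        bad = [fid for fid, z in zip(table.feature_ids, all_zero) if z]
        raise ValueError(
            f"features with no observed intensity (remove them first): {bad[:10]}"
        )
    masked = np.where(intens > 0, intens, np.inf)
    fill = params.imputation_scalar * masked.min(axis=1)
    out = np.where(intens > 0, intens, fill[:, np.newaxis])
    frame = table.frame.copy()
    frame[table.sample_columns] = out
    return table.with_frame(frame)


# ---------------------------------------------------------------------------
# batch correction (delegated to ComBat)
# ---------------------------------------------------------------------------

_COMBAT_R = """\
suppressMessages(library(sva))
args <- commandArgs(trailingOnly = TRUE)
m <- as.matrix(read.table(args[1], sep = "\\t", header = TRUE,
                          row.names = 1, check.names = FALSE))
batch <- scan(args[2], what = character(), quiet = TRUE)
out <- ComBat(dat = m, batch = batch, par.prior = TRUE)
write.table(out, args[3], sep = "\\t", quote = FALSE, col.names = NA)
"""


def batch_correct(
    table: FeatureTable,
    batches: dict[str, str],
    rscript: str = "Rscript",
) -> FeatureTable:
    """Remove batch effects with ComBat (Bioconductor sva) on log2 intensities.

    Run after imputation: the table must contain no zeros (batch correction is
    sensitive to missing values). Features with (near-)zero variance are passed
    through unchanged, as ComBat cannot standardize them. Requires at least two
    batches with at least two samples each.
    """
    labels = [batches.get(s) for s in table.sample_columns]
    if any(l is None or l == "" for l in labels):
        missing = [s for s, l in zip(table.sample_columns, labels) if not l]
        raise ValueError(f"samples without batch labels: {missing}")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("batch correction needs at least 2 batches")
    small = [b for b, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValueError(f"batches with fewer than 2 samples: {small}")
    intens = table.intensities.to_numpy(dtype=float)
    if (intens <= 0).any():
        raise ValueError("batch correction requires a fully imputed table (no zeros)")

    log = np.log2(intens)
    variable = log.var(axis=1) > 1e-12
    out_log = log.copy()
    if variable.any():
        with tempfile.TemporaryDirectory() as tmp:
            mat_path = os.path.join(tmp, "matrix.tsv")
            batch_path = os.path.join(tmp, "batches.txt")
            out_path = os.path.join(tmp, "corrected.tsv")
            script_path = os.path.join(tmp, "combat.R")
            sub = pd.DataFrame(
                log[variable],
                index=[f"f{i}" for i in np.flatnonzero(variable)],
                columns=table.sample_columns,
            )
            sub.to_csv(mat_path, sep="\t")
            with open(batch_path, "w") as fh:
                fh.write("\n".join(str(l) for l in labels) + "\n")
            with open(script_path, "w") as fh:
                fh.write(_COMBAT_R)
            proc = subprocess.run(
                [rscript, "--vanilla", script_path, mat_path, batch_path, out_path],
                capture_output=True,
                text=True,
            )
            if proc.returncode != 0:
                raise RuntimeError(f"ComBat (sva) failed:\n{proc.stderr[-2000:]}")
            corrected = pd.read_csv(out_path, sep="\t", index_col=0)
            out_log[variable] = corrected[table.sample_columns].to_numpy(dtype=float)

    frame = table.frame.copy()
    frame[table.sample_columns] = np.power(2.0, out_log)
    return table.with_frame(frame)


def default_workflow(
    table: FeatureTable,
    blank_names: list[str],
    study_names: list[str],
    batches: dict[str, str] | None = None,
    params: CurationParams = DEFAULT_PARAMS,
) -> FeatureTable:
    """Run the recommended curation order on a raw feature table.

    blank masking -> outlier sample removal -> TIC normalization ->
    infrequent-feature removal -> imputation. Two-pass normalization is used
    when batch labels are supplied, one-pass otherwise.
    """
    t = blank_mask(table, blank_names, study_names, params)
    t = drop_outlier_samples(t, params)
    if batches is not None and len(set(batches.get(s, "") for s in t.sample_columns)) > 1:
        t = normalize_tic(t, "two_pass", batches, params)
    else:
        t = normalize_tic(t, "one_pass", None, params)
    t = drop_infrequent_features(t, params)
    t = impute_missing(t, params)
    return t
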