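"""Quality assessment: per-sample metrics, projections and the PDF report.

Per-sample summaries (TIC, feature counts, Z-scores, correlation structure,
PCA) flag problem acquisitions — above all failed injections, which show up
as anomalously low feature-count Z-scores. The report collects the default
battery of figures plus an annotation accounting and the full command
timeline into one PDF (a user-supplied JSON template can reorder or subset
the sections).
"""

from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.backends.backend_pdf import PdfPages

from .curation import sample_zscores
from .models import Experiment, FeatureTable


@dataclass
class QCSummary:
    """Computed QC metrics for one feature table."""

    per_sample: pd.DataFrame  # TIC, feature_count, missing_count, median/mean, Z-scores
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    pca_coordinates: pd.DataFrame  # samples x PCs
    explained_variance: np.ndarray
    tsne_coordinates: pd.DataFrame | None = None
    per_feature: pd.DataFrame | None = None  # upstream metrics when present
    options: dict = field(default_factory=dict)


#: per-feature QC columns some preprocessors emit; carried through if present
UPSTREAM_FEATURE_METRICS = ("cSelectivity", "goodness_fitting", "peak_area", "snr")


def compute_qc_summary(
    table: FeatureTable,
    n_components: int = 2,
    with_tsne: bool = False,
    seed: int = 0,
) -> QCSummary:
    """Compute the QC battery for a table with at least 3 samples.

    Correlations and PCA are computed on log10(intensity + 1); PCA centers
    each feature and uses the deterministic full-SVD solver so coordinates
    are reproducible run to run.
    """
    if table.n_samples < 3:
        raise ValueError("QC summary needs at least 3 samples")
    intens = table.intensities.to_numpy(dtype=float)
    log = np.log10(intens + 1.0)
    samples = table.sample_columns

    per_sample = pd.DataFrame(index=pd.Index(samples, name="sample"))
    per_sample["tic"] = intens.sum(axis=0)
    per_sample["feature_count"] = (intens > 0).sum(axis=0)
    per_sample["missing_count"] = (intens == 0).sum(axis=0)
    observed = np.where(intens > 0, intens, np.nan)
    with np.errstate(invalid="ignore"):
        per_sample["median_intensity"] = np.nanmedian(observed, axis=0)
        per_sample["mean_intensity"] = np.nanmean(observed, axis=0)
    for metric in ("feature_count", "missing_count", "median_correlation"):
        per_sample[f"z_{metric}"] = sample_zscores(table, metric)

    log_df = pd.DataFrame(log, columns=samples)
    with np.errstate(invalid="ignore", divide="ignore"):
        pearson = log_df.corr(method="pearson")
        spearman = log_df.corr(method="spearman")

    from sklearn.decomposition import PCA

    k = min(n_components, len(samples), table.n_features)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(log.T)
    pca_coords = pd.DataFrame(
        coords, index=per_sample.index, columns=[f"PC{i + 1}" for i in range(k)]
    )

    tsne_coords = None
    if with_tsne:
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (len(samples) - 1) / 3))
        emb = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
        tsne_coords = pd.DataFrame(
            emb.fit_transform(log.T), index=per_sample.index, columns=["tSNE1", "tSNE2"]
        )

    per_feature = None
    upstream = [c for c in UPSTREAM_FEATURE_METRICS if c in table.frame.columns]
    if upstream:
        per_feature = table.frame[upstream].apply(pd.to_numeric, errors="coerce")

    return QCSummary(
        per_sample=per_sample,
        pearson=pearson,
        spearman=spearman,
        pca_coordinates=pca_coords,
        explained_variance=pca.explained_variance_ratio_,
        tsne_coordinates=tsne_coords,
        per_feature=per_feature,
        options={"n_components": k, "with_tsne": with_tsne, "seed": seed},
    )


def detect_failed_injections(table: FeatureTable, cutoff: float = 2.5) -> list[str]:
    """Samples whose feature-count Z-score falls below -cutoff.

    One-sided: a failed injection loses features, so only anomalously low
    counts are flagged. Lowering the cutoff can only grow the list.
    """
    z = sample_zscores(table, "feature_count")
    return [s for s in table.sample_columns if z[s] < -cutoff]


# ---------------------------------------------------------------------------
# PDF report
# ---------------------------------------------------------------------------

DEFAULT_TEMPLATE: list[dict] = [
    {"section": "timestamp"},
    {"section": "pca"},
    {"section": "log_tics"},
    {"section": "correlation_clustermap"},
    {"section": "missing_feature_zscores"},
    {"section": "annotation_accounting"},
    {"section": "command_timeline"},
]

#: samples shown in the TIC bar plot (random subset, fixed seed)
TIC_PLOT_MAX_SAMPLES = 50


def _text_page(pdf: PdfPages, title: str, lines: list[str]) -> None:
    fig, ax = plt.subplots(figsize=(8.5, 11))
    ax.axis("off")
    ax.set_title(title, loc="left", fontsize=14)
    body = "\n".join(lines[:60]) if lines else "(empty)"
    ax.text(0.01, 0.97, body, va="top", family="monospace", fontsize=8, wrap=True)
    pdf.savefig(fig)
    plt.close(fig)


def _each_table(experiment: Experiment):
    for moniker in sorted(experiment.table_registry):
        yield moniker, experiment.get_table(moniker)


def _render_timestamp(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    now = datetime.datetime.now().isoformat(timespec="seconds")
    _text_page(
        pdf,
        "QC report",
        [
            f"generated: {now}",
            f"experiment directory: {experiment.directory}",
            f"acquisitions: {len(experiment.acquisitions)}",
            f"feature tables: {sorted(experiment.table_registry)}",
            f"empirical compound sets: {sorted(experiment.empcpd_registry)}",
        ],
    )


def _render_pca(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    for moniker, table in _each_table(experiment):
        if table.n_samples < 3 or table.n_features < 2:
            continue
        qc = compute_qc_summary(table)
        fig, ax = plt.subplots(figsize=(7, 6))
        ax.scatter(qc.pca_coordinates["PC1"], qc.pca_coordinates.iloc[:, 1], s=18)
        ev = qc.explained_variance
        ax.set_xlabel(f"PC1 ({ev[0] * 100:.1f}%)")
        ax.set_ylabel(f"PC2 ({ev[1] * 100:.1f}%)" if len(ev) > 1 else "PC2")
        ax.set_title(f"PCA — {moniker}")
        pdf.savefig(fig)
        plt.close(fig)


def _render_log_tics(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    rng = np.random.default_rng(seed)
    for moniker, table in _each_table(experiment):
        tic = table.intensities.to_numpy(dtype=float).sum(axis=0)
        samples = np.array(table.sample_columns)
        if len(samples) > TIC_PLOT_MAX_SAMPLES:
            pick = np.sort(rng.choice(len(samples), TIC_PLOT_MAX_SAMPLES, replace=False))
            samples, tic = samples[pick], tic[pick]
        fig, ax = plt.subplots(figsize=(max(7, len(samples) * 0.2), 5))
        ax.bar(range(len(samples)), np.log10(tic + 1.0))
        ax.set_xticks(range(len(samples)))
        ax.set_xticklabels(samples, rotation=90, fontsize=6)
        ax.set_ylabel("log10 TIC")
        ax.set_title(f"log TICs — {moniker}")
        fig.tight_layout()
        pdf.savefig(fig)
        plt.close(fig)


def _render_clustermap(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    import seaborn as sns

    for moniker, table in _each_table(experiment):
        if table.n_samples < 3:
            continue
        qc = compute_qc_summary(table)
        grid = sns.clustermap(qc.pearson, cmap="vlag", vmin=-1, vmax=1, figsize=(8, 8))
        grid.fig.suptitle(f"Pearson correlation clustermap — {moniker}")
        pdf.savefig(grid.fig)
        plt.close(grid.fig)


def _render_missing_zscores(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    for moniker, table in _each_table(experiment):
        if table.n_samples < 3:
            continue
        z = sample_zscores(table, "missing_count")
        fig, ax = plt.subplots(figsize=(max(7, len(z) * 0.2), 5))
        ax.bar(range(len(z)), z.to_numpy())
        ax.axhline(2.5, color="red", ls="--", lw=0.8)
        ax.axhline(-2.5, color="red", ls="--", lw=0.8)
        ax.set_xticks(range(len(z)))
        ax.set_xticklabels(z.index, rotation=90, fontsize=6)
        ax.set_ylabel("missing-feature Z")
        ax.set_title(f"Missing-feature Z-scores — {moniker}")
        fig.tight_layout()
        pdf.savefig(fig)
        plt.close(fig)


def annotation_accounting(experiment: Experiment) -> dict[str, dict]:
    """Counts of empirical compounds and features per annotation level,
    for each registered empirical-compound set."""
    accounting: dict[str, dict] = {}
    for moniker in sorted(experiment.empcpd_registry):
        empcpds = experiment.get_empcpds(moniker)
        levels: dict[str, dict[str, int]] = {}
        for e in empcpds:
            seen = sorted({a.level for a in e.annotations})
            for level in seen:
                entry = levels.setdefault(level, {"empcpds": 0, "features": 0})
                entry["empcpds"] += 1
                entry["features"] += len(e.members)
        accounting[moniker] = {
            "n_empcpds": len(empcpds),
            "n_features": sum(len(e.members) for e in empcpds),
            "n_annotated_empcpds": sum(1 for e in empcpds if e.annotations),
            "per_level": levels,
        }
    return accounting


def _render_accounting(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    lines = []
    for moniker, acct in annotation_accounting(experiment).items():
        lines.append(f"empirical compound set: {moniker}")
        lines.append(
            f"  {acct['n_empcpds']} empirical compounds covering "
            f"{acct['n_features']} features; {acct['n_annotated_empcpds']} annotated"
        )
        for level in sorted(acct["per_level"]):
            c = acct["per_level"][level]
            lines.append(
                f"  level {level}: {c['empcpds']} empcpds, {c['features']} features"
            )
        lines.append("")
    _text_page(pdf, "Annotation accounting", lines or ["(no empirical compound sets)"])


def _render_timeline(experiment: Experiment, pdf: PdfPages, seed: int) -> None:
    lines = [
        f"{entry['timestamp']}  {entry['command']}  {json.dumps(entry['params'], sort_keys=True)}"
        for entry in experiment.command_log
    ]
    _text_page(pdf, "Command timeline", lines or ["(no commands logged)"])


SECTION_RENDERERS = {
    "timestamp": _render_timestamp,
    "pca": _render_pca,
    "log_tics": _render_log_tics,
    "correlation_clustermap": _render_clustermap,
    "missing_feature_zscores": _render_missing_zscores,
    "annotation_accounting": _render_accounting,
    "command_timeline": _render_timeline,
}


@dataclass
class ReportManifest:
    path: str
    sections: list[str]


def assemble_report(
    experiment: Experiment,
    template: list[dict] | None = None,
    out_path: str | None = None,
    seed: int = 0,
) -> ReportManifest:
    """Render the QC report PDF.

    ``template`` is a JSON-style list of section descriptors
    (``[{"section": "pca"}, ...]``); the default template contains the seven
    standard sections. Unknown section names raise, listing valid ones. An
    empty template yields a title/timestamp-only report.
    """
    if not experiment.table_registry:
        raise ValueError("experiment has no registered feature tables to report on")
    if template is None:
        template = DEFAULT_TEMPLATE
    for item in template:
        name = item.get("section")
        if name not in SECTION_RENDERERS:
            raise ValueError(
                f"unknown report section {name!r}; valid sections: "
                f"{sorted(SECTION_RENDERERS)}"
            )
    if out_path is None:
        out_path = os.path.join(experiment.directory, "report.pdf")
    os.makedirs(os.path.dirname(os.path.abspath(out_path)), exist_ok=True)

    rendered: list[str] = []
    with PdfPages(out_path) as pdf:
        if not template:
            _render_timestamp(experiment, pdf, seed)
            rendered.append("timestamp")
        for item in template:
            name = item["section"]
            SECTION_RENDERERS[name](experiment, pdf, seed)
            rendered.append(name)
    return ReportManifest(path=out_path, sections=rendered)
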