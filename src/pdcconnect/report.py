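"""Exploratory figures, the t-SNE embedding, and the end-to-end driver.

`run_pipeline` chains synthetic-cohort generation (or cohort files) through
preprocessing, PDC feature extraction, ANOVA selection and SVM evaluation,
writing a reproducibility manifest, a results file and the standard figure
set (feature colorplot, per-band accuracy chart, p-value grid, directed-
edge diagram, rhythm × α summary table).
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import classify, connectivity, features, io, preprocess, synthetic  # noqa: E402
from .bands import rhythm_bands  # noqa: E402

logger = logging.getLogger(__name__)

#: approximate 2-D 10–20 layout coordinates (x = right, y = anterior)
ELECTRODE_POS = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95), "F3": (-0.40, 0.50),
    "F4": (0.40, 0.50), "C3": (-0.50, 0.00), "C4": (0.50, 0.00),
    "P3": (-0.40, -0.50), "P4": (0.40, -0.50), "O1": (-0.31, -0.95),
    "O2": (0.31, -0.95), "F7": (-0.81, 0.59), "F8": (0.81, 0.59),
    "T3": (-1.00, 0.00), "T4": (1.00, 0.00), "T5": (-0.81, -0.59),
    "T6": (0.81, -0.59), "FZ": (0.00, 0.50), "PZ": (0.00, -0.50),
    "CZ": (0.00, 0.00),
}


def tsne_embed(x, dims: int = 3, perplexity: float = 30.0, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE embedding (PCA initialization) of a feature matrix."""
    from sklearn.manifold import TSNE

    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (rows × features)")
    if len(x) < 3 * perplexity:
        raise ValueError(
            f"need at least {int(3 * perplexity)} rows for perplexity {perplexity}"
        )
    # exact gradients: Barnes-Hut is unreliable in 3-D on near-duplicate
    # inputs, and the O(n^2) cost is fine at per-cohort segment counts.
    # PCA init divides by the first component's variance, so a (near-)
    # constant cloud needs a random start instead.
    init = "pca" if np.ptp(x, axis=0).max() > 1e-12 else "random"
    emb = TSNE(n_components=dims, perplexity=perplexity, init=init,
               method="exact", random_state=seed).fit_transform(x)
    if not np.all(np.isfinite(emb)):  # pragma: no cover
        raise RuntimeError("t-SNE produced non-finite coordinates")
    return emb


@dataclass
class PipelineConfig:
    """Fully serializable description of one pipeline run."""

    cohort: str = "gamma"  # gamma | null | manifest path
    n_subjects_per_class: int = 10
    duration_s: float = 60.0
    effect_gain: float = 0.15
    subject_jitter_sd: float = 0.02
    mvar_order: int = 5
    rhythm: str = "gamma"
    alpha: float = 0.01
    split: str = "segment"
    k_folds: int = 5
    repeats: int = 2
    tune_budget: int = 10
    amplitude_limit: float | None = None
    seed: int = 0
    outdir: str = "pdcconnect_run"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_cohort(cfg: PipelineConfig):
    if cfg.cohort == "gamma":
        cc = synthetic.gamma_effect_config(
            n_subjects_per_class=cfg.n_subjects_per_class,
            duration_s=cfg.duration_s, effect_gain=cfg.effect_gain,
            subject_jitter_sd=cfg.subject_jitter_sd, seed=cfg.seed)
        return synthetic.make_cohort(cc).recordings
    if cfg.cohort == "null":
        cc = synthetic.null_config(n_subjects_per_class=cfg.n_subjects_per_class,
                                   duration_s=cfg.duration_s, seed=cfg.seed,
                                   subject_jitter_sd=cfg.subject_jitter_sd)
        return synthetic.make_cohort(cc).recordings
    return io.read_cohort(cfg.cohort)


def render_outputs(outdir, feature_set=None, mask=None, sweep=None,
                   summary: pd.DataFrame | None = None, band: int = 55) -> list[Path]:
    """Write the standard figure/table set; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if feature_set is not None:
        subj = feature_set.subjects
        first = subj[0]
        mat = feature_set.band_matrix(band)[subj == first]
        fig, ax = plt.subplots(figsize=(7, 3))
        im = ax.imshow(mat, aspect="auto", cmap="viridis", vmin=0, vmax=1)
        ax.set_xlabel("connectivity index (1..324)")
        ax.set_ylabel(f"segment ({first})")
        ax.set_title(f"PDCaM feature colorplot, band {band}")
        fig.colorbar(im, ax=ax, label="squared PDC")
        p = outdir / "colorplot.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if sweep is not None:
        bands_ = sorted(sweep["reports"])
        accs = [100 * sweep["reports"][b].accuracy for b in bands_]
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.bar(bands_, accs, color="steelblue")
        ax.axhline(100 * sweep["mean_accuracy"], color="firebrick", ls="--",
                   label=f"mean {100 * sweep['mean_accuracy']:.1f}%")
        ax.set_xlabel("frequency band")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        p = outdir / "band_accuracy.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if mask is not None:
        grid = mask.p_matrix()
        fig, ax = plt.subplots(figsize=(5.5, 5))
        im = ax.imshow(grid, cmap="viridis_r", vmin=0, vmax=1)
        ky, kx = np.nonzero(grid < mask.alpha)
        ax.scatter(kx, ky, s=12, facecolors="none", edgecolors="yellow")
        labels = mask.node_labels
        if labels:
            ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
            ax.set_yticks(range(len(labels)), labels, fontsize=6)
        ax.set_title(f"ANOVA p-values (kept: p < {mask.alpha:g})")
        fig.colorbar(im, ax=ax, label="p-value")
        p = outdir / "p_grid.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

        # directed-edge diagram: arrow from source w to target v for kept pairs
        fig, ax = plt.subplots(figsize=(5, 5))
        for name, (px, py) in ELECTRODE_POS.items():
            if not labels or name in labels:
                ax.plot(px, py, "o", color="lightgray", ms=14, zorder=1)
                ax.annotate(name, (px, py), ha="center", va="center", fontsize=6)
        if labels:
            pos = [ELECTRODE_POS[lb] for lb in labels]
            for v, w in zip(ky, kx):
                if v == w:
                    continue
                (x0, y0), (x1, y1) = pos[w], pos[v]
                ax.annotate("", xy=(x1, y1), xytext=(x0, y0),
                            arrowprops=dict(arrowstyle="->", color="tab:red",
                                            alpha=0.4, lw=0.8))
        ax.set_xlim(-1.25, 1.25)
        ax.set_ylim(-1.25, 1.25)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title("significant directed connections (w → v)")
        p = outdir / "connectivity_arrows.png"
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    if summary is not None:
        p = outdir / "summary.tsv"
        summary.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write manifest, results and figures.

    Returns ``{"manifest": ..., "results": ..., "report": EvaluationReport,
    "mask": SelectionMask, "features": FeatureSet}``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings = _build_cohort(config)

    segments = []
    seg_counts = {}
    for rec in recordings:
        try:
            segs = preprocess.preprocess_recording(
                rec, amplitude_limit=config.amplitude_limit)
        except Exception as err:
            raise RuntimeError(f"preprocess failed for subject {rec.subject_id}: {err}"
                               ) from err
        seg_counts[rec.subject_id] = len(segs)
        segments.extend(segs)
    logger.info("preprocessed %d recordings into %d segments", len(recordings),
                len(segments))

    feats = connectivity.extract_features(segments, order=config.mvar_order)
    band_list = rhythm_bands(config.rhythm)
    mask = features.anova_select(feats, band_list, alpha=config.alpha)
    table = features.concat_bands(feats, band_list, mask=mask)
    x, y, groups = classify.table_xy(table)
    spec = classify.tune_svm(x, y, budget=config.tune_budget, k=config.k_folds,
                             seed=config.seed)
    report = classify.evaluate(x, y, spec, groups=groups, split=config.split,
                               k=config.k_folds, repeats=config.repeats,
                               seed=config.seed,
                               identifier=f"{config.rhythm} (masked, alpha={config.alpha})")

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {"python": platform.python_version(),
                     "numpy": np.__version__, "pandas": pd.__version__},
        "n_recordings": len(recordings),
        "segments_per_subject": seg_counts,
        "n_segments": len(segments),
        "n_features_kept": mask.n_kept,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    results = {"report": report.to_dict(), "svm": asdict(spec),
               "alpha": config.alpha, "kept": mask.n_kept}
    (outdir / "results.json").write_text(json.dumps(results, indent=1))
    mask.to_json(outdir / "selection_mask.json")

    summary = pd.DataFrame([{
        "rhythm": config.rhythm, "alpha": config.alpha,
        "n_bands": len(band_list), "l_f": mask.n_kept,
        "feature_length": len(band_list) * mask.n_kept,
        "accuracy_pct": 100 * report.accuracy,
        "accuracy_sd_pct": 100 * report.accuracy_sd,
    }])
    in_band = band_list[len(band_list) // 2]
    render_outputs(outdir, feature_set=feats, mask=mask, summary=summary,
                   band=in_band)
    return {"manifest": manifest, "results": results, "report": report,
            "mask": mask, "features": feats}
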