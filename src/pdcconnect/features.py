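"""Rhythm-band grouping, ANOVA feature selection, and multi-band tables.

A connectivity feature is one of the 324 directed electrode pairs (target v,
source w, diagonal included).  Selection tests each connectivity with a
two-group one-way ANOVA on segment-level values pooled across the bands of
interest and keeps those with raw p < α — deliberately without multiple-
testing correction, matching the thresholded-p workflow this pipeline
reproduces.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bands import rhythm_bands  # noqa: F401  (re-exported)
from .connectivity import VEC_LEN, FeatureSet, feature_columns

logger = logging.getLogger(__name__)


def connectivity_names(node_labels) -> list[str]:
    """'source->target' name for each of the 324 vector positions."""
    return [f"{node_labels[w]}->{node_labels[v]}"
            for v in range(len(node_labels)) for w in range(len(node_labels))]


@dataclass
class SelectionMask:
    """Per-connectivity ANOVA p-values and the keep mask at threshold α."""

    p_values: np.ndarray  # (324,)
    alpha: float
    node_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.p_values = np.asarray(self.p_values, dtype=float)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def keep(self) -> np.ndarray:
        return self.p_values < self.alpha

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def at(self, alpha: float) -> "SelectionMask":
        """Same p-values re-thresholded at a different α."""
        return SelectionMask(self.p_values, alpha, self.node_labels)

    def p_matrix(self) -> np.ndarray:
        """p-values reshaped to the (target, source) adjacency layout."""
        n = int(round(np.sqrt(self.p_values.size)))
        return self.p_values.reshape(n, n)

    def to_json(self, path) -> None:
        names = (connectivity_names(self.node_labels) if self.node_labels
                 else [f"c{i}" for i in range(self.p_values.size)])
        payload = {"alpha": self.alpha,
                   "node_labels": list(self.node_labels),
                   "p_values": dict(zip(names, map(float, self.p_values)))}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionMask":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(list(payload["p_values"].values())), payload["alpha"],
                   tuple(payload["node_labels"]))


def anova_select(features: FeatureSet, band_list, alpha: float = 0.01,
                 by_subject: bool = False) -> SelectionMask:
    """Two-group one-way ANOVA per connectivity, pooled across ``band_list``.

    The grouping unit is the segment (each segment-band value is one
    observation); ``by_subject=True`` averages within subject first, a
    leakage-aware variant.  Zero-variance connectivities get p = 1 by
    convention, with a log message.
    """
    try:
        band_idx = np.array([features.band_index.index(int(b))
                             for b in sorted(band_list)])
    except ValueError:
        missing = [b for b in band_list if b not in features.band_index]
        raise ValueError(f"bands not present: {missing}") from None
    labels = features.labels
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    groups = []
    for cls in classes:
        sel = features.tensor[labels == cls][:, band_idx, :]  # (n_cls, n_bands, 324)
        if by_subject:
            subj = features.subjects[labels == cls]
            pooled = sel.mean(axis=1)  # (n_cls, 324): per-segment band means
            df = pd.DataFrame(pooled).groupby(pd.Series(subj)).mean()
            vals = df.to_numpy(dtype=float)
        else:
            vals = sel.reshape(-1, sel.shape[-1]).astype(float)
        if vals.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 observations")
        groups.append(vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.f_oneway(groups[0], groups[1], axis=0)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        logger.info("%d zero-variance connectivities set to p=1", int(degenerate.sum()))
        p = np.where(degenerate, 1.0, p)
    return SelectionMask(p_values=p, alpha=alpha, node_labels=features.node_labels)


def concat_bands(features: FeatureSet, band_list, mask: SelectionMask | None = None) -> pd.DataFrame:
    """Feature table concatenating bands in ascending order (N_fb × l_f columns).

    If a mask is given, the same kept-connectivity filter applies to every
    band before concatenation; column names are ``b<band>_f<idx>``.
    """
    band_list = sorted(set(int(b) for b in band_list))
    if not band_list:
        raise ValueError("band_list is empty")
    missing = [b for b in band_list if b not in features.band_index]
    if missing:
        raise ValueError(f"bands not present: {missing}")
    keep = mask.keep if mask is not None else np.ones(VEC_LEN, dtype=bool)
    base_cols = np.asarray(feature_columns())[keep]
    blocks, names = [], []
    for b in band_list:
        blocks.append(features.band_matrix(b)[:, keep])
        names.extend([f"b{b:02d}_{c}" for c in base_cols])
    table = pd.DataFrame(np.concatenate(blocks, axis=1), columns=names)
    return pd.concat([features.meta.reset_index(drop=True), table], axis=1)


def rhythm_table(features: FeatureSet, rhythm: str,
                 mask: SelectionMask | None = None) -> pd.DataFrame:
    """Concatenated feature table for a named brain rhythm."""
    return concat_bands(features, rhythm_bands(rhythm), mask=mask)
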