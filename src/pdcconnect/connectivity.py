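"""Segment-level PDC adjacency matrices (PDCaM) and feature vectorization.

Each 2-s segment is fitted with an MVAR model on the 18 network channels
(the Cz reference is dropped before fitting), the squared column-normalized
PDC is evaluated on the 64-band grid (mean over ``k`` intra-band
frequencies), and each band's 18 × 18 adjacency matrix is flattened
row-major (target-major) into a 324-length feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bands
from .mvar import MVAR, MVARResults
from .preprocess import REFERENCE_LABEL, Segment

N_NODES = 18
VEC_LEN = N_NODES * N_NODES  # 324


def fit_mvar(seg: Segment, order: int | str = 5,
             exclude: str | None = REFERENCE_LABEL, max_order: int = 20) -> MVARResults:
    """Least-squares MVAR fit on a segment, reference channel excluded.

    ``order='auto'`` selects the lag order by BIC over 1..``max_order``; the
    fixed default (5) is what the pipeline and test suite use for
    reproducibility.
    """
    data = seg.data
    labels = tuple(seg.channel_labels)
    if exclude is not None:
        if exclude not in labels:
            raise ValueError(
                f"reference channel {exclude!r} not present in segment "
                f"{seg.subject_id}/{seg.index} (labels {labels})"
            )
        keep = [i for i, lb in enumerate(labels) if lb != exclude]
        data = data[keep]
    try:
        return MVAR(data).fit(order=order, max_order=max_order)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"segment {seg.subject_id}/{seg.index}: {err}"
        ) from err


@dataclass
class PDCStack:
    """64-band × nodes × nodes PDC tensor for one segment, with provenance."""

    values: np.ndarray  # (64, S, S) in [0, 1]
    band_edges: np.ndarray  # (64, 2) Hz
    node_labels: tuple[str, ...]
    subject_id: str = ""
    segment_index: int = -1
    class_label: str | None = None

    def matrix(self, band: int) -> np.ndarray:
        """18 × 18 adjacency matrix of band ``band`` (1-based)."""
        if not 1 <= band <= self.values.shape[0]:
            raise ValueError(f"band index out of range: {band}")
        return self.values[band - 1]


def band_pdcam(fitted: MVARResults, fs: float = 256.0, k: int = 4,
               node_labels: tuple[str, ...] | None = None,
               squared: bool = True, seg: Segment | None = None) -> PDCStack:
    """Band-averaged PDC adjacency stack of a fitted segment model."""
    values = fitted.band_pdc(fs, k=k, squared=squared)
    if node_labels is None:
        node_labels = tuple(f"ch{i}" for i in range(fitted.n_channels))
    return PDCStack(values=values, band_edges=bands.band_edges(),
                    node_labels=tuple(node_labels),
                    subject_id=getattr(seg, "subject_id", ""),
                    segment_index=getattr(seg, "index", -1),
                    class_label=getattr(seg, "class_label", None))


def vectorize(stack: PDCStack, band: int) -> np.ndarray:
    """Row-major (target-major) 324-length vector of one band's matrix.

    Entry (v, w) of the matrix lands at 0-based index (v−1)·18 + (w−1); the
    flattening is invertible via :func:`unvectorize`.
    """
    return stack.matrix(band).reshape(-1).copy()


def unvectorize(vec: np.ndarray, n_nodes: int = N_NODES) -> np.ndarray:
    vec = np.asarray(vec)
    if vec.size != n_nodes * n_nodes:
        raise ValueError(f"expected length {n_nodes * n_nodes}, got {vec.size}")
    return vec.reshape(n_nodes, n_nodes)


def feature_columns(n: int = VEC_LEN) -> list[str]:
    return [f"f{i + 1:03d}" for i in range(n)]


@dataclass
class FeatureSet:
    """Per-segment, per-band PDC feature vectors for a whole cohort.

    ``tensor`` is (n_segments, n_bands, 324) float32; ``meta`` has one row
    per segment (subject_id, class_label, segment index); ``band_index``
    maps tensor positions back to 1-based band numbers on the 64-band grid
    (all 64 unless extraction was restricted to a subset).
    """

    tensor: np.ndarray
    meta: pd.DataFrame
    node_labels: tuple[str, ...]
    band_index: tuple[int, ...] = tuple(range(1, bands.N_BANDS + 1))

    @property
    def n_segments(self) -> int:
        return self.tensor.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.meta["class_label"].to_numpy()

    @property
    def subjects(self) -> np.ndarray:
        return self.meta["subject_id"].to_numpy()

    def band_matrix(self, band: int) -> np.ndarray:
        """(n_segments, 324) feature matrix of one band (1-based index)."""
        try:
            pos = self.band_index.index(band)
        except ValueError:
            raise ValueError(f"band {band} not present in this feature set") from None
        return np.asarray(self.tensor[:, pos, :], dtype=float)

    def band_table(self, band: int) -> pd.DataFrame:
        """Feature table of one band: meta columns + f001..f324."""
        df = pd.DataFrame(self.band_matrix(band), columns=feature_columns())
        return pd.concat([self.meta.reset_index(drop=True), df], axis=1)

    def concat_bands(self, band_list, mask=None) -> pd.DataFrame:
        from .features import concat_bands

        return concat_bands(self, band_list, mask=mask)


def _batched_band_pdc(data: np.ndarray, order: int, fs: float, k: int,
                      squared: bool, band_list, chunk: int = 64) -> np.ndarray:
    """Vectorized OLS fit + band PDC for a stack of same-shape segments.

    ``data`` is (n_segments, S, L); returns (n_segments, n_bands, S*S)
    float32 for the bands in ``band_list``.  Numerically equivalent to
    fitting each segment with :class:`MVAR` at the same fixed order (normal
    equations instead of per-segment lstsq).
    """
    from .mvar import pdc_from_transfer

    n_seg, n_ch, n_samp = data.shape
    n_eff = n_samp - order
    p = order * n_ch
    if n_eff <= p:
        raise ValueError(f"segments too short ({n_samp}) for order {order}")

    n_bands = len(band_list)
    freqs = np.concatenate([bands.band_frequencies(b, k) for b in band_list])
    omegas = bands.hz_to_omega(freqs, fs)
    lags = np.arange(1, order + 1)
    phase = np.exp(-1j * omegas[:, None] * lags[None, :])  # (n_omega, order)
    eye = np.eye(n_ch)
    out = np.empty((n_seg, n_bands, n_ch * n_ch), dtype=np.float32)
    for s0 in range(0, n_seg, chunk):
        y = data[s0:s0 + chunk] - data[s0:s0 + chunk].mean(axis=2, keepdims=True)
        y = y.transpose(0, 2, 1)  # (c, L, S)
        targets = y[:, order:, :]
        design = np.concatenate([y[:, order - z: n_samp - z, :]
                                 for z in range(1, order + 1)], axis=2)
        design_t = design.swapaxes(1, 2)
        beta = np.linalg.solve(design_t @ design, design_t @ targets)  # (c, p, S)
        n_c = len(beta)
        coeffs = beta.transpose(0, 2, 1).reshape(n_c, n_ch, order, n_ch)
        coeffs = coeffs.transpose(0, 2, 1, 3)  # (c, order, S, S)
        a_bar = eye[None, None] - np.einsum("wz,nzvs->nwvs", phase, coeffs,
                                            optimize=True)
        pdc = pdc_from_transfer(a_bar, squared=squared)
        band_mean = pdc.reshape(n_c, n_bands, k, n_ch, n_ch).mean(axis=2)
        out[s0:s0 + chunk] = band_mean.reshape(n_c, n_bands, -1)
    return out


def extract_features(segments, order: int | str = 5, fs: float = 256.0,
                     k: int = 4, exclude: str | None = REFERENCE_LABEL,
                     squared: bool = True, band_list=None) -> FeatureSet:
    """Fit every segment and stack its vectorized PDC adjacency matrices.

    With a fixed integer ``order`` and homogeneous segment shapes the fit
    and spectral transform run batched over segments; ``order='auto'`` (or
    ragged input) falls back to the per-segment path.  ``band_list``
    restricts extraction to a subset of the 64 bands (default: all).
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to extract features from")
    band_list = (tuple(range(1, bands.N_BANDS + 1)) if band_list is None
                 else tuple(sorted(set(int(b) for b in band_list))))
    if any(not 1 <= b <= bands.N_BANDS for b in band_list):
        raise ValueError(f"band indices must be in 1..{bands.N_BANDS}")
    meta = pd.DataFrame([{"subject_id": s.subject_id, "class_label": s.class_label,
                          "segment": s.index} for s in segments])
    labels0 = tuple(segments[0].channel_labels)
    node_labels = tuple(lb for lb in labels0 if lb != exclude)
    homogeneous = all(tuple(s.channel_labels) == labels0
                      and s.data.shape == segments[0].data.shape for s in segments)
    if isinstance(order, int) and homogeneous:
        if exclude is not None and exclude not in labels0:
            raise ValueError(f"reference channel {exclude!r} not present")
        keep = [i for i, lb in enumerate(labels0) if lb != exclude]
        data = np.stack([s.data[keep] for s in segments])
        try:
            tensor = _batched_band_pdc(data, order, fs, k, squared, band_list)
            return FeatureSet(tensor=tensor, meta=meta, node_labels=node_labels,
                              band_index=band_list)
        except np.linalg.LinAlgError:
            pass  # singular normal equations somewhere: per-segment path names it
    idx = np.asarray(band_list, dtype=int) - 1
    tensors = []
    for seg in segments:
        fitted = fit_mvar(seg, order=order, exclude=exclude)
        stack = fitted.band_pdc(fs, k=k, squared=squared)
        tensors.append(stack[idx].reshape(len(band_list), -1).astype(np.float32))
    return FeatureSet(tensor=np.stack(tensors), meta=meta, node_labels=node_labels,
                      band_index=band_list)
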