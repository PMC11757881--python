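"""Frequency-band grid and brain-rhythm mapping.

The analysis band [0.1, 70) Hz is tiled by 64 equal-width bands of
(70 - 0.1)/64 ≈ 1.092 Hz each.  Bands are indexed 1..64.  Conventional EEG
rhythms map onto inclusive index ranges of this grid.
"""

from __future__ import annotations

import numpy as np

F_LO = 0.1
F_HI = 70.0
N_BANDS = 64
BAND_WIDTH_HZ = (F_HI - F_LO) / N_BANDS  # 1.0921875 Hz

#: rhythm name -> inclusive (first, last) band index on the 64-band grid
RHYTHM_BANDS = {
    "delta": (1, 6),
    "theta": (7, 12),
    "alpha": (13, 19),
    "beta": (20, 47),
    "gamma": (48, 64),
}


def band_edges() -> np.ndarray:
    """(64, 2) array of [low, high) band edges in Hz, tiling [0.1, 70) exactly."""
    lo = F_LO + BAND_WIDTH_HZ * np.arange(N_BANDS)
    return np.column_stack([lo, lo + BAND_WIDTH_HZ])


def band_frequencies(band: int, k: int = 4) -> np.ndarray:
    """``k`` equally spaced frequencies (Hz) inside band ``band`` (1-based).

    The points are the centres of ``k`` equal sub-intervals, so they lie
    strictly inside the band.
    """
    if not 1 <= band <= N_BANDS:
        raise ValueError(f"band index must be in 1..{N_BANDS}, got {band}")
    lo = F_LO + BAND_WIDTH_HZ * (band - 1)
    return lo + BAND_WIDTH_HZ * (np.arange(k) + 0.5) / k


def rhythm_bands(rhythm: str) -> list[int]:
    """Inclusive band-index list for a named brain rhythm.

    >>> rhythm_bands("gamma")[0], rhythm_bands("gamma")[-1]
    (48, 64)
    """
    try:
        first, last = RHYTHM_BANDS[rhythm.lower()]
    except KeyError:
        raise ValueError(
            f"unknown rhythm {rhythm!r}; expected one of {sorted(RHYTHM_BANDS)}"
        ) from None
    return list(range(first, last + 1))


def hz_to_omega(f_hz: np.ndarray | float, fs: float) -> np.ndarray:
    """Convert frequency in Hz to normalized angular frequency ω = 2πf/fs."""
    return 2.0 * np.pi * np.asarray(f_hz, dtype=float) / fs
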