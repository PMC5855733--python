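"""Discrete-wavelet-transform band statistics of the physicochemical tracks.

Each of the six property columns of a PC matrix is treated as a 1-D signal
and decomposed with a 4-level DWT cascade: at every level the current
approximation is split into a detail (high-frequency) and an approximation
(low-frequency) band, and the approximation is carried to the next level.
Per level the features are

    max, min, mean, std of the detail band   (4)
    max, min, mean, std of the approximation (4)
    first 5 approximation coefficients       (5)

i.e. 13 per level, 52 per property over 4 levels, 312 for all six tracks.
Standard deviations use the population convention (divide by n).  Short
approximation bands are zero-padded on the right to fill the 5-coefficient
slot, so the dimensionality is fixed for any window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .errors import SequenceLengthError
from .physchem import PROPERTY_NAMES

DEFAULT_WAVELET = "haar"
DEFAULT_MODE = "symmetric"
DEFAULT_LEVELS = 4

SLOT_NAMES: tuple[str, ...] = (
    "high_max", "high_min", "high_mean", "high_std",
    "low_max", "low_min", "low_mean", "low_std",
    "low_c1", "low_c2", "low_c3", "low_c4", "low_c5",
)
PER_LEVEL = len(SLOT_NAMES)  # 13
DWT_DIM = len(PROPERTY_NAMES) * DEFAULT_LEVELS * PER_LEVEL  # 312

DWT_NAMES: tuple[str, ...] = tuple(
    f"{prop}_L{level}_{slot}"
    for prop in PROPERTY_NAMES
    for level in range(1, DEFAULT_LEVELS + 1)
    for slot in SLOT_NAMES
)


@dataclass(frozen=True)
class DwtLevelFeatures:
    """The 13 per-level values: detail stats, approximation stats, head."""

    high_stats: tuple[float, float, float, float]
    low_stats: tuple[float, float, float, float]
    low_head: tuple[float, float, float, float, float]

    def as_array(self) -> np.ndarray:
        return np.array(self.high_stats + self.low_stats + self.low_head)


def _band_stats(band: np.ndarray) -> tuple[float, float, float, float]:
    return (
        float(band.max()),
        float(band.min()),
        float(band.mean()),
        float(band.std()),  # population std
    )


def dwt_column_features(
    signal,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> list[DwtLevelFeatures]:
    """Per-level band features of one property track.

    Boundary padding (``mode``) lets signals shorter than 2**levels be
    decomposed; the cascade simply keeps halving whatever remains.
    """
    approx = np.asarray(signal, dtype=float)
    if approx.size == 0:
        raise SequenceLengthError("cannot transform an empty signal")
    out: list[DwtLevelFeatures] = []
    for _ in range(levels):
        approx, detail = pywt.dwt(approx, wavelet, mode=mode)
        head = np.zeros(5)
        head[: min(5, approx.size)] = approx[:5]
        out.append(
            DwtLevelFeatures(
                high_stats=_band_stats(detail),
                low_stats=_band_stats(approx),
                low_head=tuple(head),
            )
        )
    return out


def dwt_features(
    pc: np.ndarray,
    levels: int = DEFAULT_LEVELS,
    wavelet: str = DEFAULT_WAVELET,
    mode: str = DEFAULT_MODE,
) -> np.ndarray:
    """The 312-dimensional DWT vector of a PC matrix.

    Property columns are processed in table order (Twist ... Rise), each
    contributing levels x 13 values (levels 1..4, slots in SLOT_NAMES order).
    """
    pc = np.asarray(pc, dtype=float)
    blocks = []
    for j in range(pc.shape[1]):
        for lv in dwt_column_features(pc[:, j], levels=levels, wavelet=wavelet, mode=mode):
            blocks.append(lv.as_array())
    return np.concatenate(blocks)
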