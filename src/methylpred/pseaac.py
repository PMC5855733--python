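"""Pseudo-composition autocovariance of the physicochemical tracks.

For property column i of a PC matrix with L rows, the lag-lambda feature is
the raw (unnormalised) autocovariance sum about the column mean:

    p(i, lambda) = sum_{n=1}^{L-lambda} (PC_i(n) - mean_i) (PC_i(n+lambda) - mean_i)

with lambda = 0..30, giving 31 values per property and 186 in total.  For
the canonical 41-bp windows L = 40; the upper limit generalises to L-lambda
so longer windows (e.g. 201-bp, L = 200) use the same lag range.  No
division by (L - lambda) or by the variance is applied.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError
from .physchem import PROPERTY_NAMES

DEFAULT_LAMBDA_MAX = 30
PSEAAC_DIM = len(PROPERTY_NAMES) * (DEFAULT_LAMBDA_MAX + 1)  # 186


def pseaac_names(lambda_max: int = DEFAULT_LAMBDA_MAX) -> tuple[str, ...]:
    return tuple(
        f"{prop}_lag{lam}"
        for prop in PROPERTY_NAMES
        for lam in range(lambda_max + 1)
    )


def pseaac_features(pc: np.ndarray, lambda_max: int = DEFAULT_LAMBDA_MAX) -> np.ndarray:
    """Autocovariance features, property-major then lag 0..lambda_max."""
    pc = np.asarray(pc, dtype=float)
    L = pc.shape[0]
    if L <= lambda_max:
        raise ConfigurationError(
            f"PC matrix has {L} rows but lambda_max={lambda_max}; the window "
            "must be at least lambda_max + 2 nucleotides long"
        )
    centered = pc - pc.mean(axis=0, keepdims=True)
    out = np.empty((pc.shape[1], lambda_max + 1), dtype=float)
    for lam in range(lambda_max + 1):
        if lam == 0:
            out[:, lam] = np.sum(centered * centered, axis=0)
        else:
            out[:, lam] = np.sum(centered[:-lam] * centered[lam:], axis=0)
    return out.ravel()
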