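"""k-gram composition features: overlapping 1-, 2- and 3-mer occurrence counts.

The 84 entries are ordered as the 4 single bases, the 16 dinucleotides, then
the 64 trinucleotides, each block lexicographic with A < C < G < T.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .physchem import BASES, validate_sequence

KGRAM_NAMES: tuple[str, ...] = tuple(
    "".join(p) for k in (1, 2, 3) for p in product(BASES, repeat=k)
)
KGRAM_DIM = len(KGRAM_NAMES)  # 4 + 16 + 64 = 84

_INDEX = {name: i for i, name in enumerate(KGRAM_NAMES)}


def kgram_features(sequence: str, normalize: bool = False) -> np.ndarray:
    """Occurrence counts of every 1/2/3-mer in the window (sliding, step 1).

    With ``normalize=True`` each block is divided by its window count
    (len, len-1, len-2); the default is raw counts.
    """
    seq = validate_sequence(sequence, min_length=3)
    counts = np.zeros(KGRAM_DIM, dtype=float)
    n = len(seq)
    for i in range(n):
        counts[_INDEX[seq[i]]] += 1
        if i + 2 <= n:
            counts[_INDEX[seq[i : i + 2]]] += 1
        if i + 3 <= n:
            counts[_INDEX[seq[i : i + 3]]] += 1
    if normalize:
        counts[:4] /= n
        counts[4:20] /= n - 1
        counts[20:] /= n - 2
    return counts
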