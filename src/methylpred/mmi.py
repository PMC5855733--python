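"""Multivariate mutual information features over unordered base tuples.

A window is summarised by 30 values: one 2-tuple mutual information per
canonical unordered pair (10 of them) and one 3-tuple value per canonical
unordered triple (20).  "Canonical" means the multiset written in sorted
order (A < C < G < T), so e.g. the adjacent windows CA and AC both count
toward the tuple AC.  Frequencies come from contiguous overlapping windows:
f1 over single bases, f2 over adjacent pairs, f3 over adjacent triples.

The 3-tuple statistic is a directed decomposition, not the symmetric
interaction information:

    I(N1 N2 N3) = f(N1,N2) ln[f(N1,N2) / (f(N1) f(N2))]
                + [f(N1,N3)/f(N3)] ln[f(N1,N3)/f(N3)]
                - [f(N1,N2,N3)/f(N2,N3)] ln[f(N1,N2,N3)/f(N2,N3)]

with the convention that any term whose numerator or denominator is zero
contributes zero, which keeps every feature finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from math import log

import numpy as np

from .errors import ConfigurationError
from .physchem import BASES, validate_sequence

TUPLES2: tuple[str, ...] = tuple(
    "".join(t) for t in combinations_with_replacement(BASES, 2)
)
TUPLES3: tuple[str, ...] = tuple(
    "".join(t) for t in combinations_with_replacement(BASES, 3)
)
MMI_NAMES: tuple[str, ...] = TUPLES2 + TUPLES3
MMI_DIM = len(MMI_NAMES)  # 10 + 20 = 30


def canonical(tup: str) -> str:
    """Sorted-order representative of an unordered base tuple."""
    return "".join(sorted(tup))


@dataclass(frozen=True)
class TupleFrequencies:
    """Single-base, pair and triple frequencies of one window."""

    f1: dict[str, float]
    f2: dict[str, float]
    f3: dict[str, float]


def tuple_frequencies(sequence: str, pseudocount: float = 0.0) -> TupleFrequencies:
    """Frequencies of bases, adjacent unordered pairs and adjacent triples.

    Each dictionary sums to 1 (counts divided by the window count: n, n-1,
    n-2).  An optional additive pseudocount (per category, before
    normalisation) is available but off by default.
    """
    seq = validate_sequence(sequence, min_length=3)
    n = len(seq)
    c1 = {b: pseudocount for b in BASES}
    c2 = {t: pseudocount for t in TUPLES2}
    c3 = {t: pseudocount for t in TUPLES3}
    for ch in seq:
        c1[ch] += 1
    for i in range(n - 1):
        c2[canonical(seq[i : i + 2])] += 1
    for i in range(n - 2):
        c3[canonical(seq[i : i + 3])] += 1
    z1 = n + 4 * pseudocount
    z2 = (n - 1) + 10 * pseudocount
    z3 = (n - 2) + 20 * pseudocount
    return TupleFrequencies(
        f1={k: v / z1 for k, v in c1.items()},
        f2={k: v / z2 for k, v in c2.items()},
        f3={k: v / z3 for k, v in c3.items()},
    )


def _plogr(num: float, den: float) -> float:
    # num * ln(num/den), vanishing when either side is 0
    if num <= 0.0 or den <= 0.0:
        return 0.0
    return num * log(num / den)


def _rlogr(num: float, den: float) -> float:
    # (num/den) * ln(num/den), vanishing when either side is 0
    if num <= 0.0 or den <= 0.0:
        return 0.0
    r = num / den
    return r * log(r)


def mmi2(pair: str, freqs: TupleFrequencies) -> float:
    """2-tuple mutual information of a canonical pair.

    Zero whenever the pair frequency factorises into the base frequencies.
    """
    if pair not in freqs.f2:
        raise ConfigurationError(
            f"{pair!r} is not a canonical 2-tuple; use canonical() first"
        )
    n1, n2 = pair
    return _plogr(freqs.f2[pair], freqs.f1[n1] * freqs.f1[n2])


def mmi3(triple: str, freqs: TupleFrequencies) -> float:
    """3-tuple mutual information of a canonical triple N1 <= N2 <= N3."""
    if triple not in freqs.f3:
        raise ConfigurationError(
            f"{triple!r} is not a canonical 3-tuple; use canonical() first"
        )
    n1, n2, n3 = triple
    f12 = freqs.f2[canonical(n1 + n2)]
    f13 = freqs.f2[canonical(n1 + n3)]
    f23 = freqs.f2[canonical(n2 + n3)]
    term1 = _plogr(f12, freqs.f1[n1] * freqs.f1[n2])
    term2 = _rlogr(f13, freqs.f1[n3])
    term3 = _rlogr(freqs.f3[triple], f23)
    return term1 + term2 - term3


def mmi_features(sequence: str, pseudocount: float = 0.0) -> np.ndarray:
    """The 30-dimensional MMI vector: 10 pair values then 20 triple values."""
    freqs = tuple_frequencies(sequence, pseudocount=pseudocount)
    out = np.empty(MMI_DIM, dtype=float)
    for i, t in enumerate(TUPLES2):
        out[i] = mmi2(t, freqs)
    for i, t in enumerate(TUPLES3):
        out[len(TUPLES2) + i] = mmi3(t, freqs)
    return out
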