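"""Dinucleotide physicochemical constants and the per-sequence property matrix.

A DNA window of length l+1 is mapped to an l x 6 matrix: each adjacent
dinucleotide contributes one row of six structural properties (Twist, Tilt,
Roll, Shift, Slide, Rise).  The shipped constants derive from crystallographic
dinucleotide step parameters and satisfy reverse-complement symmetry, so the
property track of a window and of its reverse complement are mirror images.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import AlphabetError, ConfigurationError, SequenceLengthError

PROPERTY_NAMES = ("Twist", "Tilt", "Roll", "Shift", "Slide", "Rise")
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)


def revcomp(sequence: str) -> str:
    """Reverse complement of an A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PropertyTable:
    """16 x 6 lookup: ordered dinucleotide -> six structural property values."""

    values: dict[str, tuple[float, ...]]
    property_names: tuple[str, ...] = PROPERTY_NAMES

    def __post_init__(self):
        if set(self.values) != set(DINUCLEOTIDES):
            missing = set(DINUCLEOTIDES) - set(self.values)
            extra = set(self.values) - set(DINUCLEOTIDES)
            raise ConfigurationError(
                f"property table must have exactly the 16 dinucleotides; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for k, v in self.values.items():
            if len(v) != len(self.property_names):
                raise ConfigurationError(
                    f"property row {k} has {len(v)} values, "
                    f"expected {len(self.property_names)}"
                )

    def as_array(self) -> np.ndarray:
        """16 x 6 array in DINUCLEOTIDES order (AA, AC, ... TT)."""
        return np.array([self.values[d] for d in DINUCLEOTIDES], dtype=float)

    def is_revcomp_symmetric(self, atol: float = 0.0) -> bool:
        return all(
            np.allclose(self.values[d], self.values[revcomp(d)], atol=atol)
            for d in DINUCLEOTIDES
        )


def load_property_table(path: str | Path | None = None) -> PropertyTable:
    """Load a property table from a tab-separated file.

    The file has comment lines starting with '#', a header row, then 16 rows
    of dinucleotide followed by six numbers.  With ``path=None`` the packaged
    default constants are loaded.  Alternative property sets can be supplied
    through this hook.
    """
    if path is None:
        ref = importlib.resources.files("methylpred") / "data/dinucleotide_properties.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    prop_names = tuple(header[1:])
    values: dict[str, tuple[float, ...]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        values[parts[0]] = tuple(float(x) for x in parts[1:])
    return PropertyTable(values=values, property_names=prop_names)


_DEFAULT_TABLE: PropertyTable | None = None


def build_property_table() -> PropertyTable:
    """The packaged default 16 x 6 property table (cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_property_table()
    return _DEFAULT_TABLE


def validate_sequence(sequence: str, min_length: int = 2, context: str = "") -> str:
    """Upper-case and check alphabet/length; returns the normalised sequence."""
    seq = sequence.upper()
    if len(seq) < min_length:
        prefix = f"{context}: " if context else ""
        raise SequenceLengthError(
            f"{prefix}sequence of length {len(seq)} is shorter than the "
            f"required minimum {min_length}"
        )
    for i, ch in enumerate(seq):
        if ch not in BASES:
            raise AlphabetError(ch, i, context)
    return seq


def build_pc_matrix(sequence: str, table: PropertyTable | None = None) -> np.ndarray:
    """Physicochemical property matrix of a window.

    Parameters
    ----------
    sequence
        DNA string over {A, C, G, T}, length >= 2.
    table
        Property lookup; defaults to the packaged constants.

    Returns
    -------
    (len(sequence) - 1, 6) float array; row i holds the six property values
    of the dinucleotide at positions (i, i+1).
    """
    seq = validate_sequence(sequence, min_length=2)
    if table is None:
        table = build_property_table()
    lut = table.as_array()
    idx = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(256, dtype=np.int64)
    for k, b in enumerate(BASES):
        code[ord(b)] = k
    base_idx = code[idx]
    dinuc_idx = base_idx[:-1] * 4 + base_idx[1:]
    return lut[dinuc_idx]
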