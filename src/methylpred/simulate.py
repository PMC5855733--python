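"""Synthetic labeled-window generator.

Emulates the two-class window datasets the predictor is trained on: positive
(methylated) windows differ from negatives both compositionally — a short
consensus motif planted near the centre with a per-position match
probability — and physicochemically, through a shift in G+C content that
propagates into the dinucleotide property tracks.  All windows have an odd
length with a C forced at the centre, so every record passes the feature
extractors.  The generator can also emit a toy multi-chromosome genome with
a read-count site table that round-trips through window extraction and
site labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import (
    NEGATIVE,
    POSITIVE,
    LabeledDataset,
    SiteRecord,
    WindowRecord,
)
from .errors import ConfigurationError

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    n_pos / n_neg
        Class sizes (positives carry the signal).
    window_length
        Odd window size; 41 mirrors the benchmark-style windows.
    motif
        Consensus planted immediately right of the central C in positives;
        each motif position matches the consensus with probability
        ``motif_match_prob``, otherwise a random base is used.
    background
        Base probabilities (A, C, G, T) for both classes.
    gc_shift
        Added G+C fraction in positive windows (physicochemical signal).
    """

    n_pos: int = 200
    n_neg: int = 200
    window_length: int = 41
    motif: str | None = "CGCGG"
    motif_match_prob: float = 0.9
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gc_shift: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.window_length % 2 == 0 or self.window_length < 5:
            raise ConfigurationError(
                f"window_length must be odd and >= 5, got {self.window_length}"
            )
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ConfigurationError("background probabilities must sum to 1")
        if self.motif and len(self.motif) > self.window_length // 2:
            raise ConfigurationError(
                f"motif of length {len(self.motif)} does not fit in the "
                f"{self.window_length // 2} positions right of the centre"
            )


def signal_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The planted-signal conditions: strong motif plus a G+C shift."""
    return SyntheticSpec(seed=seed, **overrides)


def null_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """Exchangeable classes: no motif, no G+C shift."""
    return SyntheticSpec(motif=None, gc_shift=0.0, seed=seed, **overrides)


def _class_probs(spec: SyntheticSpec, positive: bool) -> np.ndarray:
    p = np.array(spec.background, dtype=float)
    if positive and spec.gc_shift:
        gc = p[1] + p[2]
        at = p[0] + p[3]
        gc_new = min(gc + spec.gc_shift, 0.98)
        p[[1, 2]] *= gc_new / gc
        p[[0, 3]] *= (1.0 - gc_new) / at
    return p


def _draw_window(rng, spec: SyntheticSpec, positive: bool) -> str:
    n = spec.window_length
    center = n // 2
    probs = _class_probs(spec, positive)
    chars = rng.choice(BASES, size=n, p=probs)
    chars[center] = "C"
    if positive and spec.motif:
        for k, base in enumerate(spec.motif):
            if rng.random() < spec.motif_match_prob:
                chars[center + 1 + k] = base
    return "".join(chars)


def generate(spec: SyntheticSpec) -> LabeledDataset:
    """Deterministic (seeded) two-class window dataset."""
    rng = np.random.default_rng(spec.seed)
    records = [
        WindowRecord(f"pos_{i}", _draw_window(rng, spec, True), POSITIVE)
        for i in range(spec.n_pos)
    ] + [
        WindowRecord(f"neg_{i}", _draw_window(rng, spec, False), NEGATIVE)
        for i in range(spec.n_neg)
    ]
    return LabeledDataset(records)


def generate_genome(spec: SyntheticSpec, n_chromosomes: int = 12,
                    spacing: int | None = None):
    """Toy genome + site table that reproduce :func:`generate`-style windows.

    Windows are embedded back-to-back (with ``spacing`` background bases
    between them, default window_length) into ``n_chromosomes`` chromosomes
    named "1".."n".  Each embedded site gets a read-count record consistent
    with its label (methylated majority for positives, unmethylated for
    negatives), so ``label_sites`` + ``extract_windows`` recover the same
    windows and labels.

    Returns (genome dict, list of SiteRecord, LabeledDataset of the
    embedded windows re-identified by coordinate).
    """
    rng = np.random.default_rng(spec.seed + 1)
    dataset = generate(spec)
    spacing = spacing if spacing is not None else spec.window_length
    flank = spec.window_length // 2
    per_chrom = -(-len(dataset) // n_chromosomes)  # ceil
    genome: dict[str, str] = {}
    sites: list[SiteRecord] = []
    records = list(dataset)
    relabeled: list[WindowRecord] = []
    for c in range(n_chromosomes):
        chrom = str(c + 1)
        chunk = records[c * per_chrom : (c + 1) * per_chrom]
        parts, pos_cursor = [], 0
        pad = "".join(rng.choice(BASES, size=spacing, p=np.array(spec.background)))
        for rec in chunk:
            parts.append(pad)
            pos_cursor += len(pad)
            center_pos = pos_cursor + flank + 1  # 1-based position of the C
            parts.append(rec.sequence)
            pos_cursor += len(rec.sequence)
            total = int(rng.integers(6, 15))
            if rec.label == POSITIVE:
                meth = int(rng.integers(total // 2 + 1, total + 1))
            else:
                meth = int(rng.integers(0, (total + 1) // 2))
            sites.append(SiteRecord(chrom, center_pos, meth, total))
            relabeled.append(
                replace(rec, identifier=f"{chrom}:{center_pos}",
                        chromosome=chrom, position=center_pos)
            )
            pad = "".join(
                rng.choice(BASES, size=spacing, p=np.array(spec.background))
            )
        parts.append(pad)
        genome[chrom] = "".join(parts)
    return genome, sites, LabeledDataset(relabeled)


def write_genome_fasta(path, genome: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
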