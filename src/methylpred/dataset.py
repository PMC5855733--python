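"""Labeled window datasets: extraction, labeling, de-duplication, balancing.

Windows are fixed-length odd sequences centred on a candidate cytosine.  A
dataset can be assembled either from pre-cut window FASTA files or from a
reference genome plus a site table (chromosome, 1-based position, methylated
reads, total reads).  Sites are labeled by read majority after a minimum
coverage filter; exact duplicate windows within a class are collapsed, and
windows appearing in both classes are removed from both.  Class imbalance is
corrected in feature space with SMOTE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, DataError
from .physchem import revcomp, validate_sequence

POSITIVE, NEGATIVE = 1, 0


@dataclass(frozen=True)
class SiteRecord:
    """One CpG site with bisulfite read support."""

    chromosome: str
    position: int  # 1-based coordinate of the cytosine
    methylated_reads: int
    total_reads: int

    def __post_init__(self):
        if not 0 <= self.methylated_reads <= self.total_reads:
            raise DataError(
                f"site {self.chromosome}:{self.position}: methylated reads "
                f"{self.methylated_reads} outside [0, {self.total_reads}]"
            )


@dataclass(frozen=True)
class WindowRecord:
    identifier: str
    sequence: str
    label: int  # POSITIVE (methylated) or NEGATIVE
    origin: str = "real"  # "real" or "synthetic"
    chromosome: str | None = None
    position: int | None = None


@dataclass
class LabeledDataset:
    """A list of same-length windows with unique identifiers."""

    records: list[WindowRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.identifier for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("record identifiers must be unique")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) > 1:
            raise DataError(f"all windows must share one length, got {sorted(lengths)}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    def subset(self, keep) -> "LabeledDataset":
        return LabeledDataset([r for r in self.records if keep(r)])


# ---------------------------------------------------------------------------
# site labeling and window extraction

def load_genome(path):
    """Open a reference FASTA with indexed access for window extraction.

    Returns a pyfaidx handle usable as ``genome[chrom][start:end] -> str``;
    a plain dict of chromosome strings works interchangeably.
    """
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def label_sites(sites, min_reads: int = 4):
    """Assign methylation labels by read majority.

    Sites with total_reads < min_reads are discarded (insufficient
    coverage); a site is methylated when methylated reads outnumber
    unmethylated reads.  Exact ties are discarded as ambiguous and reported.

    Returns (list of (SiteRecord, label), report dict).
    """
    labeled = []
    report = {"kept": 0, "low_coverage": 0, "ambiguous_tie": 0}
    for s in sites:
        if s.total_reads < min_reads:
            report["low_coverage"] += 1
            continue
        unmeth = s.total_reads - s.methylated_reads
        if s.methylated_reads == unmeth:
            report["ambiguous_tie"] += 1
            continue
        labeled.append((s, POSITIVE if s.methylated_reads > unmeth else NEGATIVE))
        report["kept"] += 1
    return labeled, report


def extract_windows(genome, labeled_sites, flank: int = 20,
                    require_center_c: bool = True,
                    reverse_complement_minus: bool = False,
                    strands=None):
    """Cut (2*flank + 1)-length windows centred on each labeled site.

    Parameters
    ----------
    genome
        Mapping chromosome -> sequence (a dict of strings or a
        ``pyfaidx.Fasta``; anything supporting ``genome[chrom][a:b]``).
    labeled_sites
        (SiteRecord, label) pairs as produced by :func:`label_sites`.
    flank
        Bases on each side of the site; 20 gives 41-bp windows, 100 gives
        201-bp.
    require_center_c
        Skip (and report) windows whose central base is not C.
    reverse_complement_minus, strands
        Optional per-site strand list ('+'/'-'); minus-strand windows are
        reverse-complemented when enabled.

    Returns (LabeledDataset, skipped) with skipped = list of (site, reason).
    """
    if flank < 1:
        raise ConfigurationError(f"flank must be >= 1, got {flank}")
    records, skipped = [], []
    for k, (site, label) in enumerate(labeled_sites):
        chrom_seq = genome[site.chromosome]
        chrom_len = len(chrom_seq)
        start = site.position - 1 - flank  # 0-based inclusive
        end = site.position + flank  # 0-based exclusive
        if start < 0 or end > chrom_len:
            skipped.append((site, "out-of-bounds"))
            continue
        window = str(chrom_seq[start:end]).upper()
        if strands is not None and reverse_complement_minus and strands[k] == "-":
            window = revcomp(window)
        if require_center_c and window[flank] != "C":
            skipped.append((site, f"center base {window[flank]!r} is not C"))
            continue
        records.append(
            WindowRecord(
                identifier=f"{site.chromosome}:{site.position}",
                sequence=window,
                label=label,
                chromosome=site.chromosome,
                position=site.position,
            )
        )
    return LabeledDataset(records), skipped


# ---------------------------------------------------------------------------
# redundancy handling

def deduplicate(positive: LabeledDataset, negative: LabeledDataset):
    """Collapse within-class exact duplicates; drop cross-class conflicts.

    Within one class, only the first occurrence of each exact sequence is
    kept.  A sequence present in both classes is contradictory evidence and
    is removed from both.  Similarity-based clustering (e.g. CD-HIT) is out
    of scope; :func:`apply_representatives` accepts an externally produced
    representative list.

    Returns (positive', negative', report).
    """
    if len(positive) and len(negative):
        lp = len(positive.records[0].sequence)
        ln = len(negative.records[0].sequence)
        if lp != ln:
            raise DataError(f"window length mismatch between classes: {lp} vs {ln}")

    def collapse(ds):
        seen, kept, dropped = set(), [], 0
        for r in ds:
            if r.sequence in seen:
                dropped += 1
            else:
                seen.add(r.sequence)
                kept.append(r)
        return kept, dropped

    pos_kept, pos_dup = collapse(positive)
    neg_kept, neg_dup = collapse(negative)
    pos_seqs = {r.sequence for r in pos_kept}
    neg_seqs = {r.sequence for r in neg_kept}
    conflicts = pos_seqs & neg_seqs
    report = {
        "positive_duplicates_removed": pos_dup,
        "negative_duplicates_removed": neg_dup,
        "cross_set_conflicts_removed": len(conflicts),
    }
    return (
        LabeledDataset([r for r in pos_kept if r.sequence not in conflicts]),
        LabeledDataset([r for r in neg_kept if r.sequence not in conflicts]),
        report,
    )


def apply_representatives(dataset: LabeledDataset, representative_ids) -> LabeledDataset:
    """Keep only records named in an external cluster-representative list."""
    keep = set(representative_ids)
    return dataset.subset(lambda r: r.identifier in keep)


# ---------------------------------------------------------------------------
# class balancing (SMOTE)

def smote_balance(features, labels, k_neighbors: int = 5, seed: int | None = None):
    """Equalise class counts by synthetic minority oversampling.

    Each synthetic row is x + u*(x_nn - x) with u ~ Uniform[0, 1], where x is
    a random minority row and x_nn one of its ``k_neighbors`` nearest
    minority neighbours (Euclidean distance).  Original rows are kept
    unchanged and come first; synthetic rows are flagged origin="synthetic".

    Returns (features', labels', origins') as DataFrame/Series aligned on a
    common index; synthetic rows get identifiers ``smote_<i>``.
    """
    X = pd.DataFrame(features)
    y = pd.Series(np.asarray(labels), index=X.index, name="label")
    counts = y.value_counts()
    if len(counts) != 2:
        raise DataError(f"need exactly 2 classes, got {len(counts)}")
    minority = counts.idxmin()
    n_new = int(counts.max() - counts.min())
    origins = pd.Series("real", index=X.index, name="origin")
    if n_new == 0:
        return X, y, origins
    Xmin = X[y == minority]
    if len(Xmin) <= k_neighbors:
        raise DataError(
            f"minority class has {len(Xmin)} rows; needs more than "
            f"k_neighbors={k_neighbors}"
        )
    rng = np.random.default_rng(seed)
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xmin.values)
    _, idx = nn.kneighbors(Xmin.values)  # column 0 is the point itself
    base = rng.integers(0, len(Xmin), size=n_new)
    pick = rng.integers(1, k_neighbors + 1, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    xb = Xmin.values[base]
    xn = Xmin.values[idx[base, pick]]
    synth = xb + u[:, None] * (xn - xb)
    synth_df = pd.DataFrame(
        synth, columns=X.columns, index=[f"smote_{i}" for i in range(n_new)]
    )
    X_out = pd.concat([X, synth_df])
    y_out = pd.concat([y, pd.Series(minority, index=synth_df.index, name="label")])
    origins = pd.concat(
        [origins, pd.Series("synthetic", index=synth_df.index, name="origin")]
    )
    return X_out, y_out, origins


# ---------------------------------------------------------------------------
# file dialects

def read_site_table(path) -> list[SiteRecord]:
    """Tab-separated site table with header: chrom, pos, methylated_reads, total_reads."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns[:4])
    return [
        SiteRecord(str(r[cols[0]]), int(r[cols[1]]), int(r[cols[2]]), int(r[cols[3]]))
        for _, r in df.iterrows()
    ]


def write_site_table(path, sites) -> None:
    pd.DataFrame(
        [
            {
                "chrom": s.chromosome,
                "pos": s.position,
                "methylated_reads": s.methylated_reads,
                "total_reads": s.total_reads,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def _record_description(r: WindowRecord) -> str:
    parts = [f"label={r.label}", f"origin={r.origin}"]
    if r.chromosome is not None:
        parts.append(f"chrom={r.chromosome}")
    if r.position is not None:
        parts.append(f"pos={r.position}")
    return " ".join(parts)


def write_windows_fasta(path, dataset: LabeledDataset) -> None:
    """Windows as FASTA; label/origin/coordinates encoded in the description."""
    recs = [
        SeqRecord(Seq(r.sequence), id=r.identifier, description=_record_description(r))
        for r in dataset
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_windows_fasta(path, default_label: int | None = None) -> LabeledDataset:
    """Read a window FASTA written by :func:`write_windows_fasta`.

    Records without a ``label=`` tag take ``default_label`` (error if None).
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        if "label" in tags:
            label = int(tags["label"])
        elif default_label is not None:
            label = default_label
        else:
            raise DataError(f"record {rec.id}: no label tag and no default label")
        seq = validate_sequence(str(rec.seq), min_length=2, context=rec.id)
        records.append(
            WindowRecord(
                identifier=rec.id,
                sequence=seq,
                label=label,
                origin=tags.get("origin", "real"),
                chromosome=tags.get("chrom"),
                position=int(tags["pos"]) if "pos" in tags else None,
            )
        )
    return LabeledDataset(records)
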