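import numpy as np
import pytest

from methylpred.dataset import (
    LabeledDataset,
    NEGATIVE,
    POSITIVE,
    SiteRecord,
    WindowRecord,
    deduplicate,
    extract_windows,
    label_sites,
    read_windows_fasta,
    smote_balance,
    write_windows_fasta,
)
from methylpred.errors import DataError

from conftest import random_seq


def make_ds(seqs, label=POSITIVE, prefix="r"):
    return LabeledDataset(
        [WindowRecord(f"{prefix}{i}", s, label) for i, s in enumerate(seqs)]
    )


class TestLabelSites:
    def test_majority_methylated(self):
        labeled, _ = label_sites([SiteRecord("1", 10, 5, 6)])
        assert labeled[0][1] == POSITIVE

    def test_low_coverage_discarded(self):
        labeled, report = label_sites([SiteRecord("1", 10, 1, 3)])
        assert labeled == [] and report["low_coverage"] == 1

    def test_tie_discarded(self):
        labeled, report = label_sites([SiteRecord("1", 10, 2, 4)])
        assert labeled == [] and report["ambiguous_tie"] == 1

    def test_majority_unmethylated(self):
        labeled, _ = label_sites([SiteRecord("1", 10, 1, 5)])
        assert labeled[0][1] == NEGATIVE

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataError):
            SiteRecord("1", 10, 7, 5)


class TestExtractWindows:
    def setup_method(self):
        self.rng = np.random.default_rng(7)
        chrom = list(random_seq(self.rng, 300))
        chrom[99] = "C"  # site at 1-based position 100
        self.genome = {"1": "".join(chrom), "toy": random_seq(self.rng, 60)}

    def test_flank_20_gives_41bp_centered(self):
        sites = [(SiteRecord("1", 100, 5, 6), POSITIVE)]
        ds, skipped = extract_windows(self.genome, sites, flank=20)
        assert not skipped
        rec = ds.records[0]
        assert len(rec.sequence) == 41
        assert rec.sequence[20] == "C"  # 1-based center index 21
        assert rec.sequence == self.genome["1"][79:120]

    def test_flank_100_gives_201bp(self):
        sites = [(SiteRecord("1", 150, 5, 6), POSITIVE)]
        genome = {"1": self.genome["1"][:149] + "C" + self.genome["1"][150:]}
        ds, _ = extract_windows(genome, sites, flank=100, require_center_c=False)
        assert len(ds.records[0].sequence) == 201

    def test_out_of_bounds_skipped(self):
        sites = [(SiteRecord("toy", 50, 5, 6), POSITIVE)]
        ds, skipped = extract_windows(self.genome, sites, flank=100)
        assert len(ds) == 0
        assert skipped[0][1] == "out-of-bounds"

    def test_non_c_center_reported(self):
        pos = next(
            i + 1 for i, ch in enumerate(self.genome["1"][30:270], start=30)
            if ch != "C"
        )
        sites = [(SiteRecord("1", pos, 5, 6), POSITIVE)]
        ds, skipped = extract_windows(self.genome, sites, flank=20)
        assert len(ds) == 0 and "not C" in skipped[0][1]


class TestDeduplicate:
    def test_within_set_collapse(self):
        pos = make_ds(["ACGTA", "ACGTA", "CCGTA"])
        neg = make_ds(["TTGTA"], NEGATIVE, "n")
        p, n, report = deduplicate(pos, neg)
        assert [r.sequence for r in p] == ["ACGTA", "CCGTA"]
        assert len(n) == 1
        assert report["positive_duplicates_removed"] == 1

    def test_cross_set_conflict_removes_both(self):
        p, n, report = deduplicate(
            make_ds(["ACGTA"]), make_ds(["ACGTA"], NEGATIVE, "n")
        )
        assert len(p) == 0 and len(n) == 0
        assert report["cross_set_conflicts_removed"] == 1

    def test_disjoint_unchanged(self):
        p, n, _ = deduplicate(
            make_ds(["ACGTA", "CCCCC"]), make_ds(["TTTTT"], NEGATIVE, "n")
        )
        assert len(p) == 2 and len(n) == 1

    def test_idempotent(self, rng):
        pos = make_ds([random_seq(rng, 11) for _ in range(20)] * 2)
        neg = make_ds([random_seq(rng, 11) for _ in range(30)], NEGATIVE, "n")
        p1, n1, _ = deduplicate(pos, neg)
        p2, n2, _ = deduplicate(p1, n1)
        assert [r.identifier for r in p1] == [r.identifier for r in p2]
        assert [r.identifier for r in n1] == [r.identifier for r in n2]


class TestSmote:
    def make_features(self, rng, n_min=20, n_maj=50):
        X = np.vstack([rng.normal(0, 1, (n_min, 5)), rng.normal(4, 1, (n_maj, 5))])
        y = np.array([1] * n_min + [0] * n_maj)
        return X, y

    def test_balances_counts_and_keeps_originals(self, rng):
        X, y = self.make_features(rng)
        Xb, yb, origins = smote_balance(X, y, seed=0)
        assert (yb == 1).sum() == (yb == 0).sum() == 50
        assert (origins == "synthetic").sum() == 30
        np.testing.assert_array_equal(Xb.values[: len(X)], X)

    def test_already_balanced_no_synthetics(self, rng):
        X, y = self.make_features(rng, 30, 30)
        Xb, yb, origins = smote_balance(X, y, seed=0)
        assert len(Xb) == 60 and (origins == "synthetic").sum() == 0

    def test_synthetic_rows_on_neighbor_segments(self, rng):
        X, y = self.make_features(rng)
        Xb, yb, origins = smote_balance(X, y, k_neighbors=5, seed=1)
        Xmin = X[y == 1]
        for row in Xb.values[(origins == "synthetic").values]:
            # row = x + u (x_nn - x): collinear with some minority pair,
            # with u in [0, 1]
            ok = False
            for a in Xmin:
                d = row - a
                if np.allclose(d, 0, atol=1e-9):
                    ok = True
                    break
                for b in Xmin:
                    ab = b - a
                    if np.linalg.norm(ab) == 0:
                        continue
                    u = (d @ ab) / (ab @ ab)
                    if 0 <= u <= 1 and np.allclose(a + u * ab, row, atol=1e-8):
                        ok = True
                        break
                if ok:
                    break
            assert ok

    def test_minority_too_small(self, rng):
        X, y = self.make_features(rng, n_min=4)
        with pytest.raises(DataError):
            smote_balance(X, y, k_neighbors=5)

    def test_deterministic_given_seed(self, rng):
        X, y = self.make_features(rng)
        Xa, *_ = smote_balance(X, y, seed=42)
        Xb, *_ = smote_balance(X, y, seed=42)
        np.testing.assert_array_equal(Xa.values, Xb.values)


class TestFastaDialect:
    def test_roundtrip(self, tmp_path, rng):
        ds = LabeledDataset(
            [
                WindowRecord("a", random_seq(rng, 41), POSITIVE, "real", "3", 500),
                WindowRecord("b", random_seq(rng, 41), NEGATIVE),
            ]
        )
        path = tmp_path / "win.fa"
        write_windows_fasta(path, ds)
        back = read_windows_fasta(path)
        assert [(r.identifier, r.sequence, r.label, r.chromosome, r.position)
                for r in back] == [
            (r.identifier, r.sequence, r.label, r.chromosome, r.position)
            for r in ds
        ]


def test_dataset_invariants():
    with pytest.raises(DataError):
        LabeledDataset([WindowRecord("a", "ACGTA", 1), WindowRecord("a", "CCGTA", 1)])
    with pytest.raises(DataError):
        LabeledDataset([WindowRecord("a", "ACGTA", 1), WindowRecord("b", "CCTA", 1)])
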