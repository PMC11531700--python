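"""Database preprocessing, binary round-trip, binning, batching, workers."""

import gzip
import itertools

import numpy as np
import pytest
from Bio.SeqIO.FastaIO import SimpleFastaParser

from lanesw.alphabet import PROTEIN
from lanesw.db import (
    DEFAULT_RESIDUE_BUDGET,
    LONG_BIN,
    MAX_UNTILED_LENGTH,
    N_BINS,
    assign_to_workers,
    bin_of,
    iterate_batches,
    load_db,
    makedb,
    partition_by_length,
    select_kernel_config,
)
from lanesw.fixtures import gen_distributed_db


@pytest.fixture()
def small_fasta(tmp_path):
    text = ">s1 first\nMKVLAATRSW\n>s2 second\nMKVLA\n>s3 third\nMKVLAAT\n"
    path = tmp_path / "in.fasta"
    path.write_text(text)
    return path


class TestMakeDB:
    def test_sorted_by_length(self, small_fasta, tmp_path):
        db = load_db(makedb(small_fasta, tmp_path / "db"))
        assert db.lengths.tolist() == [5, 7, 10]
        assert db.ids == ["s2", "s3", "s1"]
        assert db.headers[2] == "s1 first"

    def test_gzip_transparent(self, small_fasta, tmp_path):
        gz = tmp_path / "in.fasta.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(small_fasta.read_text())
        d1 = makedb(small_fasta, tmp_path / "d1")
        d2 = makedb(gz, tmp_path / "d2")
        assert (d1 / "db.bin").read_bytes() == (d2 / "db.bin").read_bytes()

    def test_round_trip_multiset(self, tmp_path, rng):
        text = gen_distributed_db(50, mean_len=60, max_len=400, seed=11)
        src = tmp_path / "r.fasta"
        src.write_text(text)
        db = load_db(makedb(src, tmp_path / "db"))
        with open(src) as fh:
            original = {
                h.split()[0]: seq for h, seq in SimpleFastaParser(fh)
            }
        decoded = {
            db.ids[i]: PROTEIN.decode(db.sequence(i).codes)
            for i in range(db.n_sequences)
        }
        assert decoded == original

    def test_equal_length_ties_keep_file_order(self, tmp_path):
        path = tmp_path / "t.fasta"
        path.write_text(">b\nAAAA\n>a\nCCCC\n>c\nGGGG\n")
        db = load_db(makedb(path, tmp_path / "db"))
        assert db.ids == ["b", "a", "c"]

    def test_empty_record_rejected(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">ok\nMKV\n>empty\n\n>also\nMK\n")
        with pytest.raises(ValueError, match="record 2"):
            makedb(path, tmp_path / "db")

    def test_malformed_input_rejected(self, tmp_path):
        path = tmp_path / "junk.fasta"
        path.write_text("this is not fasta\nMKV\n")
        with pytest.raises(ValueError, match="malformed FASTA"):
            makedb(path, tmp_path / "db")

    def test_multi_file_input(self, tmp_path):
        a = tmp_path / "a.fasta"
        b = tmp_path / "b.fasta"
        a.write_text(">x\nMKVL\n")
        b.write_text(">y\nMK\n")
        db = load_db(makedb([a, b], tmp_path / "db"))
        assert db.n_sequences == 2
        assert db.lengths.tolist() == [2, 4]


class TestBatching:
    def _db(self, tmp_path, lengths):
        path = tmp_path / "f.fasta"
        path.write_text(
            "".join(f">q{i}\n{'A' * ln}\n" for i, ln in enumerate(lengths))
        )
        return load_db(makedb(path, tmp_path / "db"))

    def test_single_batch_when_budget_large(self, tmp_path):
        db = self._db(tmp_path, [10, 20, 30])
        plan = iterate_batches(db, DEFAULT_RESIDUE_BUDGET)
        assert list(plan) == [(0, 3)]

    def test_budget_splits_arithmetically(self, tmp_path):
        db = self._db(tmp_path, [100] * 10)
        plan = iterate_batches(db, 300)
        assert [stop - start for start, stop in plan] == [3, 3, 3, 1]

    def test_batches_partition_in_order(self, tmp_path, rng):
        db = self._db(tmp_path, list(rng.integers(1, 50, size=40)))
        plan = iterate_batches(db, 120)
        joined = list(
            itertools.chain.from_iterable(range(a, b) for a, b in plan)
        )
        assert joined == list(range(db.n_sequences))
        for start, stop in plan:
            if stop - start > 1:
                assert db.lengths[start:stop].sum() <= 120

    def test_oversized_sequence_gets_own_batch(self, tmp_path):
        db = self._db(tmp_path, [10, 500, 10])
        plan = iterate_batches(db, 100)
        sizes = [int(db.lengths[a:b].sum()) for a, b in plan]
        assert 500 in sizes


class TestLengthBins:
    def test_printed_boundaries(self):
        assert partition_by_length([64]).tolist() == [0]
        assert partition_by_length([65]).tolist() == [1]
        assert partition_by_length([1280]).tolist() == [19]
        assert partition_by_length([1281]).tolist() == [LONG_BIN]

    def test_every_length_maps_to_one_bin(self):
        lengths = np.arange(1, 5001)
        bins = partition_by_length(lengths)
        for b in range(N_BINS):
            covered = lengths[bins == b]
            assert covered.min() == 64 * b + 1
            assert covered.max() == 64 * (b + 1)
        assert (lengths[bins == LONG_BIN] > MAX_UNTILED_LENGTH).all()

    def test_bin_metadata_consistent(self):
        for b in range(N_BINS):
            spec = bin_of(b)
            assert (spec.lo, spec.hi) == (64 * b + 1, 64 * (b + 1))
        assert bin_of(LONG_BIN).is_long

    def test_config_covers_bin(self):
        """Each bin's kernel can hold that bin's longest sequence untiled."""
        for b in range(N_BINS):
            spec = bin_of(b)
            cfg = select_kernel_config(spec)
            assert not cfg.tiled
            assert spec.hi <= cfg.width
        assert select_kernel_config(bin_of(LONG_BIN)).tiled

    @pytest.mark.parametrize(
        "length,p,k",
        [(128, 4, 32), (256, 8, 32), (512, 16, 32), (1024, 32, 32), (1280, 32, 40)],
    )
    def test_kernel_menu(self, length, p, k):
        b = int(partition_by_length([length])[0])
        cfg = select_kernel_config(bin_of(b))
        assert (cfg.p, cfg.k) == (p, k)
        assert cfg.width >= length


class TestWorkerAssignment:
    def _db(self, tmp_path, lengths):
        path = tmp_path / "w.fasta"
        path.write_text(
            "".join(f">q{i}\n{'A' * ln}\n" for i, ln in enumerate(lengths))
        )
        return load_db(makedb(path, tmp_path / "db"))

    def test_single_worker_identity(self, tmp_path):
        db = self._db(tmp_path, [10, 20, 30])
        wa = assign_to_workers(db, 1)
        assert wa.workers[0].tolist() == [0, 1, 2]

    def test_equal_lengths_split_evenly(self, tmp_path):
        db = self._db(tmp_path, [50, 50, 50, 50])
        wa = assign_to_workers(db, 2)
        assert sorted(len(w) for w in wa.workers) == [2, 2]

    def test_partition_property(self, tmp_path, rng):
        db = self._db(tmp_path, list(rng.integers(1, 2000, size=60)))
        wa = assign_to_workers(db, 4)
        merged = np.sort(np.concatenate(wa.workers))
        assert merged.tolist() == list(range(db.n_sequences))

    def test_per_bin_imbalance_bound(self, tmp_path, rng):
        """Within each bin, worker residue totals differ by at most the
        longest sequence of that bin (greedy balancing guarantee)."""
        db = self._db(tmp_path, list(rng.integers(1, 3000, size=80)))
        n_workers = 3
        wa = assign_to_workers(db, n_workers)
        bins = partition_by_length(db.lengths)
        for b in np.unique(bins):
            totals = []
            for w in wa.workers:
                mask = np.isin(w, np.flatnonzero(bins == b))
                totals.append(int(db.lengths[w[mask]].sum()))
            longest = int(db.lengths[bins == b].max())
            assert max(totals) - min(totals) <= longest

    def test_greedy_close_to_optimal_small(self, tmp_path, rng):
        """On tiny instances the greedy split is within the longest-sequence
        bound of the brute-force optimal two-way split."""
        lengths = [int(x) for x in rng.integers(1, 64, size=10)]
        db = self._db(tmp_path, lengths)
        wa = assign_to_workers(db, 2)
        totals = [int(db.lengths[w].sum()) for w in wa.workers]
        total = sum(lengths)
        best = min(
            abs((total - sum(c)) - sum(c))
            for r in range(len(lengths) + 1)
            for c in itertools.combinations(sorted(db.lengths.tolist()), r)
        )
        assert abs(totals[0] - totals[1]) - best <= max(lengths)
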