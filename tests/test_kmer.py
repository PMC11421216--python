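"""k-mer baseline: table building and the occurrence-weighted prediction."""

import itertools

import numpy as np
import pytest

from ophpred.data import CuratedDataset, ProteinRecord
from ophpred.errors import ValidationError
from ophpred.kmer import (
    build_kmer_table,
    iter_kmers,
    predict_kmer_ph,
    predict_kmer_ph_flagged,
    predict_kmer_range,
    read_kmer_table,
    write_kmer_table,
)


def _dataset(entries):
    records = [ProteinRecord(f"r{i}", seq) for i, (seq, _) in enumerate(entries)]
    return CuratedDataset(
        records, {f"r{i}": ph for i, (_, ph) in enumerate(entries)}
    )


def brute_force_literal(train_entries, query, k, alphabet):
    """Materialized-vocabulary oracle for the sparse dot product (P . T) / N.

    T holds the mean tabulated pH for every k-mer of the full vocabulary
    (0 when absent); P counts occurrences in the query; N = len - k + 1.
    """
    values = {}
    for seq, ph in train_entries:
        for m in iter_kmers(seq, k):
            values.setdefault(m, []).append(ph)
    total = 0.0
    n_positions = len(query) - k + 1
    for vocab_kmer in ("".join(t) for t in itertools.product(alphabet, repeat=k)):
        T_i = float(np.mean(values[vocab_kmer])) if vocab_kmer in values else 0.0
        P_i = sum(
            1
            for i in range(n_positions)
            if query[i : i + k] == vocab_kmer
        )
        total += P_i * T_i
    return total / n_positions


class TestBuildTable:
    def test_single_source_sequence(self):
        table = build_kmer_table(_dataset([("AAA", 6.0)]), k=2)
        assert set(table.entries) == {"AA"}
        s = table.entries["AA"]
        assert (s.mean_ph, s.min_ph, s.max_ph, s.count) == (6.0, 6.0, 6.0, 2)

    def test_aggregation_across_sequences(self):
        table = build_kmer_table(_dataset([("AAC", 4.0), ("CAA", 8.0)]), k=2)
        s = table.entries["AA"]
        assert (s.mean_ph, s.min_ph, s.max_ph) == (6.0, 4.0, 8.0)

    def test_short_sequences_skipped_with_count(self):
        table = build_kmer_table(_dataset([("MK", 7.0)]), k=3)
        assert len(table) == 0
        assert table.n_skipped_short == 1

    def test_set_mode_counts_each_sequence_once(self):
        table = build_kmer_table(_dataset([("AAA", 6.0)]), k=2, multiset=False)
        assert table.entries["AA"].count == 1

    def test_order_invariant(self):
        entries = [("AACW", 4.0), ("CAAM", 8.0), ("WMAC", 5.5)]
        a = build_kmer_table(_dataset(entries), k=2)
        b = build_kmer_table(_dataset(entries[::-1]), k=2)
        assert a.entries == b.entries

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValidationError):
            build_kmer_table(_dataset([]), k=2)


class TestPredict:
    def test_full_coverage(self):
        table = build_kmer_table(_dataset([("AAA", 6.0)]), k=2)
        assert predict_kmer_ph(table, "AAAA") == pytest.approx(6.0)

    def test_literal_mode_counts_absent_kmers_in_denominator(self):
        table = build_kmer_table(_dataset([("AAA", 4.0)]), k=2)
        # query AAGG has occurrences AA, AG, GG; only AA tabulated
        assert predict_kmer_ph(table, "AAGG", "literal") == pytest.approx(4.0 / 3)

    def test_present_only_mode_restricts_denominator(self):
        table = build_kmer_table(_dataset([("AAA", 4.0)]), k=2)
        assert predict_kmer_ph(table, "AAGG", "present_only") == pytest.approx(4.0)

    def test_no_hits_falls_back_to_train_median_flagged(self):
        table = build_kmer_table(_dataset([("AAA", 4.0), ("CCC", 6.0)]), k=2)
        value, fallback = predict_kmer_ph_flagged(table, "WWWW", "present_only")
        assert value == table.train_median == 5.0
        assert fallback

    def test_query_shorter_than_k_rejected(self):
        table = build_kmer_table(_dataset([("AAA", 4.0)]), k=3)
        with pytest.raises(ValidationError):
            predict_kmer_ph(table, "AA")

    def test_unique_kmers_reproduce_training_label(self):
        # r1's k-mers occur in no other training sequence
        table = build_kmer_table(
            _dataset([("WYWYWY", 9.5), ("AAAA", 5.0)]), k=3
        )
        for mode in ("literal", "present_only"):
            assert predict_kmer_ph(table, "WYWYWY", mode) == pytest.approx(9.5)

    def test_present_only_stays_within_training_range(self, rng):
        letters = np.array(list("ACDG"))
        entries = [
            ("".join(rng.choice(letters, 12)), float(rng.uniform(3, 11)))
            for _ in range(10)
        ]
        table = build_kmer_table(_dataset(entries), k=2)
        labels = [ph for _, ph in entries]
        for _ in range(20):
            q = "".join(rng.choice(letters, 15))
            p = predict_kmer_ph(table, q, "present_only")
            assert min(labels) - 1e-9 <= p <= max(labels) + 1e-9


class TestPredictRange:
    def test_single_entry_range(self):
        table = build_kmer_table(
            _dataset([("AAA", 5.0), ("CAA", 7.0), ("AAC", 6.0)]), k=2
        )
        lo, hi = predict_kmer_range(table, "AAA", "present_only")
        assert lo <= predict_kmer_ph(table, "AAA", "present_only") <= hi
        assert lo == pytest.approx(5.0)
        assert hi == pytest.approx(7.0)

    def test_fallback_returns_degenerate_median_range(self):
        table = build_kmer_table(_dataset([("AAA", 4.0)]), k=2)
        assert predict_kmer_range(table, "WWW", "present_only") == (
            table.train_median,
            table.train_median,
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("k", [1, 2])
    def test_literal_matches_materialized_dot_product(self, k, rng):
        alphabet = "ACDE"
        letters = np.array(list(alphabet))
        for _ in range(20):
            entries = [
                (
                    "".join(rng.choice(letters, int(rng.integers(k, 10)))),
                    float(rng.uniform(2, 12)),
                )
                for _ in range(int(rng.integers(1, 6)))
            ]
            query = "".join(rng.choice(letters, int(rng.integers(k, 12))))
            table = build_kmer_table(_dataset(entries), k=k)
            expected = brute_force_literal(entries, query, k, alphabet)
            assert predict_kmer_ph(table, query, "literal") == pytest.approx(
                expected, abs=1e-9
            )


class TestSerialization:
    def test_round_trip(self, tmp_path, toy_dataset):
        table = build_kmer_table(toy_dataset, k=3)
        path = tmp_path / "table.csv"
        write_kmer_table(table, str(path))
        back = read_kmer_table(str(path))
        assert back.k == table.k
        assert back.train_median == table.train_median
        assert back.entries == table.entries
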