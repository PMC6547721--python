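"""Signal normalization, stay-merging and event statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modcaller.events import (
    EventTable,
    RawEvent,
    ReadSignal,
    merge_stay_events,
    normalize_signals,
    read_event_table,
    read_fast5,
    summarize_event,
    write_event_table,
    write_fast5,
)


def _oracle_normalize(values):
    """Independent median/MAD normalization, plain-Python arithmetic."""
    xs = sorted(values)
    n = len(xs)
    med = (xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2)
    devs = sorted(abs(x - med) for x in values)
    mad = (devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2)
    scale = mad * 1.4826
    return [max(-5.0, min(5.0, (x - med) / scale)) for x in values]


class TestNormalizeSignals:
    def test_constant_signal_maps_to_zero(self):
        assert normalize_signals([3.1, 3.1, 3.1]).tolist() == [0.0, 0.0, 0.0]

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 5.0, -3.0, 0.5, 9.0])
        np.testing.assert_allclose(
            normalize_signals(x), normalize_signals(2.0 * x + 7.0), atol=1e-12
        )

    def test_matches_direct_formula_with_clipping(self):
        raw = [1.0, 2.0, 3.0, 4.0, 100.0]
        np.testing.assert_allclose(normalize_signals(raw), _oracle_normalize(raw), rtol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty signal"):
            normalize_signals([])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-1e3, 1e3).map(lambda v: round(v, 3)),
                 min_size=1, max_size=40),
        st.floats(0.1, 10.0),
        st.floats(-50.0, 50.0),
    )
    def test_output_bounded_and_affine_invariant(self, values, a, b):
        x = np.asarray(values)
        out = normalize_signals(x)
        assert np.all(out >= -5.0) and np.all(out <= 5.0)
        np.testing.assert_allclose(out, normalize_signals(a * x + b), atol=1e-6)


def _events(moves, counts, kmer="AACGT"):
    start = 0
    out = []
    for m, c in zip(moves, counts):
        out.append(RawEvent(start, c, m, kmer, 0.0, 0.0))
        start += c
    return out


class TestMergeStayEvents:
    def test_stays_pool_into_preceding_move_event(self):
        evs = _events([1, 0, 0, 1, 0], [3, 2, 2, 4, 1])
        raw = np.zeros(12)
        merged = merge_stay_events(evs, raw)
        assert merged.n_samples.tolist() == [7, 5]
        assert len(merged) == 2

    def test_all_moves_identity(self):
        evs = _events([1, 1, 1], [2, 3, 4])
        raw = np.arange(9, dtype=float)
        merged = merge_stay_events(evs, raw)
        assert len(merged) == 3
        np.testing.assert_allclose(merged.mean, [0.5, 3.0, 6.5])

    def test_pooled_statistics_match_concatenated_samples(self):
        evs = _events([1, 0], [2, 2])
        raw = np.array([1.0, 2.0, 3.0, 4.0])
        merged = merge_stay_events(evs, raw)
        # oracle: pooled mean/population stdv over [1, 2] + [3, 4]
        assert merged.mean[0] == pytest.approx(2.5)
        assert merged.stdv[0] == pytest.approx(np.sqrt(1.25))

    def test_leading_stay_rejected_by_default(self):
        evs = _events([0, 1], [2, 2])
        with pytest.raises(ValueError, match="stay"):
            merge_stay_events(evs, np.zeros(4))

    def test_leading_stay_attach_policy(self):
        evs = _events([0, 1, 0], [2, 2, 1])
        merged = merge_stay_events(evs, np.arange(5, dtype=float), leading_stay="attach")
        assert merged.n_samples.tolist() == [5]

    def test_sample_conservation_and_idempotence(self):
        rng = np.random.default_rng(0)
        moves = rng.integers(0, 2, 30)
        moves[0] = 1
        counts = rng.integers(1, 6, 30)
        evs = _events(moves.tolist(), counts.tolist())
        raw = rng.normal(size=int(counts.sum()))
        merged = merge_stay_events(evs, raw)
        assert merged.n_samples.sum() == counts.sum()
        # already-merged lists (all moves >= 1) pass through unchanged
        evs2 = []
        start = 0
        for me in merged:
            evs2.append(RawEvent(start, me.n_samples, 1, "AAAA" + me.base, 0, 0))
            start += me.n_samples
        again = merge_stay_events(evs2, raw)
        np.testing.assert_allclose(again.mean, merged.mean)
        np.testing.assert_allclose(again.n_samples, merged.n_samples)

    def test_move2_emits_shared_bases(self):
        evs = [RawEvent(0, 4, 1, "AAACG", 0, 0), RawEvent(4, 2, 2, "ACGTT", 0, 0)]
        raw = np.arange(6, dtype=float)
        merged = merge_stay_events(evs, raw)
        assert merged.sequence() == "GTT"
        assert merged.shared.tolist() == [False, True, False]
        # both emitted bases of the move-2 event carry the same pooled stats
        assert merged.mean[1] == merged.mean[2]

    def test_merge_from_stored_statistics_without_raw(self):
        evs = [
            RawEvent(0, 2, 1, "AAAAC", 1.5, 0.5),
            RawEvent(2, 2, 0, "AAAAC", 3.5, 0.5),
        ]
        merged = merge_stay_events(evs, None)
        # oracle: two samples at mean 1.5 and two at 3.5, each with var 0.25
        assert merged.mean[0] == pytest.approx(2.5)
        assert merged.stdv[0] == pytest.approx(np.sqrt(0.25 + 1.0))


class TestSummarizeEvent:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            ([5.0], (5.0, 0.0, 1)),
            ([-1.0, 1.0], (0.0, 1.0, 2)),
            ([0.2, 0.4, 0.9], (0.5, np.sqrt(((0.3) ** 2 + (0.1) ** 2 + (0.4) ** 2) / 3), 3)),
        ],
    )
    def test_mean_population_stdv_count(self, samples, expected):
        mean, stdv, n = summarize_event(samples)
        assert mean == pytest.approx(expected[0])
        assert stdv == pytest.approx(expected[1])
        assert n == expected[2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_event([])


class TestEventTableIO:
    def _reads(self):
        rng = np.random.default_rng(7)
        out = []
        for rid in ("r1", "r2"):
            counts = rng.integers(1, 5, 8)
            moves = rng.integers(0, 2, 8)
            moves[0] = 1
            starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
            raw = rng.normal(size=int(counts.sum()))
            kmers = np.array([b"ACGTA"] * 8, dtype="S5")
            table = EventTable(starts, counts, moves, kmers,
                               rng.normal(size=8), np.abs(rng.normal(size=8)))
            out.append(ReadSignal(rid, raw, table))
        return out

    def test_tsv_round_trip_preserves_fields(self, tmp_path):
        reads = self._reads()
        path = tmp_path / "events.tsv"
        write_event_table(reads, path)
        back = read_event_table(path, format="tsv")
        assert [r.read_id for r in back] == ["r1", "r2"]
        for orig, rb in zip(reads, back):
            np.testing.assert_array_equal(orig.events.move, rb.events.move)
            np.testing.assert_array_equal(orig.events.n_samples, rb.events.n_samples)
            np.testing.assert_array_equal(orig.events.kmers, rb.events.kmers)
            np.testing.assert_array_equal(orig.events.mean, rb.events.mean)  # bit-exact
            np.testing.assert_array_equal(orig.events.stdv, rb.events.stdv)

    def test_fast5_matches_tsv_twin(self, tmp_path):
        reads = self._reads()
        write_event_table(reads, tmp_path / "events.tsv")
        write_fast5(reads, tmp_path / "events.fast5")
        from_tsv = {r.read_id: r for r in read_event_table(tmp_path / "events.tsv")}
        from_f5 = {r.read_id: r for r in read_fast5(tmp_path / "events.fast5")}
        assert from_tsv.keys() == from_f5.keys()
        for rid in from_tsv:
            a, b = from_tsv[rid].events, from_f5[rid].events
            np.testing.assert_array_equal(a.move, b.move)
            np.testing.assert_array_equal(a.mean, b.mean)
            np.testing.assert_array_equal(a.kmers, b.kmers)
        # raw signal survives only in the HDF5 container
        assert from_f5["r1"].raw is not None and from_tsv["r1"].raw is None

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("read_id\tstart_index\tn_samples\tmove\tmean\tstdv\nr1\t0\t1\t1\t0\t0\n")
        with pytest.raises(ValueError, match="kmer"):
            read_event_table(path, format="tsv")

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            read_event_table(p, format="parquet")
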