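import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalturns.corpus import (
    CallRecord,
    SchemaError,
    Session,
    label_events,
    read_call_table,
    rolling_rate,
    segment_conversations,
    shuffle_pairs,
    write_call_table,
)
from vocalturns.synth import gen_poisson_corpus


def test_call_record_invariants():
    with pytest.raises(ValueError):
        CallRecord("s", "m", 5.0, 4.0)  # offset before onset
    with pytest.raises(ValueError):
        CallRecord("s", "m", -1.0, 2.0)
    with pytest.raises(ValueError):
        CallRecord("s", "m", 0.0, 3.0, pulse_onsets=(2.0, 1.0))
    c = CallRecord("s", "m", 1.0, 3.5, pulse_onsets=(1.0, 2.0, 3.0))
    assert c.duration == 2.5


def test_session_sorts_calls_and_checks_roster():
    calls = [CallRecord("s", "M2", 10.0, 12.0), CallRecord("s", "M1", 1.0, 3.0)]
    s = Session("s", 1800, "pair", ["M1", "M2"], calls)
    assert [c.onset for c in s.calls] == [1.0, 10.0]
    with pytest.raises(ValueError):
        Session("s", 1800, "pair", ["M1"], [])
    with pytest.raises(ValueError):
        Session("s", 5.0, "solo", ["M1"], [CallRecord("s", "M1", 1.0, 6.0)])


class TestCallTableIO:
    def test_round_trip_identity(self, tmp_path, truth_corpus):
        p = tmp_path / "calls.csv"
        m = tmp_path / "sessions.csv"
        write_call_table(truth_corpus, p, m)
        back = read_call_table(p, m)
        assert len(back) == len(truth_corpus)
        by_id = {s.session_id: s for s in back}
        for a in truth_corpus:
            b = by_id[a.session_id]
            assert a.roster == b.roster
            assert len(a.calls) == len(b.calls)
            np.testing.assert_allclose(a.onsets(), b.onsets())
        # write(read(write(x))) is byte-identical to write-after-first-read
        p2 = tmp_path / "calls2.csv"
        write_call_table(back, p2)
        back2 = read_call_table(p2, m)
        p3 = tmp_path / "calls3.csv"
        write_call_table(back2, p3)
        assert p2.read_bytes() == p3.read_bytes()

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"session_id": ["s"], "caller_id": ["m"],
                      "onset_s": [1.0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError):
            read_call_table(p)

    def test_invalid_row_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"session_id": ["s", "s"], "caller_id": ["a", "b"],
                      "onset_s": [1.0, 9.0], "offset_s": [3.0, 7.0]}
                     ).to_csv(p, index=False)
        with pytest.raises(ValueError, match="row 1"):
            read_call_table(p)


class TestLabelEvents:
    def test_interruption_containment(self):
        s = Session("s", 100, "pair", ["M1", "M2"],
                    [CallRecord("s", "M1", 0.0, 3.0),
                     CallRecord("s", "M2", 1.0, 2.0)])
        lab = label_events(s)
        assert list(lab["is_interrupting"]) == [False, True]

    def test_simultaneous_onsets_flag_both(self):
        s = Session("s", 100, "pair", ["M1", "M2"],
                    [CallRecord("s", "M1", 0.0, 3.0),
                     CallRecord("s", "M2", 0.0, 2.0)])
        assert label_events(s)["is_interrupting"].all()

    def test_response_delay(self):
        s = Session("s", 100, "pair", ["M1", "M2"],
                    [CallRecord("s", "M1", 0.0, 3.0),
                     CallRecord("s", "M2", 5.0, 8.0)])
        lab = label_events(s)
        assert not lab.loc[0, "is_response"]
        assert lab.loc[1, "is_response"]
        assert lab.loc[1, "responder_delay"] == pytest.approx(2.0)

    def test_interruption_rate_matches_interval_oracle(self):
        corpus = gen_poisson_corpus([80, 80], n_sessions=5, seed=1)
        for s in corpus:
            lab = label_events(s)
            expected = 0
            for i, c in enumerate(s.calls):
                for j, o in enumerate(s.calls):
                    if i == j or o.caller_id == c.caller_id:
                        continue
                    if o.onset <= c.onset < o.offset and \
                            not (o.onset == c.onset and j > i and False):
                        expected += 1
                        break
            assert int(lab["is_interrupting"].sum()) == expected

    def test_invariant_to_row_order(self):
        corpus = gen_poisson_corpus([40, 40], n_sessions=1, seed=5)
        s = corpus[0]
        shuffled = Session(s.session_id, s.duration, s.context,
                           list(s.roster), list(reversed(s.calls)))
        pd.testing.assert_frame_equal(label_events(s), label_events(shuffled))


class TestSegmentation:
    def test_threshold_split(self):
        # gaps between consecutive calls: 3, 4, 20, 3 s with window 10
        onsets = [0.0, 4.0, 9.0, 30.0, 34.0]
        calls = [CallRecord("s", "M1" if i % 2 == 0 else "M2", t, t + 1.0)
                 for i, t in enumerate(onsets)]
        s = Session("s", 100, "pair", ["M1", "M2"], calls)
        segs = segment_conversations(s, response_window=10.0)
        assert [seg.n_calls for seg in segs] == [3, 2]

    def test_empty_session(self):
        s = Session("s", 100, "pair", ["M1", "M2"], [])
        assert segment_conversations(s) == []

    def test_each_call_in_at_most_one_segment(self, truth_corpus):
        for s in truth_corpus:
            segs = segment_conversations(s)
            seen = [i for seg in segs for i in seg.call_indices]
            assert len(seen) == len(set(seen))

    def test_matches_brute_force_gap_scan(self, truth_corpus):
        for s in truth_corpus[:5]:
            segs = segment_conversations(s, 10.0)
            # oracle: scan gaps directly
            runs, run = [], [0] if s.calls else []
            for i in range(1, len(s.calls)):
                if s.calls[i].onset - s.calls[run[-1]].offset <= 10.0:
                    run.append(i)
                else:
                    if len(run) >= 2:
                        runs.append(run)
                    run = [i]
            if len(run) >= 2:
                runs.append(run)
            assert len(segs) == len(runs)
            assert [seg.n_calls for seg in segs] == [len(r) for r in runs]


class TestRollingRate:
    def test_window_count_for_standard_session(self):
        s = Session("s", 1800, "solo", ["M1"], [])
        assert len(rolling_rate(s, "M1")) == 55

    def test_zero_calls_all_zero(self):
        s = Session("s", 1800, "solo", ["M1"], [])
        assert np.all(rolling_rate(s, "M1").values == 0)

    def test_uniform_grid_counts(self):
        calls = [CallRecord("s", "M1", t, t + 1.0)
                 for t in np.arange(0, 1800, 30.0)]
        s = Session("s", 1800, "solo", ["M1"], calls)
        rs = rolling_rate(s, "M1")
        assert np.all(rs.values == 6)

    def test_short_session_errors(self):
        s = Session("s", 100, "solo", ["M1"], [])
        with pytest.raises(ValueError):
            rolling_rate(s, "M1")


class TestShufflePairs:
    def test_requires_two_sessions(self):
        corpus = gen_poisson_corpus([10, 10], n_sessions=1, seed=0)
        with pytest.raises(ValueError):
            shuffle_pairs(corpus, 5, seed=0)

    def test_deterministic_given_seed(self):
        corpus = gen_poisson_corpus([30, 30], n_sessions=4, seed=0)
        a = shuffle_pairs(corpus, 10, seed=7)
        b = shuffle_pairs(corpus, 10, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.onsets(), y.onsets())

    def test_trains_come_from_different_sessions(self):
        corpus = gen_poisson_corpus([30, 30], n_sessions=4, seed=0)
        pools = {}
        for s in corpus:
            for cid in s.roster:
                pools[tuple(np.round(s.onsets(cid), 6))] = s.session_id
        for v in shuffle_pairs(corpus, 20, seed=1):
            src = {pools[tuple(np.round(v.onsets(a), 6))] for a in v.roster}
            assert len(src) == 2

    def test_marginals_preserved(self):
        corpus = gen_poisson_corpus([30, 30], n_sessions=4, seed=0)
        originals = {tuple(np.round(s.onsets(cid), 6))
                     for s in corpus for cid in s.roster}
        for v in shuffle_pairs(corpus, 10, seed=2):
            for alias in v.roster:
                assert tuple(np.round(v.onsets(alias), 6)) in originals

    def test_poisson_overlap_matches_closed_form(self):
        # P(onset inside the other's call) = 1 - exp(-lambda * mean length)
        lam, mean_len = 80, 2.5
        corpus = gen_poisson_corpus([lam, lam], n_sessions=30, seed=3)
        shuffles = shuffle_pairs(corpus, 200, seed=4)
        n_int = n_tot = 0
        for s in shuffles:
            lab = label_events(s)
            n_int += lab["is_interrupting"].sum()
            n_tot += len(lab)
        observed = n_int / n_tot
        expected = 1 - np.exp(-lam / 1800 * mean_len)
        assert observed == pytest.approx(expected, rel=0.15)


@settings(max_examples=20, deadline=None)
@given(st.lists(st.floats(0, 1790), min_size=2, max_size=40),
       st.lists(st.floats(0, 1790), min_size=2, max_size=40))
def test_segmentation_invariant_to_input_order(t1, t2):
    calls = [CallRecord("s", "M1", t, t + 1.0) for t in t1]
    calls += [CallRecord("s", "M2", t, t + 1.0) for t in t2]
    s = Session("s", 1800, "pair", ["M1", "M2"], calls)
    s_rev = Session("s", 1800, "pair", ["M1", "M2"], list(reversed(calls)))
    a = segment_conversations(s)
    b = segment_conversations(s_rev)
    assert [seg.call_indices for seg in a] == [seg.call_indices for seg in b]
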