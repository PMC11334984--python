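import numpy as np
import pytest

from vocalturns.corpus import CallRecord, Session


@pytest.fixture
def toy_pair_session():
    """Six near-point calls whose PRC statistics are known by hand:
    M1 at 0, 20, 40, 100 and M2 at 5, 47."""
    eps = 1e-6
    calls = [CallRecord("toy", "M1", t, t + eps) for t in (0, 20, 40, 100)]
    calls += [CallRecord("toy", "M2", t, t + eps) for t in (5, 47)]
    return Session("toy", 1800, "pair", ["M1", "M2"], calls)


@pytest.fixture(scope="session")
def truth_factors():
    from vocalturns.synth import gen_truth_factors

    return gen_truth_factors()


@pytest.fixture(scope="session")
def truth_corpus(truth_factors):
    from vocalturns.synth import gen_model_corpus

    return gen_model_corpus(truth_factors, rates=(60.0, 60.0),
                            n_sessions=20, seed=2)


def brute_force_pair_stats(session, response_window=10.0):
    """Independent enumeration oracle for R / PR / T0 on a session."""
    calls = sorted(session.calls, key=lambda c: c.onset)
    r_vals, pr_vals, t0_vals = [], [], []
    for c in calls:
        prev_other = [o.offset for o in calls
                      if o.caller_id != c.caller_id and o.offset < c.onset]
        if prev_other:
            gap = c.onset - max(prev_other)
            if 0 < gap <= response_window:
                r_vals.append(gap)
    for cid in {c.caller_id for c in calls}:
        own = [c.onset for c in calls if c.caller_id == cid]
        other = [c.onset for c in calls if c.caller_id != cid]
        for a, b in zip(own[:-1], own[1:]):
            between = [t for t in other if a < t < b]
            if len(between) == 0:
                t0_vals.append(b - a)
            elif len(between) == 1:
                pr_vals.append(b - a)
    return (np.mean(r_vals) if r_vals else np.nan,
            np.mean(pr_vals) if pr_vals else np.nan,
            np.mean(t0_vals) if t0_vals else np.nan)
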