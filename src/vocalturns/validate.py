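"""Model-vs-data comparison suite.

Simulated sessions are interchangeable with recorded ones, so every
statistic here is computed by a single code path applied to both sides:
intercall-interval (ICI) distributions and their peaks, conversation counts
and lengths, factor ablations, k-fold cross-validation, the trio
suppression-level sweep, volubility changes, and the behavioural-state
covariation control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from vocalturns.corpus import (
    DEFAULT_RESPONSE_WINDOW,
    Session,
    rolling_rate,
    segment_conversations,
    shuffle_pairs,
)
from vocalturns.model import FactorSet, SimConfig, simulate_session

#: ICI density binning: 0.5 s bins over 0-30 s.
ICI_EDGES = np.arange(0.0, 30.5, 0.5)


# ---------------------------------------------------------------------------
# Per-session statistics (single code path for data and model)


def session_icis(session: Session) -> np.ndarray:
    """Intercall intervals between consecutive calls (any caller),
    onset to onset."""
    onsets = session.onsets()
    return np.diff(onsets) if onsets.size > 1 else np.array([])


def session_self_icis(session: Session) -> np.ndarray:
    """Same-caller intercall intervals (the 'self ICI'), pooled over the
    roster."""
    out = [np.diff(session.onsets(cid)) for cid in session.roster
           if session.onsets(cid).size > 1]
    return np.concatenate(out) if out else np.array([])


def pooled_self_ici_histogram(corpus: list[Session],
                              edges: np.ndarray = ICI_EDGES) -> np.ndarray:
    icis = np.concatenate([session_self_icis(s) for s in corpus]) \
        if corpus else np.array([])
    hist = np.histogram(icis, bins=edges)[0].astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


def self_ici_distance(corpus_a: list[Session], corpus_b: list[Session],
                      edges: np.ndarray = ICI_EDGES) -> float:
    pa = pooled_self_ici_histogram(corpus_a, edges)
    pb = pooled_self_ici_histogram(corpus_b, edges)
    return float(0.5 * np.abs(pa - pb).sum())


def ici_density(session: Session, edges: np.ndarray = ICI_EDGES,
                ) -> np.ndarray | None:
    icis = session_icis(session)
    if icis.size < 2:
        return None
    width = edges[1] - edges[0]
    hist = np.histogram(icis, bins=edges)[0].astype(float)
    total = hist.sum()
    return hist / (total * width) if total > 0 else None


def peak_ici(session: Session, edges: np.ndarray = ICI_EDGES) -> float:
    dens = ici_density(session, edges)
    if dens is None:
        return np.nan
    centers = edges[:-1] + (edges[1] - edges[0]) / 2
    return float(centers[int(np.argmax(dens))])


def conversation_stats(session: Session,
                       response_window: float = DEFAULT_RESPONSE_WINDOW,
                       ) -> dict:
    segs = segment_conversations(session, response_window)
    lengths = [seg.n_calls for seg in segs]
    dyads = [seg for seg in segs if len(seg.participants) == 2]
    return {"n_conversations": len(segs),
            "mean_length": float(np.mean(lengths)) if lengths else np.nan,
            "dyad_proportion": (len(dyads) / len(segs)) if segs else np.nan}


def pooled_ici_histogram(corpus: list[Session],
                         edges: np.ndarray = ICI_EDGES) -> np.ndarray:
    icis = np.concatenate([session_icis(s) for s in corpus]) \
        if corpus else np.array([])
    hist = np.histogram(icis, bins=edges)[0].astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


def ici_distance(corpus_a: list[Session], corpus_b: list[Session],
                 edges: np.ndarray = ICI_EDGES) -> float:
    """Total-variation distance between pooled ICI histograms — the scalar
    'ICI shift' used to rank ablations."""
    pa = pooled_ici_histogram(corpus_a, edges)
    pb = pooled_ici_histogram(corpus_b, edges)
    return float(0.5 * np.abs(pa - pb).sum())


# ---------------------------------------------------------------------------
# Two-corpus comparison


@dataclass
class ComparisonReport:
    statistic: str
    data_values: np.ndarray
    model_values: np.ndarray
    p_value: float
    paired: bool
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def _compare_values(name: str, data_vals, model_vals, paired: bool,
                    ) -> ComparisonReport:
    """Mixed/paired comparison of a per-session statistic between sources.

    With matched sessions this is a paired test (session as the random
    grouping unit); otherwise a rank-sum test.  Identical inputs return
    p = 1 (the no-difference outcome).
    """
    d = np.asarray(data_vals, float)
    m = np.asarray(model_vals, float)
    d, m = d[~np.isnan(d)], m[~np.isnan(m)]
    if d.size == 0 or m.size == 0:
        return ComparisonReport(name, d, m, np.nan, paired)
    if paired and d.size == m.size:
        diffs = m - d
        if np.allclose(diffs, 0):
            p = 1.0
        else:
            p = float(sps.ttest_rel(d, m).pvalue)
    else:
        if d.size == m.size and np.allclose(np.sort(d), np.sort(m)):
            p = 1.0
        else:
            p = float(sps.ranksums(d, m).pvalue)
    return ComparisonReport(name, d, m, p, paired)


def _is_paired(data: list[Session], model: list[Session]) -> bool:
    return (len(data) == len(model)
            and all(a.session_id == b.session_id
                    for a, b in zip(data, model)))


def compare_ici(data: list[Session], model: list[Session],
                edges: np.ndarray = ICI_EDGES, alpha: float = 0.05,
                ) -> ComparisonReport:
    """Compare ICI distributions between a data and a model corpus.

    Sessions with fewer than 2 ICIs are skipped.  The headline p-value
    compares per-session mean ICIs (paired across matched session ids where
    possible); the report also carries per-session peak-ICI times, their
    comparison, and a per-bin density battery (rank-sum with Holm-Bonferroni
    across bins).
    """
    if not data or not model:
        raise ValueError("both corpora must be non-empty")
    d_keep = [s for s in data if session_icis(s).size >= 2]
    m_keep = [s for s in model if session_icis(s).size >= 2]
    paired = _is_paired(d_keep, m_keep)
    d_mean = [float(np.mean(session_icis(s))) for s in d_keep]
    m_mean = [float(np.mean(session_icis(s))) for s in m_keep]
    rep = _compare_values("ici_mean", d_mean, m_mean, paired)
    d_peak = np.array([peak_ici(s, edges) for s in d_keep])
    m_peak = np.array([peak_ici(s, edges) for s in m_keep])
    peak_rep = _compare_values("ici_peak", d_peak, m_peak, paired)
    d_dens = np.array([v for s in d_keep
                       if (v := ici_density(s, edges)) is not None])
    m_dens = np.array([v for s in m_keep
                       if (v := ici_density(s, edges)) is not None])
    n_bins = len(edges) - 1
    p_bins = np.ones(n_bins)
    if len(d_dens) >= 3 and len(m_dens) >= 3:
        for k in range(n_bins):
            if np.ptp(d_dens[:, k]) > 0 or np.ptp(m_dens[:, k]) > 0 \
                    or d_dens[:, k].mean() != m_dens[:, k].mean():
                p_bins[k] = sps.ranksums(d_dens[:, k], m_dens[:, k]).pvalue
        sig_bins = multipletests(p_bins, alpha=alpha, method="holm")[0]
    else:
        sig_bins = np.zeros(n_bins, bool)
    rep.extras.update(
        peak_p=peak_rep.p_value,
        data_peaks=d_peak, model_peaks=m_peak,
        bin_p_values=p_bins, significant_bins=sig_bins,
        n_skipped=(len(data) - len(d_keep)) + (len(model) - len(m_keep)),
    )
    return rep


def compare_conversations(data: list[Session], model: list[Session],
                          response_window: float = DEFAULT_RESPONSE_WINDOW,
                          ) -> dict[str, ComparisonReport]:
    """Per-session conversation count and mean length, data vs model."""
    paired = _is_paired(data, model)
    out = {}
    for key in ("n_conversations", "mean_length"):
        d = [conversation_stats(s, response_window)[key] for s in data]
        m = [conversation_stats(s, response_window)[key] for s in model]
        out[key] = _compare_values(key, d, m, paired)
    return out


# ---------------------------------------------------------------------------
# Ablations


def simulate_matched_corpus(data: list[Session], factors: FactorSet,
                            seed: int = 0, suppression: float = 0.0,
                            response_window: float = DEFAULT_RESPONSE_WINDOW,
                            use_correction: bool = True) -> list[Session]:
    """One simulated session per data session, driven by the data session's
    measured per-caller output rates (input-equivalent rates when a
    correction model is available)."""
    ss = np.random.SeedSequence(seed)
    out = []
    for s, child in zip(data, ss.spawn(len(data))):
        observed = np.array([s.call_rate(c) for c in s.roster])
        cfg = SimConfig(rates=tuple(observed), duration=s.duration,
                        suppression=suppression, session_id=s.session_id,
                        response_window=response_window,
                        apply_correction=use_correction)
        out.append(simulate_session(cfg, factors,
                                    np.random.default_rng(child)))
    return out


def run_ablation(factors: FactorSet, data: list[Session], seed: int = 0,
                 response_window: float = DEFAULT_RESPONSE_WINDOW,
                 recalibrate: bool = True) -> pd.DataFrame:
    """Exclude each factor in turn and quantify the change in conversation
    dynamics relative to the data.

    Returns one row per condition (``full`` plus the four single-factor
    ablations) with the pooled ICI shift (total-variation distance to the
    data) and the conversation-count/length comparison p-values.  With
    ``recalibrate`` (default) the correction factor is refitted for every
    ablated factor set, so each condition reproduces the data's calling
    rates and the comparison isolates timing structure rather than a bulk
    rate change.  The same seed drives every condition, so ``exclude=None``
    with ``recalibrate=False`` reproduces the full model exactly.
    """
    from vocalturns.model import fit_correction_model

    conditions = [None, *FactorSet.FACTOR_NAMES]
    rows = []
    for cond in conditions:
        f = factors if cond is None else factors.ablate(cond)
        if recalibrate:
            f = replace(f, correction=fit_correction_model(f, seed=seed))
        sim = simulate_matched_corpus(data, f, seed=seed,
                                      response_window=response_window,
                                      use_correction=recalibrate
                                      or f.correction is not None)
        conv = compare_conversations(data, sim, response_window)
        rows.append({
            "excluded": cond or "none",
            "ici_shift": self_ici_distance(data, sim),
            "pooled_ici_shift": ici_distance(data, sim),
            "ici_p": compare_ici(data, sim).p_value,
            "n_conversations_p": conv["n_conversations"].p_value,
            "mean_length_p": conv["mean_length"].p_value,
            "mean_model_conversations": float(np.mean(
                [conversation_stats(s, response_window)["n_conversations"]
                 for s in sim])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cross-validation


def crossvalidate(corpus: list[Session], k: int = 5, seed: int = 0,
                  response_window: float = DEFAULT_RESPONSE_WINDOW,
                  calibrate: bool = False) -> list[dict]:
    """k-fold cross-validation: factors fitted on k-1 folds, held-out
    sessions simulated from their own measured rates, comparisons on the
    held-out fold only."""
    from vocalturns.model import TurnTakingModel

    if k > len(corpus):
        raise ValueError("k exceeds number of sessions")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = np.array_split(order, k)
    reports = []
    for fi, test_idx in enumerate(folds):
        train = [corpus[i] for i in order if i not in set(test_idx)]
        test = [corpus[i] for i in test_idx]
        model = TurnTakingModel(response_window=response_window,
                                calibrate=calibrate, seed=seed).fit(train)
        sim = simulate_matched_corpus(test, model.factors,
                                      seed=seed + fi,
                                      response_window=response_window,
                                      use_correction=calibrate)
        reports.append({
            "fold": fi,
            "test_sessions": [s.session_id for s in test],
            "ici": compare_ici(test, sim),
            "conversations": compare_conversations(test, sim,
                                                   response_window),
        })
    return reports


# ---------------------------------------------------------------------------
# Trio suppression sweep


def suppression_sweep(trio_corpus: list[Session], factors: FactorSet,
                      levels=None, seed: int = 0,
                      response_window: float = DEFAULT_RESPONSE_WINDOW,
                      ) -> pd.DataFrame:
    """Evaluate third-caller suppression levels (default 0-20% in 2.5%
    steps) against trio data.

    The same seed drives every level (common random numbers), so level 0 is
    bit-identical to the base trio model.  Distance to data combines the
    absolute dyad-proportion difference with standardized differences in
    conversation count and mean length (components reported separately).
    """
    if levels is None:
        levels = np.arange(0.0, 0.201, 0.025)
    data_stats = pd.DataFrame(
        [conversation_stats(s, response_window) for s in trio_corpus])
    d_dyad = data_stats["dyad_proportion"].mean()
    d_count = data_stats["n_conversations"]
    d_len = data_stats["mean_length"]
    rows = []
    for lev in np.atleast_1d(levels):
        sim = simulate_matched_corpus(trio_corpus, factors, seed=seed,
                                      suppression=float(lev),
                                      response_window=response_window)
        s_stats = pd.DataFrame(
            [conversation_stats(s, response_window) for s in sim])
        dyad = s_stats["dyad_proportion"].mean()
        count_z = abs(s_stats["n_conversations"].mean() - d_count.mean()) \
            / max(d_count.std(ddof=1), 1e-9)
        len_z = abs(np.nanmean(s_stats["mean_length"]) - d_len.mean()) \
            / max(d_len.std(ddof=1), 1e-9)
        rows.append({
            "suppression": float(lev),
            "dyad_proportion": float(dyad) if np.isfinite(dyad) else np.nan,
            "dyad_abs_diff": float(abs(dyad - d_dyad)),
            "count_z": float(count_z),
            "length_z": float(len_z),
            "distance": float(abs(dyad - d_dyad) + count_z + len_z),
        })
    df = pd.DataFrame(rows)
    df.attrs["best_level"] = float(df.loc[df["distance"].idxmin(),
                                          "suppression"])
    df.attrs["data_dyad_proportion"] = float(d_dyad)
    return df


# ---------------------------------------------------------------------------
# Volubility change


def volubility_change(trio_corpus: list[Session], baseline_rates: dict,
                      correction=None) -> pd.DataFrame:
    """Per-caller volubility change in trio sessions relative to baseline.

    Callers in each session are ranked high/medium/low by their baseline
    (solo/pair) rate; ``change`` is the session rate minus baseline and
    ``corrected_change`` removes partner-rate effects by mapping the session
    rates back to input-equivalent rates through the correction model.
    Callers without a baseline are excluded (count in ``df.attrs``).
    """
    ranks = ["high", "medium", "low"]
    rows, n_excluded = [], 0
    for s in trio_corpus:
        known = [c for c in s.roster if c in baseline_rates]
        n_excluded += len(s.roster) - len(known)
        if len(known) < 2:
            continue
        observed = np.array([s.call_rate(c) for c in known])
        base = np.array([baseline_rates[c] for c in known])
        corrected = (correction.inferred_inputs(observed)
                     if correction is not None else observed)
        order = np.argsort(-base)
        for rank_pos, idx in enumerate(order):
            rows.append({
                "session_id": s.session_id,
                "caller_id": known[idx],
                "rank": ranks[rank_pos] if rank_pos < 3 else str(rank_pos),
                "baseline": float(base[idx]),
                "observed": float(observed[idx]),
                "change": float(observed[idx] - base[idx]),
                "corrected_change": float(corrected[idx] - base[idx]),
            })
    df = pd.DataFrame(rows)
    df.attrs["n_excluded"] = n_excluded
    return df


# ---------------------------------------------------------------------------
# Behavioural-state covariation control


def state_covariation_test(pair_corpus: list[Session], n_shuffles: int = 100,
                           seed: int = 0) -> dict:
    """Do partners' slow calling-rate fluctuations covary beyond chance?

    Correlates the two callers' rolling-rate series per session and compares
    the distribution against correlations from shuffled (cross-session)
    pairings with a rank-sum test.
    """
    def pair_corr(session: Session) -> float:
        a = rolling_rate(session, session.roster[0]).values
        b = rolling_rate(session, session.roster[1]).values
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    observed = np.array([pair_corr(s) for s in pair_corpus])
    observed = observed[~np.isnan(observed)]
    shuffled_sessions = shuffle_pairs(pair_corpus, n_shuffles, seed)
    shuffled = np.array([pair_corr(s) for s in shuffled_sessions])
    shuffled = shuffled[~np.isnan(shuffled)]
    p = float(sps.ranksums(observed, shuffled).pvalue) \
        if observed.size and shuffled.size else np.nan
    return {"observed": observed, "shuffled": shuffled, "p_value": p}
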