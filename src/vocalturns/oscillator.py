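"""Coupled-oscillator test battery.

Under coupled-oscillator turn-taking, the interval between a caller's own
consecutive calls should shorten or lengthen depending on when the partner
responded in between.  The battery tests this three ways:

1. **Interruption rate vs shuffle** — do callers actively avoid overlapping
   calls, compared to virtual pairs assembled from different sessions?
2. **Call-train correlograms** — is there an oscillatory pattern in the
   cross- and autocorrelation of call onsets?
3. **Phase-response-curve (PRC) analysis** — per session, the response
   interval R (call -> response), the phase response PR (own-call pair with a
   single intervening partner call) and the baseline own-call interval T0
   (own-call pair with no intervening call); coupling predicts a positive
   correlation between R and PR - T0 across sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from vocalturns.corpus import (
    DEFAULT_RESPONSE_WINDOW,
    Session,
    label_events,
    shuffle_pairs,
)

# ---------------------------------------------------------------------------
# Interruption rate


def interruption_rate(corpus: list[Session],
                      response_window: float = DEFAULT_RESPONSE_WINDOW,
                      ) -> float:
    """Fraction of calls that start inside another caller's ongoing call."""
    n_calls = n_int = 0
    for s in corpus:
        lab = label_events(s, response_window)
        n_calls += len(lab)
        n_int += int(lab["is_interrupting"].sum())
    if n_calls == 0:
        raise ValueError("corpus has no calls")
    return n_int / n_calls


def interruption_analysis(corpus: list[Session], n_shuffles: int = 200,
                          seed: int = 0,
                          response_window: float = DEFAULT_RESPONSE_WINDOW,
                          ) -> dict:
    """Observed interruption rate vs the shuffled-pair control.

    The one-sided permutation p-value tests observed < control.
    """
    observed = interruption_rate(corpus, response_window)
    shuffles = shuffle_pairs(corpus, n_shuffles, seed)
    control = np.array(
        [interruption_rate([s], response_window) for s in shuffles]
    )
    p = (1 + np.count_nonzero(control <= observed)) / (n_shuffles + 1)
    return {"observed_pct": 100 * observed,
            "control_pct": 100 * control,
            "control_mean_pct": 100 * control.mean(),
            "p_value": p}


# ---------------------------------------------------------------------------
# Correlograms


@dataclass
class CorrelogramResult:
    lags: np.ndarray
    observed_mean: np.ndarray
    shuffle_mean: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray  # Holm-Bonferroni corrected mask
    observed: np.ndarray = field(repr=False, default=None)
    shuffled: np.ndarray = field(repr=False, default=None)


def _onset_diff_histogram(session: Session, mode: str, edges: np.ndarray,
                          ) -> np.ndarray:
    """Rate of (other-/own-) call onsets at lag bins after each call onset,
    normalized per reference call."""
    counts = np.zeros(len(edges) - 1)
    n_ref = 0
    for cid in session.roster:
        own = session.onsets(cid)
        if own.size == 0:
            continue
        if mode == "cross":
            other = np.concatenate(
                [session.onsets(c) for c in session.roster if c != cid]
            ) if len(session.roster) > 1 else np.array([])
        else:
            other = own
        n_ref += own.size
        if other.size == 0:
            continue
        d = (other[None, :] - own[:, None]).ravel()
        d = d[d > 0]
        counts += np.histogram(d, bins=edges)[0]
    return counts / max(n_ref, 1)


def _ici_shuffled(session: Session, rng: np.random.Generator) -> Session:
    """Surrogate with each caller's intercall intervals permuted (preserves
    the ICI distribution, destroys higher-order timing)."""
    calls = []
    for cid in session.roster:
        own = session.calls_by(cid)
        if len(own) < 2:
            calls.extend(own)
            continue
        onsets = np.array([c.onset for c in own])
        icis = rng.permutation(np.diff(onsets))
        new_onsets = onsets[0] + np.concatenate([[0], np.cumsum(icis)])
        for c, t in zip(own, new_onsets):
            dur = min(c.duration, session.duration - t)
            calls.append(type(c)(c.session_id, cid, float(t), float(t + dur)))
    return Session(session.session_id, session.duration, session.context,
                   list(session.roster), calls)


def call_train_correlogram(corpus: list[Session], mode: str = "cross",
                           bin_s: float = 1.0, max_lag: float = 60.0,
                           n_shuffles: int | None = None, seed: int = 0,
                           alpha: float = 0.05) -> CorrelogramResult:
    """Cross- or autocorrelogram of call onsets, tested per lag vs a shuffle
    control (Wilcoxon rank-sum, Holm-Bonferroni across lags).

    Cross mode uses virtual pairs from different sessions as the control;
    auto mode uses ICI-permuted surrogates of the same trains.
    """
    if mode not in ("cross", "auto"):
        raise ValueError("mode must be 'cross' or 'auto'")
    if bin_s <= 0 or max_lag % bin_s > 1e-9:
        raise ValueError("bin must be > 0 and divide max_lag")
    if any(max_lag >= s.duration for s in corpus):
        raise ValueError("max_lag must be smaller than session duration")
    if n_shuffles is None:
        n_shuffles = len(corpus)
    edges = np.arange(0, max_lag + bin_s / 2, bin_s)
    obs = np.array([_onset_diff_histogram(s, mode, edges) for s in corpus])
    rng = np.random.default_rng(seed)
    if mode == "cross":
        ctrl_sessions = shuffle_pairs(corpus, n_shuffles, rng)
    else:
        ctrl_sessions = [_ici_shuffled(corpus[i % len(corpus)], rng)
                         for i in range(n_shuffles)]
    ctrl = np.array([_onset_diff_histogram(s, mode, edges)
                     for s in ctrl_sessions])
    p = np.ones(len(edges) - 1)
    for k in range(len(p)):
        if np.ptp(obs[:, k]) > 0 or np.ptp(ctrl[:, k]) > 0 \
                or obs[:, k].mean() != ctrl[:, k].mean():
            p[k] = stats.ranksums(obs[:, k], ctrl[:, k]).pvalue
    sig = multipletests(p, alpha=alpha, method="holm")[0]
    lags = edges[:-1] + bin_s / 2
    return CorrelogramResult(lags, obs.mean(axis=0), ctrl.mean(axis=0),
                             p, sig, obs, ctrl)


# ---------------------------------------------------------------------------
# Phase-response-curve analysis


@dataclass
class PRCResult:
    per_session: pd.DataFrame      # session_id, R, PR, T0, bias_flag
    mean_t0: float
    r: float
    p: float
    r_below: float
    p_below: float
    r_above: float
    p_above: float
    n_excluded: int

    @property
    def significantly_positive(self, alpha: float = 0.05) -> bool:
        return bool(self.r > 0 and self.p < alpha)


def session_prc_stats(session: Session,
                      response_window: float = DEFAULT_RESPONSE_WINDOW,
                      ) -> dict:
    """Per-session R, PR, T0 (NaN where undefined).

    Intervals are onset-to-onset between a caller's consecutive calls; a pair
    with exactly one intervening partner-call onset is a PR pair, with none a
    T0 pair, and pairs spanning two or more partner calls enter neither.  R
    and PR are means; T0 is the median baseline call interval.  R averages
    the responder delays (offset -> onset gaps within the response window).
    """
    lab = label_events(session, response_window)
    r_vals = lab.loc[lab["is_response"], "responder_delay"].to_numpy()
    pr_vals, t0_vals = [], []
    for cid in session.roster:
        own = session.onsets(cid)
        others = np.concatenate(
            [session.onsets(c) for c in session.roster if c != cid]
        ) if len(session.roster) > 1 else np.array([])
        for a, b in zip(own[:-1], own[1:]):
            k = np.count_nonzero((others > a) & (others < b))
            if k == 0:
                t0_vals.append(b - a)
            elif k == 1:
                pr_vals.append(b - a)
    return {
        "session_id": session.session_id,
        "R": float(np.mean(r_vals)) if r_vals.size else np.nan,
        "PR": float(np.mean(pr_vals)) if pr_vals else np.nan,
        "T0": float(np.median(t0_vals)) if t0_vals else np.nan,
    }


def _pearson(x, y):
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def prc_analysis(corpus: list[Session],
                 response_window: float = DEFAULT_RESPONSE_WINDOW,
                 ) -> PRCResult:
    """Pooled PRC correlation: Pearson r between per-session R and PR - T0.

    Sessions lacking any of R, PR, T0 are excluded (count reported).
    Bias-correction points (PR < R) are retained and flagged.  The
    correlation is also split at the grand-mean T0: points with R below vs
    above it.
    """
    rows = [session_prc_stats(s, response_window) for s in corpus]
    df = pd.DataFrame(rows)
    valid = df.dropna()
    n_excluded = len(df) - len(valid)
    if len(valid) == 0:
        raise ValueError("no session has all of R, PR, T0 defined")
    valid = valid.assign(
        pr_minus_t0=valid["PR"] - valid["T0"],
        bias_flag=valid["PR"] < valid["R"],
    )
    mean_t0 = float(valid["T0"].mean())
    r, p = _pearson(valid["R"].to_numpy(), valid["pr_minus_t0"].to_numpy())
    below = valid[valid["R"] < mean_t0]
    above = valid[valid["R"] >= mean_t0]
    rb, pb = _pearson(below["R"].to_numpy(), below["pr_minus_t0"].to_numpy())
    ra, pa = _pearson(above["R"].to_numpy(), above["pr_minus_t0"].to_numpy())
    return PRCResult(valid.reset_index(drop=True), mean_t0, r, p,
                     rb, pb, ra, pa, n_excluded)


def prc_subset_resampling(corpus: list[Session], subset_sizes,
                          n_draws: int = 200, seed: int = 0,
                          response_window: float = DEFAULT_RESPONSE_WINDOW,
                          outlier_p: float = 1e-4) -> pd.DataFrame:
    """PRC correlation over random session subsets of the given sizes.

    For each size, draws ``n_draws`` subsets without replacement, computes
    the pooled PRC r and p, and reports the fraction of 'outlier' draws
    (p < ``outlier_p`` and r > 0) — the rate at which a small sample would
    spuriously support oscillator coupling.
    """
    rng = np.random.default_rng(seed)
    stats_rows = [session_prc_stats(s, response_window) for s in corpus]
    valid = pd.DataFrame(stats_rows).dropna().reset_index(drop=True)
    records = []
    for size in np.atleast_1d(subset_sizes):
        size = int(size)
        if size > len(valid):
            raise ValueError(f"subset size {size} exceeds usable corpus "
                             f"({len(valid)} sessions)")
        for d in range(n_draws):
            idx = rng.choice(len(valid), size=size, replace=False)
            sub = valid.iloc[idx]
            r, p = _pearson(sub["R"].to_numpy(),
                            (sub["PR"] - sub["T0"]).to_numpy())
            records.append({"subset_size": size, "draw": d, "r": r, "p": p})
    df = pd.DataFrame(records)
    df["outlier"] = (df["p"] < outlier_p) & (df["r"] > 0)
    return df
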