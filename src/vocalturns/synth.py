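"""Synthetic corpora with known ground truth.

Every downstream stage is testable without real recordings by generating
corpora whose structure is known by construction:

- homogeneous **Poisson** call trains — the null for all timing analyses;
- **coupled-oscillator** pair corpora with a built-in positive
  phase-response relation — the positive control for the oscillator battery;
- synthetic **phee audio** with an exact f0 trajectory — the round-trip
  oracle for acoustic feature extraction;
- **planted-effect feature tables** — ground truth for the mixed-effects
  and classifier pipeline.

All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.io import wavfile

from vocalturns.corpus import CallRecord, Session

#: Plausible phee-call length distribution for null corpora (s): Gaussian
#: truncated from below.  The fitted model estimates its own from data.
CALL_LENGTH_MEAN = 2.5
CALL_LENGTH_SD = 0.5
CALL_LENGTH_MIN = 0.5


def _draw_call_lengths(rng, n, mean=CALL_LENGTH_MEAN, sd=CALL_LENGTH_SD,
                       lo=CALL_LENGTH_MIN):
    x = rng.normal(mean, sd, size=n)
    while np.any(x <= lo):
        bad = x <= lo
        x[bad] = rng.normal(mean, sd, size=bad.sum())
    return x


# ---------------------------------------------------------------------------
# Null (Poisson) corpora


def gen_poisson_corpus(rates_per_session, duration: float = 1800.0,
                       n_sessions: int = 20, seed: int = 0,
                       call_length_mean: float = CALL_LENGTH_MEAN,
                       call_length_sd: float = CALL_LENGTH_SD,
                       rate_profile=None) -> list[Session]:
    """Independent Poisson call trains, one per caller.

    ``rates_per_session`` gives expected calls/session per caller (1-3
    callers).  Call lengths are Gaussian (mean 2.5 s, sd 0.5 s) truncated at
    0.5 s.  ``rate_profile`` (optional callable of time, mean ~1 over the
    session) modulates the intensity, making the process inhomogeneous via
    thinning.
    """
    rates = np.atleast_1d(np.asarray(rates_per_session, float))
    if np.any(rates < 0):
        raise ValueError("rates must be >= 0")
    if not 1 <= len(rates) <= 3:
        raise ValueError("1-3 callers supported")
    context = {1: "solo", 2: "pair", 3: "trio"}[len(rates)]
    roster = [f"M{i + 1}" for i in range(len(rates))]
    rng = np.random.default_rng(seed)
    corpus = []
    for k in range(n_sessions):
        sid = f"poisson_{k}"
        calls = []
        for cid, rate in zip(roster, rates):
            if rate_profile is None:
                n = rng.poisson(rate)
                onsets = np.sort(rng.uniform(0, duration, size=n))
            else:
                grid = np.linspace(0, duration, 2048)
                prof = np.asarray(rate_profile(grid), float)
                peak = prof.max()
                n_cand = rng.poisson(rate * peak)
                cand = np.sort(rng.uniform(0, duration, size=n_cand))
                keep = rng.uniform(size=n_cand) < np.interp(
                    cand, grid, prof) / peak
                onsets = cand[keep]
            n = len(onsets)
            lengths = _draw_call_lengths(rng, n, call_length_mean,
                                         call_length_sd)
            for t, ln in zip(onsets, lengths):
                off = min(t + ln, duration)
                if off > t:
                    calls.append(CallRecord(sid, cid, float(t), float(off)))
        corpus.append(Session(sid, duration, context, roster, calls))
    return corpus


# ---------------------------------------------------------------------------
# Coupled-oscillator positive control


@dataclass(frozen=True)
class OscillatorSpec:
    """Ground truth for the coupled-oscillator positive control.

    The initiator calls with a fixed intrinsic ``period``; whenever the
    partner responds (delay ``R``), the initiator's next onset is advanced by
    ``coupling_gain * R``, which builds in an exact linear phase-response
    relation PR - T0 = coupling_gain * R.
    """

    period: float = 20.0
    coupling_gain: float = 0.5
    jitter_sd: float = 0.0
    response_prob: float = 0.7
    delay_range: tuple[float, float] = (1.0, 8.0)
    call_length: float = 0.2

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def gen_oscillator_corpus(spec: OscillatorSpec, duration: float = 1800.0,
                          n_sessions: int = 20, seed: int = 0,
                          ) -> list[Session]:
    """Two alternating callers with oscillator coupling built in.

    Caller A cycles with ``spec.period``; caller B responds with probability
    ``response_prob`` after a session-specific delay drawn from
    ``delay_range`` (plus jitter).  A responded-to cycle lengthens A's next
    interval by ``coupling_gain * delay``, so the per-session phase response
    PR - T0 regressed on the response interval R has slope ``coupling_gain``
    exactly when jitter is zero.
    """
    rng = np.random.default_rng(seed)
    corpus = []
    for k in range(n_sessions):
        sid = f"osc_{k}"
        delay = rng.uniform(*spec.delay_range)
        calls = []
        t = rng.uniform(0, spec.period / 2)
        while t < duration - spec.call_length:
            calls.append(CallRecord(sid, "A", t, t + spec.call_length))
            responded = rng.uniform() < spec.response_prob
            if responded:
                rt = t + delay + rng.normal(0, spec.jitter_sd)
                rt = np.clip(rt, t + spec.call_length, t + spec.period - 2 * spec.call_length)
                if rt < duration - spec.call_length:
                    calls.append(CallRecord(sid, "B", float(rt),
                                            float(rt + spec.call_length)))
                t = t + spec.period + spec.coupling_gain * (rt - t)
            else:
                t = t + spec.period
            t += rng.normal(0, spec.jitter_sd)
        corpus.append(Session(sid, duration, "pair", ["A", "B"], calls))
    return corpus


# ---------------------------------------------------------------------------
# Synthetic phee audio


@dataclass(frozen=True)
class PheeSpec:
    """Shape of a synthetic multi-pulse phee call.

    Per pulse the instantaneous frequency rises ``f_start -> f_max`` and then
    descends to ``f_end`` at ``ending_slope`` (Hz/s, magnitude); pulses are
    separated by silent gaps.
    """

    n_pulses: int = 2
    pulse_length: float = 1.0
    gap: float = 0.1
    f_start: float = 6000.0
    f_max: float = 8000.0
    f_end: float = 7000.0
    ending_slope: float = 4000.0
    amplitude: float = 0.8
    sample_rate: float = 48000.0

    def __post_init__(self):
        if self.f_max < self.f_start or self.f_max < self.f_end:
            raise ValueError("f_max must be >= f_start and f_end")
        if min(self.pulse_length, self.gap, self.ending_slope) <= 0:
            raise ValueError("durations and slope must be > 0")
        if (self.f_max - self.f_end) / self.ending_slope >= self.pulse_length:
            raise ValueError("descent longer than the pulse; increase "
                             "ending_slope or pulse_length")

    @property
    def total_length(self) -> float:
        return self.n_pulses * self.pulse_length + (self.n_pulses - 1) * self.gap


def gen_phee_audio(spec: PheeSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Synthesize a phee waveform and return ``(waveform, t, f0)``.

    ``f0`` is the exact instantaneous-frequency trajectory used (NaN in the
    inter-pulse gaps), so extraction can be checked as a round trip.
    """
    if spec.sample_rate < 4 * spec.f_max:
        raise ValueError("sample_rate must be >= 4 * f_max")
    sr = spec.sample_rate
    t = np.arange(int(round(spec.total_length * sr))) / sr
    f0 = np.full_like(t, np.nan)
    descent = (spec.f_max - spec.f_end) / spec.ending_slope
    rise = spec.pulse_length - descent
    for p in range(spec.n_pulses):
        t0 = p * (spec.pulse_length + spec.gap)
        local = t - t0
        up = (local >= 0) & (local < rise)
        f0[up] = spec.f_start + (spec.f_max - spec.f_start) * local[up] / rise
        down = (local >= rise) & (local < spec.pulse_length)
        f0[down] = spec.f_max - spec.ending_slope * (local[down] - rise)
    phase = 2 * np.pi * np.cumsum(np.where(np.isnan(f0), 0.0, f0)) / sr
    wave = np.where(np.isnan(f0), 0.0, spec.amplitude * np.sin(phase))
    return wave.astype(np.float64), t, f0


def write_wav(path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    pcm = np.clip(waveform, -1, 1)
    wavfile.write(path, int(sample_rate), (pcm * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, float]:
    sr, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    return data, float(sr)


# ---------------------------------------------------------------------------
# Planted-truth factor sets and model-generated corpora


def gen_truth_factors(state_coefs=(0.05, 0.05, 0.1, 0.2, 0.4),
                      state_intercept: float = 1.2,
                      state_resid_sd: float = 0.8,
                      arousal=(0.8, -0.002, 0.6, -0.0002),
                      interruption_decay: float = 1.5,
                      refractory_s: float = 2.0,
                      response_peak_s: float = 3.0):
    """A four-factor set with known parameters, for recovery tests.

    The self response curve has a planted refractory period (bins below the
    base rate up to ``refractory_s``) followed by a rebound peak at
    ``response_peak_s``; the partner curve a facilitation peak at the same
    position.  Defaults are on the scale of marmoset phee behaviour
    (state mean ~6 calls per 180 s window, arousal decaying over the session,
    interruption likelihood halving every ~0.5 s).
    """
    from vocalturns.model import (
        ArousalCurve,
        FactorSet,
        InterruptionCurve,
        ResponseCurve,
        StateModel,
    )

    coefs = np.asarray(state_coefs, float)
    mean = state_intercept / max(1 - coefs.sum(), 1e-6)
    state = StateModel(coefficients=coefs, intercept=state_intercept,
                       residual_sd=state_resid_sd, rate_mean=mean,
                       rate_sd=state_resid_sd * 2)
    t = np.arange(30) + 0.5  # bin centers, s after offset
    self_vals = np.ones(30)
    self_vals[t < refractory_s] = 0.1
    self_vals += 1.2 * np.exp(-0.5 * (t - response_peak_s) ** 2)
    self_vals[-10:] = 1.0
    partner_vals = 1.0 + 1.0 * np.exp(-0.5 * (t - response_peak_s) ** 2)
    partner_vals[-10:] = 1.0
    return FactorSet(
        state=state,
        arousal=ArousalCurve(*arousal),
        interruption=InterruptionCurve(decay_rate=interruption_decay),
        response_self=ResponseCurve(self_vals, role="self"),
        response_partner=ResponseCurve(partner_vals, role="partner"),
        call_length_mean=CALL_LENGTH_MEAN,
        call_length_sd=CALL_LENGTH_SD,
    )


def gen_state_corpus(coefs=(0.05, 0.05, 0.1, 0.2, 0.4),
                     intercept: float = 6.0, innovation_sd: float = 0.8,
                     n_sessions: int = 40, duration: float = 1800.0,
                     seed: int = 0, window: float = 180.0,
                     step: float = 30.0) -> list[Session]:
    """Corpus whose rolling-rate series follows a prescribed AR(5) process.

    Per caller, a target AR(5) window-rate series is generated (50-step
    burn-in) and converted to per-30 s call counts whose rolling sums track
    the series up to integer rounding; calls are placed uniformly within
    their 30 s slot.  Used as ground truth for state-model recovery.
    """
    rng = np.random.default_rng(seed)
    c = np.asarray(coefs, float)
    n_sub = int(round(duration / step))
    n_windows = int(np.floor((duration - window) / step)) + 1
    span = int(round(window / step))
    mean = intercept / max(1 - c.sum(), 1e-9)
    corpus = []
    for k in range(n_sessions):
        sid = f"state_{k}"
        calls = []
        for cid in ("M1", "M2"):
            v = np.full(5, mean)
            for _ in range(50):  # burn-in to stationarity
                v = np.append(v[1:], intercept + v @ c
                              + rng.normal(0, innovation_sd))
            targets = np.empty(n_windows)
            hist5 = v.copy()
            for i in range(n_windows):
                nxt = intercept + hist5 @ c + rng.normal(0, innovation_sd)
                targets[i] = max(nxt, 0.0)
                hist5 = np.append(hist5[1:], targets[i])
            counts = np.zeros(n_sub, int)
            counts[:span] = np.maximum(np.round(targets[0] / span), 0)
            for i in range(1, n_windows):
                j = i + span - 1
                want = targets[i] - counts[i:j].sum()
                counts[j] = max(int(round(want)), 0)
            for j, n in enumerate(counts):
                for t in np.sort(rng.uniform(j * step, (j + 1) * step, n)):
                    calls.append(CallRecord(sid, cid, float(t),
                                            float(min(t + 0.1, duration))))
        corpus.append(Session(sid, duration, "pair", ["M1", "M2"], calls))
    return corpus


def gen_model_corpus(factors, rates=(80.0, 80.0), n_sessions: int = 20,
                     seed: int = 0, duration: float = 1800.0,
                     suppression: float = 0.0) -> list[Session]:
    """Corpus drawn from the turn-taking simulator with the given factors —
    the synthetic ground truth for fitting and validation tests."""
    from vocalturns.model import SimConfig, simulate_session

    ss = np.random.SeedSequence(seed)
    out = []
    for k, child in enumerate(ss.spawn(n_sessions)):
        cfg = SimConfig(rates=tuple(rates), duration=duration,
                        suppression=suppression, session_id=f"truth_{k}")
        out.append(simulate_session(cfg, factors,
                                    np.random.default_rng(child)))
    return out


# ---------------------------------------------------------------------------
# Planted-effect feature tables

FEATURE_NAMES = [
    "monkey_calling_rate",
    "call_number_in_conversation",
    "max_frequency",
    "loudness",
    "n_pulses",
    "ending_slope",
    "start_frequency",
    "last_pulse_length",
    "partner_call_length",
    "partner_calling_rate",
    "end_frequency",
    "partner_ici",
]


def gen_feature_table(n_calls: int = 2000, planted_betas=None,
                      intercept: float = 0.0, random_effect_sd: float = 0.3,
                      calls_per_session: int = 40, n_monkeys: int = 20,
                      seed: int = 0) -> pd.DataFrame:
    """Feature table with binary responses from a known logistic model.

    The 12 per-call predictors are standard normal (plus a binary odd/even
    flag); the response is Bernoulli with logit ``intercept + X @ beta +
    u_caller + u_partner`` where the random intercepts are Gaussian with sd
    ``random_effect_sd``.  Ground truth is stored in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    betas = np.zeros(len(FEATURE_NAMES))
    if planted_betas:
        for name, b in planted_betas.items():
            betas[FEATURE_NAMES.index(name)] = b
    monkeys = [f"M{i}" for i in range(n_monkeys)]
    u = {m: rng.normal(0, random_effect_sd) for m in monkeys}
    rows = []
    n_sessions = int(np.ceil(n_calls / calls_per_session))
    for s in range(n_sessions):
        caller, partner = rng.choice(n_monkeys, size=2, replace=False)
        k = min(calls_per_session, n_calls - s * calls_per_session)
        X = rng.normal(size=(k, len(FEATURE_NAMES)))
        odd_even = rng.integers(0, 2, size=k)
        logit = intercept + X @ betas + u[monkeys[caller]] + u[monkeys[partner]]
        y = rng.uniform(size=k) < 1 / (1 + np.exp(-logit))
        for i in range(k):
            row = dict(zip(FEATURE_NAMES, X[i]))
            row.update(session_id=f"s{s}", caller_id=monkeys[caller],
                       partner_id=monkeys[partner], odd_even=int(odd_even[i]),
                       response=int(y[i]),
                       delay=float(np.abs(rng.normal(3.0, 1.0))))
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["betas"] = dict(zip(FEATURE_NAMES, betas))
    df.attrs["intercept"] = intercept
    df.attrs["random_effect_sd"] = random_effect_sd
    return df
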