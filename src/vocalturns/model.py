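"""Four-factor stochastic model of vocal turn-taking.

Calling is modelled as a Bernoulli process on 0.2 s bins whose per-bin
probability is the product of

1. a per-caller **input rate** (volubility, calls/session), pre-corrected by
   a calibration model so the simulated output matches the input;
2. a slow **behavioural state** trace generated by a fitted AR(5) model of
   the rolling calling rate;
3. an **arousal** (volubility-decay) curve — a two-term exponential decline
   of calling rate across the session;
4. event-driven modulators: an **interruption curve** (exponential decay of
   the partner's calling probability while a call is ongoing) and **response
   curves** (self refractory-then-rebound and partner facilitation, for 30 s
   after each call offset).

In trio sessions, a caller outside an ongoing conversation between the other
two is additionally suppressed by a configurable factor.  Response *delays*
are separately modelled as the first passage of drifting noisy activity to a
threshold (ramp-to-threshold).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import statsmodels.api as sm
from scipy.interpolate import PchipInterpolator
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from vocalturns.corpus import (
    DEFAULT_RESPONSE_WINDOW,
    CallRecord,
    Session,
    rolling_rate,
)

# ---------------------------------------------------------------------------
# Factor types


@dataclass
class StateModel:
    """AR(5) model of the rolling calling rate (behavioural state).

    Fitted on 180 s / 30 s rolling-rate series: five consecutive windows
    predict the next.  Generation seeds five values from a Gaussian fitted
    to the observed window rates, recurses with Gaussian innovation noise,
    discards 70 burn-in values and cuts the rest into a bank of 200 traces
    of 70 values, each normalized to mean 1.
    """

    coefficients: np.ndarray      # lag 1..5 (most recent last)
    intercept: float
    residual_sd: float
    rate_mean: float
    rate_sd: float
    conf_int: np.ndarray | None = None
    n_traces: int = 200
    trace_length: int = 70
    burn_in: int = 70

    def generate_bank(self, rng: np.random.Generator) -> np.ndarray:
        """Bank of normalized state traces, shape (n_traces, trace_length)."""
        total = self.burn_in + self.n_traces * self.trace_length
        vals = np.empty(total + 5)
        vals[:5] = self.rng_seed_values(rng)
        c = np.asarray(self.coefficients)
        for i in range(5, total + 5):
            v = self.intercept + vals[i - 5:i] @ c
            v += rng.normal(0, self.residual_sd)
            vals[i] = max(v, 0.0)
        traces = vals[5 + self.burn_in:].reshape(self.n_traces,
                                                 self.trace_length)
        means = traces.mean(axis=1)
        means = np.maximum(means, 1e-6)
        traces = traces / means[:, None]
        return np.maximum(traces, 1e-3)  # positivity guard

    def rng_seed_values(self, rng):
        return np.maximum(rng.normal(self.rate_mean, max(self.rate_sd, 1e-9),
                                     size=5), 0.0)


def interpolate_state_trace(trace: np.ndarray, duration: float = 1800.0,
                            step: float = 30.0, window: float = 180.0,
                            ) -> np.ndarray:
    """Shape-preserving (pchip) interpolation of a windowed trace to a 1 s
    grid over ``[0, duration)``; interpolated values beyond the session span
    are dropped."""
    centers = np.arange(len(trace)) * step + window / 2
    interp = PchipInterpolator(centers, trace, extrapolate=True)
    t = np.arange(0, duration)
    return np.maximum(interp(t), 1e-3)


@dataclass
class ArousalCurve:
    """Two-term exponential volubility decay a*exp(b t) + c*exp(d t),
    renormalized to mean 1 over the session."""

    a: float
    b: float
    c: float
    d: float
    duration: float = 1800.0
    param_sd: tuple | None = None  # 1-sigma errors from the fit, (a, b, c, d)

    def __call__(self, t) -> np.ndarray:
        raw = self.a * np.exp(self.b * np.asarray(t, float)) \
            + self.c * np.exp(self.d * np.asarray(t, float))
        grid = np.arange(0, self.duration)
        mean = np.mean(self.a * np.exp(self.b * grid)
                       + self.c * np.exp(self.d * grid))
        return np.maximum(raw / mean, 1e-6)


@dataclass
class InterruptionCurve:
    """Exponential decay, origin fixed at 1, of a caller's probability of
    starting a call t seconds into another caller's ongoing call; estimated
    in 0.2 s windows over 5 s."""

    decay_rate: float
    bin_s: float = 0.2
    support_s: float = 5.0
    empirical: np.ndarray | None = None
    degenerate: bool = False

    def values(self) -> np.ndarray:
        t = np.arange(int(round(self.support_s / self.bin_s))) * self.bin_s
        if not np.isfinite(self.decay_rate):
            out = np.zeros_like(t)
            out[0] = 1.0
            return out
        return np.exp(-self.decay_rate * t)


@dataclass
class ResponseCurve:
    """Calling-probability modulation vs time since a call's offset.

    30 one-second bins, locally smoothed (quadratic least squares) and
    normalized so the mean of the last 10 bins (the base rate) is 1.  The
    *self* curve encodes the post-call refractory period and rebound; the
    *partner* curve encodes response facilitation.
    """

    values: np.ndarray
    role: str = "self"
    bin_s: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise ValueError("response curve values must be >= 0")

    def base_rate(self) -> float:
        return float(self.values[-10:].mean())

    def per_sim_bin(self, sim_bin: float = 0.2) -> np.ndarray:
        return np.repeat(self.values, int(round(self.bin_s / sim_bin)))


@dataclass
class CorrectionModel:
    """Linear model of the *relative* simulation discrepancy.

    ``(input - output) / input ~ a + b * own_rate + c * partner_rate``,
    fitted on simulator runs over a 0-300 calls/session grid and applied
    multiplicatively: corrected input = target / (1 - predicted relative
    discrepancy), solved jointly for all callers.
    """

    coef_const: float
    coef_own: float
    coef_partner: float

    def relative_discrepancy(self, own, partner) -> np.ndarray:
        return (self.coef_const + self.coef_own * np.asarray(own, float)
                + self.coef_partner * np.asarray(partner, float))

    def corrected_inputs(self, targets) -> np.ndarray:
        """Input rates whose simulated output is expected to equal
        ``targets`` (fixed-point solve of the multiplicative correction)."""
        targets = np.asarray(targets, float)
        r = targets.copy()
        for _ in range(100):
            partner = _partner_means(r)
            denom = 1 - self.relative_discrepancy(r, partner)
            denom = np.clip(denom, 0.2, 2.0)
            r_new = targets / denom
            if np.allclose(r_new, r, rtol=1e-10, atol=1e-12):
                r = r_new
                break
            r = r_new
        return np.maximum(r, 0.0)

    def inferred_inputs(self, observed_outputs) -> np.ndarray:
        """Input-equivalent rates for observed output rates (the
        model-corrected calling rate); the inverse map of the discrepancy."""
        return self.corrected_inputs(observed_outputs)


def _partner_means(rates: np.ndarray) -> np.ndarray:
    if len(rates) == 1:
        return np.zeros(1)
    total = rates.sum()
    return (total - rates) / (len(rates) - 1)


@dataclass
class RampModel:
    """Ramp-to-threshold response-delay mechanism: activity drifts up with
    additive Gaussian noise; the response is emitted at first threshold
    crossing."""

    base: float = 0.0
    drift: float = 1.0
    noise_sd: float = 0.3
    threshold: float = 3.0
    dt: float = 0.01

    def __post_init__(self):
        if self.threshold <= self.base:
            raise ValueError("threshold must exceed base")
        if self.drift <= 0:
            raise ValueError("drift must be > 0")


def simulate_response_delay_ramp(model: RampModel, n_epochs: int = 1000,
                                 seed: int | np.random.Generator = 0,
                                 max_t: float = 60.0) -> np.ndarray:
    """First-passage delays of the ramping process, one per epoch.

    Crossing times are linearly interpolated within a step, so the
    zero-noise delay is exactly ``(threshold - base) / drift``.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(np.ceil(max_t / model.dt))
    delays = np.full(n_epochs, np.nan)
    a = np.full(n_epochs, model.base, float)
    alive = np.ones(n_epochs, bool)
    sqdt = np.sqrt(model.dt)
    for k in range(1, n_steps + 1):
        prev = a[alive]
        step = model.drift * model.dt
        if model.noise_sd > 0:
            step = step + model.noise_sd * sqdt * rng.standard_normal(
                prev.shape)
        nxt = prev + step
        crossed = nxt >= model.threshold
        idx = np.flatnonzero(alive)
        hit = idx[crossed]
        frac = (model.threshold - prev[crossed]) / (nxt[crossed]
                                                    - prev[crossed])
        delays[hit] = (k - 1 + frac) * model.dt
        a[idx] = nxt
        alive[hit] = False
        if not alive.any():
            break
    return delays


@dataclass
class FactorSet:
    """The fitted model components; ``None`` means the identity factor."""

    state: StateModel | None = None
    arousal: ArousalCurve | None = None
    interruption: InterruptionCurve | None = None
    response_self: ResponseCurve | None = None
    response_partner: ResponseCurve | None = None
    correction: CorrectionModel | None = None
    call_length_mean: float = 2.5
    call_length_sd: float = 0.5

    FACTOR_NAMES = ("state", "arousal", "interruption", "response")

    @classmethod
    def identity(cls, call_length_mean: float = 2.5,
                 call_length_sd: float = 0.5) -> "FactorSet":
        return cls(call_length_mean=call_length_mean,
                   call_length_sd=call_length_sd)

    def ablate(self, factor: str) -> "FactorSet":
        """Copy with one factor replaced by the identity."""
        if factor not in self.FACTOR_NAMES:
            raise ValueError(f"unknown factor {factor!r}; "
                             f"expected one of {self.FACTOR_NAMES}")
        if factor == "response":
            return replace(self, response_self=None, response_partner=None)
        return replace(self, **{factor: None})

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def enc(obj):
            if obj is None:
                return None
            d = asdict(obj)
            return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in d.items()}

        return json.dumps({
            "state": enc(self.state),
            "arousal": enc(self.arousal),
            "interruption": enc(self.interruption),
            "response_self": enc(self.response_self),
            "response_partner": enc(self.response_partner),
            "correction": enc(self.correction),
            "call_length_mean": self.call_length_mean,
            "call_length_sd": self.call_length_sd,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FactorSet":
        raw = json.loads(text)

        def dec(key, klass, array_fields=()):
            d = raw.get(key)
            if d is None:
                return None
            for f in array_fields:
                if d.get(f) is not None:
                    d[f] = np.asarray(d[f], float)
            return klass(**d)

        return cls(
            state=dec("state", StateModel, ("coefficients", "conf_int")),
            arousal=dec("arousal", ArousalCurve),
            interruption=dec("interruption", InterruptionCurve,
                             ("empirical",)),
            response_self=dec("response_self", ResponseCurve, ("values",)),
            response_partner=dec("response_partner", ResponseCurve,
                                 ("values",)),
            correction=dec("correction", CorrectionModel),
            call_length_mean=raw["call_length_mean"],
            call_length_sd=raw["call_length_sd"],
        )


# ---------------------------------------------------------------------------
# Factor fitting


def fit_state_model(corpus: list[Session], window: float = 180.0,
                    step: float = 30.0) -> StateModel:
    """Fit the AR(5) behavioural-state model on rolling-rate series pooled
    across all sessions and callers (OLS; five lags -> next window)."""
    X, y, all_rates = [], [], []
    for s in corpus:
        for cid in s.roster:
            series = rolling_rate(s, cid, window, step).values
            all_rates.append(series)
            if len(series) < 6:
                continue
            for i in range(5, len(series)):
                X.append(series[i - 5:i])
                y.append(series[i])
    if not X:
        raise ValueError("no session provides >= 6 rate windows")
    X = np.asarray(X)
    y = np.asarray(y)
    ols = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    resid_sd = float(np.std(ols.resid, ddof=6)) if len(y) > 6 else 0.0
    pooled = np.concatenate(all_rates)
    return StateModel(
        coefficients=np.asarray(ols.params[1:]),
        intercept=float(ols.params[0]),
        residual_sd=resid_sd,
        rate_mean=float(pooled.mean()),
        rate_sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        conf_int=np.asarray(ols.conf_int())[1:],
    )


def _two_exp(t, a, b, c, d):
    return a * np.exp(b * t) + c * np.exp(d * t)


def fit_arousal(corpus: list[Session], window: float = 180.0,
                step: float = 30.0) -> ArousalCurve:
    """Fit the volubility-decay curve: average rolling rate across all
    sessions and callers, normalized to mean 1, least-squares two-term
    exponential."""
    if not corpus:
        raise ValueError("empty corpus")
    series = [rolling_rate(s, cid, window, step).values
              for s in corpus for cid in s.roster]
    mean_rate = np.mean(series, axis=0)
    if mean_rate.mean() <= 0:
        return ArousalCurve(0.5, 0.0, 0.5, 0.0, corpus[0].duration)
    norm = mean_rate / mean_rate.mean()
    centers = np.arange(len(norm)) * step + window / 2
    bounds = ([0, -1, 0, -1], [10, 0, 10, 0])
    best, best_sse, best_sd = (float(norm.mean()), 0.0, 0.0, 0.0), np.inf, None
    # two-term exponentials are poorly identified; multi-start over
    # decade-separated decay-scale pairs and keep the best fit
    for b0 in (-1e-2, -3e-3, -1e-3):
        for d0 in (-3e-4, -1e-4, -1e-5):
            try:
                params, pcov = curve_fit(_two_exp, centers, norm,
                                         p0=(0.5, b0, 0.5, d0),
                                         bounds=bounds, maxfev=20000)
            except RuntimeError:
                continue
            sse = float(np.sum((_two_exp(centers, *params) - norm) ** 2))
            if sse < best_sse:
                best = tuple(float(v) for v in params)
                best_sse = sse
                best_sd = tuple(float(v) for v in np.sqrt(np.diag(pcov)))
    return ArousalCurve(*best, duration=corpus[0].duration,
                        param_sd=best_sd)


def fit_interruption_curve(corpus: list[Session], bin_s: float = 0.2,
                           support_s: float = 5.0) -> InterruptionCurve:
    """Fit the interruption-avoidance decay.

    Counts partner-call onsets in 0.2 s windows after each focal call onset
    (while the focal call is ongoing), min-max normalizes the mean profile to
    [0, 1] and fits an exponential decay with origin 1.
    """
    n_bins = int(round(support_s / bin_s))
    edges = np.arange(0, support_s + bin_s / 2, bin_s)
    counts = np.zeros(n_bins)
    exposure = np.zeros(n_bins)  # at-risk (focal ongoing, partner free) bins
    n_calls = 0
    for s in corpus:
        for cid in s.roster:
            own = s.calls_by(cid)
            own_onsets = s.onsets(cid)
            other_calls = [c for c in s.calls if c.caller_id != cid]
            others = np.array([c.onset for c in other_calls])
            n_calls += len(own)
            for c in own:
                # skip focal calls whose own preceding call is still
                # suppressing the partner (stacked curves would bias the
                # hazard estimate toward fast decay)
                prev = own_onsets[(own_onsets < c.onset)
                                  & (own_onsets > c.onset - support_s)]
                if prev.size:
                    continue
                mids = c.onset + edges[:-1] + bin_s / 2
                ongoing = mids < c.offset
                # partner can only start a call when not already mid-call
                partner_free = np.ones(n_bins, bool)
                for o in other_calls:
                    partner_free &= ~((mids > o.onset) & (mids < o.offset))
                at_risk = ongoing & partner_free
                exposure += at_risk
                if others.size == 0:
                    continue
                rel = others[(others >= c.onset) & (others < c.offset)
                             & (others < c.onset + support_s)] - c.onset
                # onsets can sit exactly on bin edges (grid-aligned data);
                # floor with a tiny nudge instead of histogram edges
                idx = np.floor(rel / bin_s + 1e-9).astype(int)
                for j in idx[(idx >= 0) & (idx < n_bins)]:
                    counts[j] += 1
    if n_calls == 0:
        raise ValueError("corpus has no calls")
    # hazard estimate: events per at-risk focal bin; raw per-call means are
    # censored by call length and partner busy time toward fast decay
    mean_counts = np.divide(counts, np.maximum(exposure, 1),
                            out=np.zeros(n_bins), where=exposure > 0)
    if mean_counts.max() <= 0:
        # total interruption avoidance: no overlaps at all
        return InterruptionCurve(decay_rate=np.inf, bin_s=bin_s,
                                 support_s=support_s,
                                 empirical=mean_counts, degenerate=True)
    lo, hi = mean_counts.min(), mean_counts.max()
    norm = (mean_counts - lo) / (hi - lo)
    t = np.arange(n_bins) * bin_s
    # Poisson weights: hazard SE ~ sqrt(counts)/exposure, on the same scale.
    # The amplitude is fitted as a nuisance parameter because the lag-0 bin
    # carries a covocalization excess (both callers starting in the same bin
    # before either can hear the other) that would otherwise corrupt the
    # normalization scale; the reported curve keeps its origin at 1.
    sigma = np.sqrt(counts + 1) / np.maximum(exposure, 1) / (hi - lo)
    try:
        (_, k), _ = curve_fit(
            lambda tt, aa, kk: aa * np.exp(-kk * tt), t, norm,
            p0=(1.0, 1.0), sigma=sigma, bounds=([0.1, 0], [10, 100]),
            maxfev=10000)
        k = float(k)
    except RuntimeError:
        k = 1.0
    return InterruptionCurve(decay_rate=float(k), bin_s=bin_s,
                             support_s=support_s, empirical=mean_counts)


def _smooth(values: np.ndarray, span: int = 5) -> np.ndarray:
    if len(values) < span:
        return values
    return savgol_filter(values, span, polyorder=2)


def fit_response_curves(corpus: list[Session], n_bins: int = 30,
                        smooth_span: int = 5,
                        ) -> tuple[ResponseCurve, ResponseCurve]:
    """Fit the self and partner response curves.

    Per caller and session: mean number of own (self) / partner calls in
    each 1 s bin of the 30 s after each own-call offset, smoothed by local
    quadratic least squares, normalized to the base rate (mean of the last
    10 bins), then averaged.
    """
    edges = np.arange(0, n_bins + 1, 1.0)
    self_curves, partner_curves = [], []
    for s in corpus:
        for cid in s.roster:
            own = s.calls_by(cid)
            if not own:
                continue
            own_onsets = s.onsets(cid)
            partner_onsets = np.concatenate(
                [s.onsets(c) for c in s.roster if c != cid]
            ) if len(s.roster) > 1 else np.array([])
            for onsets, sink in ((own_onsets, self_curves),
                                 (partner_onsets, partner_curves)):
                hist = np.zeros(n_bins)
                for c in own:
                    rel = onsets - c.offset
                    hist += np.histogram(rel[(rel > 0) & (rel < n_bins)],
                                         bins=edges)[0]
                hist = _smooth(hist / len(own), smooth_span)
                base = hist[-10:].mean()
                if base > 0:
                    sink.append(np.maximum(hist, 0) / base)
    if not self_curves or not partner_curves:
        raise ValueError("not enough calls to fit response curves")
    return (ResponseCurve(np.mean(self_curves, axis=0), role="self"),
            ResponseCurve(np.mean(partner_curves, axis=0), role="partner"))


def fit_call_length(corpus: list[Session]) -> tuple[float, float]:
    durs = np.array([c.duration for s in corpus for c in s.calls])
    if durs.size == 0:
        raise ValueError("corpus has no calls")
    return float(durs.mean()), float(durs.std(ddof=1) if durs.size > 1
                                     else 0.0)


# ---------------------------------------------------------------------------
# Simulation


@dataclass
class SimConfig:
    """Configuration for one simulated session."""

    rates: tuple[float, ...] = (60.0, 60.0)   # input calls/session
    duration: float = 1800.0
    bin_s: float = 0.2
    suppression: float = 0.0                  # trio third-caller suppression
    response_window: float = DEFAULT_RESPONSE_WINDOW
    session_id: str = "sim"
    apply_correction: bool = True

    def __post_init__(self):
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be >= 0")
        if not 1 <= len(self.rates) <= 3:
            raise ValueError("1-3 callers supported")
        if not 0 <= self.suppression < 1:
            raise ValueError("suppression must be in [0, 1)")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_s))

    @property
    def context(self) -> str:
        return {1: "solo", 2: "pair", 3: "trio"}[len(self.rates)]


def simulate_session(config: SimConfig, factors: FactorSet | None = None,
                     seed: int | np.random.Generator = 0,
                     state_bank: np.ndarray | None = None) -> Session:
    """Simulate one session of 1-3 callers from a fitted factor set.

    Per caller the per-bin base probability is ``rate / (n_bins - rate *
    mean_call_length_bins)`` (so the identity-factor expectation equals the
    input rate despite the caller being unable to start a call during its
    own ongoing call), multiplied by the correction factor, the arousal curve
    and a randomly drawn behavioural-state trace.  Bins are then visited in
    time order; a call is emitted when a uniform variate falls below the
    (clipped) probability, its length drawn from the fitted Gaussian, and
    the interruption / response curves multiply the affected later bins.
    """
    factors = factors or FactorSet.identity()
    rng = np.random.default_rng(seed)
    n_call = len(config.rates)
    n_bins = config.n_bins
    bin_s = config.bin_s
    rates = np.asarray(config.rates, float)

    corrected = rates
    if config.apply_correction and factors.correction is not None:
        corrected = factors.correction.corrected_inputs(rates)

    len_bins = max(factors.call_length_mean / bin_s, 1.0)
    base = np.empty((n_call, n_bins))
    for i in range(n_call):
        denom = max(n_bins - corrected[i] * len_bins, n_bins * 0.05)
        base[i] = corrected[i] / denom
    if factors.arousal is not None:
        t_bins = (np.arange(n_bins) + 0.5) * bin_s
        base *= factors.arousal(t_bins)[None, :]
    if factors.state is not None:
        if state_bank is None:
            state_bank = factors.state.generate_bank(rng)
        per_bin = int(round(1.0 / bin_s))
        for i in range(n_call):
            trace = state_bank[rng.integers(len(state_bank))]
            per_s = interpolate_state_trace(trace, config.duration)
            base[i] *= np.repeat(per_s, per_bin)[:n_bins]

    # event-driven modulators, precomputed on the simulation grid
    int_curve = None
    if factors.interruption is not None:
        int_curve = factors.interruption.values()
    resp_self = (factors.response_self.per_sim_bin(bin_s)
                 if factors.response_self is not None else None)
    resp_partner = (factors.response_partner.per_sim_bin(bin_s)
                    if factors.response_partner is not None else None)

    modifier = np.ones((n_call, n_bins))
    busy_until = np.full(n_call, -1.0)
    u = rng.uniform(size=(n_call, n_bins))
    lengths_cache = np.maximum(
        rng.normal(factors.call_length_mean, factors.call_length_sd,
                   size=4096), bin_s)
    n_emitted = 0
    calls: list[tuple[int, float, float]] = []
    n_clipped = 0

    # ongoing-conversation tracking for trio suppression
    seg_participants: set[int] = set()
    seg_last_offset = -np.inf
    seg_n = 0

    def apply_curve(row: np.ndarray, start_bin: int, curve: np.ndarray):
        end = min(start_bin + len(curve), n_bins)
        if end > start_bin >= 0:
            row[start_bin:end] *= curve[: end - start_bin]

    for t in range(n_bins):
        now = t * bin_s
        for i in range(n_call):
            if now < busy_until[i]:
                continue
            p = base[i, t] * modifier[i, t]
            if (config.suppression > 0 and seg_n >= 2
                    and i not in seg_participants
                    and now <= seg_last_offset + config.response_window):
                p *= 1 - config.suppression
            if p > 1:
                n_clipped += 1
                p = 1.0
            if u[i, t] >= p:
                continue
            # emit a call
            length = float(lengths_cache[n_emitted % len(lengths_cache)])
            n_emitted += 1
            onset = now
            offset = min(onset + length, config.duration)
            if offset <= onset:
                continue
            calls.append((i, onset, offset))
            busy_until[i] = offset
            if int_curve is not None:
                # suppression acts only while the call is ongoing; calls
                # longer than the 5 s support hold the final curve value
                dur_bins = int(np.ceil((offset - onset) / bin_s))
                if dur_bins <= len(int_curve):
                    curve = int_curve[:dur_bins]
                else:
                    curve = np.concatenate(
                        [int_curve,
                         np.full(dur_bins - len(int_curve), int_curve[-1])])
                for j in range(n_call):
                    if j != i:
                        apply_curve(modifier[j], t, curve)
            off_bin = int(round(offset / bin_s))
            if resp_self is not None:
                apply_curve(modifier[i], off_bin, resp_self)
            if resp_partner is not None:
                for j in range(n_call):
                    if j != i:
                        apply_curve(modifier[j], off_bin, resp_partner)
            # conversation bookkeeping
            if seg_n == 0 or onset - seg_last_offset > config.response_window:
                seg_participants = {i}
                seg_n = 1
            else:
                seg_participants.add(i)
                seg_n += 1
            seg_last_offset = max(seg_last_offset, offset)

    roster = [f"S{i + 1}" for i in range(n_call)]
    records = [CallRecord(config.session_id, roster[i], on, off)
               for i, on, off in calls]
    session = Session(config.session_id, config.duration, config.context,
                      roster, records)
    session.n_clipped_bins = n_clipped
    return session


def generate_state_trace(state_model: StateModel,
                         seed: int | np.random.Generator = 0,
                         duration: float = 1800.0) -> np.ndarray:
    """One per-second behavioural-state trace for a session: a random trace
    from the model's generated bank, pchip-interpolated to a 1 s grid."""
    rng = np.random.default_rng(seed)
    bank = state_model.generate_bank(rng)
    return interpolate_state_trace(bank[rng.integers(len(bank))], duration)


def model_corrected_rate(correction: CorrectionModel,
                         observed_output_rates) -> np.ndarray:
    """Input-equivalent calling rates for observed session output rates
    (inverts the fitted discrepancy model; own and partner corrections are
    solved jointly)."""
    if correction is None:
        raise ValueError("a fitted CorrectionModel is required")
    return correction.inferred_inputs(np.asarray(observed_output_rates,
                                                 float))


# ---------------------------------------------------------------------------
# Correction-model calibration


def fit_correction_model(factors: FactorSet,
                         rate_grid=None, n_reps: int = 2,
                         duration: float = 1800.0, seed: int = 0,
                         ) -> CorrectionModel:
    """Calibrate the multiplicative correction factor.

    Runs pair simulations (without correction) over the input-rate grid
    0-300 calls/session in steps of 10, pairing each own rate with a rotated
    partner rate so both axes vary, and fits the relative discrepancy
    ``(input - output) / input`` linearly on (own rate, partner rate).
    """
    if rate_grid is None:
        rate_grid = np.arange(0.0, 301.0, 10.0)
    rate_grid = np.asarray(rate_grid, float)
    rng = np.random.default_rng(seed)
    own_in, partner_in, rel = [], [], []
    # both-callers-swept (diagonal) pairs anchor the operating regime;
    # rotated pairings separate the own- and partner-rate coefficients
    partners = np.roll(rate_grid, len(rate_grid) // 3)
    for rep in range(n_reps):
        for r1, r2 in list(zip(rate_grid, rate_grid)) \
                + list(zip(rate_grid, partners)):
            cfg = SimConfig(rates=(r1, r2), duration=duration,
                            apply_correction=False, session_id="calib")
            sess = simulate_session(cfg, factors, rng)
            out = [sess.call_rate(c) for c in sess.roster]
            for (rin, pin, o) in ((r1, r2, out[0]), (r2, r1, out[1])):
                if rin > 0:
                    own_in.append(rin)
                    partner_in.append(pin)
                    rel.append((rin - o) / rin)
    X = sm.add_constant(np.column_stack([own_in, partner_in]))
    # relative discrepancies have Poisson-driven variance ~ 1/input rate, so
    # low-rate observations are heavily down-weighted
    fit = sm.WLS(np.asarray(rel), X, weights=np.asarray(own_in)).fit()
    return CorrectionModel(float(fit.params[0]), float(fit.params[1]),
                           float(fit.params[2]))


# ---------------------------------------------------------------------------
# High-level wrapper


class TurnTakingModel:
    """Fit the four factors on a pair corpus and simulate new sessions."""

    def __init__(self, response_window: float = DEFAULT_RESPONSE_WINDOW,
                 calibrate: bool = True, calibration_reps: int = 2,
                 seed: int = 0):
        self.response_window = response_window
        self.calibrate = calibrate
        self.calibration_reps = calibration_reps
        self.seed = seed
        self.factors: FactorSet | None = None

    def fit(self, corpus: list[Session]) -> "TurnTakingModel":
        if not corpus:
            raise ValueError("empty corpus")
        mean_len, sd_len = fit_call_length(corpus)
        self.factors = FactorSet(
            state=fit_state_model(corpus),
            arousal=fit_arousal(corpus),
            interruption=fit_interruption_curve(corpus),
            response_self=None,
            response_partner=None,
            call_length_mean=mean_len,
            call_length_sd=sd_len,
        )
        rs, rp = fit_response_curves(corpus)
        self.factors.response_self = rs
        self.factors.response_partner = rp
        if self.calibrate:
            self.factors.correction = fit_correction_model(
                self.factors, n_reps=self.calibration_reps, seed=self.seed)
        return self

    def simulate(self, rates, seed=0, suppression: float = 0.0,
                 session_id: str = "sim", duration: float = 1800.0,
                 ) -> Session:
        if self.factors is None:
            raise ValueError("model is not fitted")
        cfg = SimConfig(rates=tuple(rates), duration=duration,
                        suppression=suppression, session_id=session_id,
                        response_window=self.response_window)
        return simulate_session(cfg, self.factors, seed)

    def simulate_corpus(self, rate_list, seed=0, suppression: float = 0.0,
                        duration: float = 1800.0) -> list[Session]:
        rng = np.random.default_rng(seed)
        return [
            self.simulate(rates, rng, suppression,
                          session_id=f"model_{k}", duration=duration)
            for k, rates in enumerate(rate_list)
        ]
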