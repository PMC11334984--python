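# Methods

`vocalturns` models vocal turn-taking in common marmosets (*Callithrix
jacchus*): pairs or trios of visually separated animals exchanging phee
calls in 1800 s recording sessions.  The package has three layers: a
point-process data model for call corpora, an analysis battery that tests
the coupled-oscillator account of turn-taking and quantifies what actually
predicts responses, and a four-factor stochastic simulator that generates
conversations from a caller's volubility plus internal and social
modulators.  Because the real recordings are not bundled, a synthetic-data
layer generates corpora with known ground truth for every fitted component.

## Data model

A call is a half-open interval `[onset, offset)` in float seconds from
session start.  Sessions carry a roster (1–3 callers) and a sorted call
list.  Derived labels:

- **response** — a call whose onset follows another caller's most recent
  offset by a gap in `(0, w]`, with `w` the response window.  The window
  defaults to 10 s: the empirical response-probability curves return to
  baseline roughly 4–5 s after a call's offset, so 10 s is a conservative
  bound on an exchange gap.  It is a parameter everywhere because no single
  operational definition of "conversation" is standard.
- **interruption** — a call starting strictly inside another caller's
  ongoing call; the later-starting call carries the flag, simultaneous
  onsets flag both.
- **conversation segment** — a maximal run of calls (self-runs included)
  in which each call starts within `w` of the previous call's offset;
  singletons are not segments.
- **rolling rate** — calls per 180 s window, stepped by 30 s (55 windows
  per 1800 s session); the substrate of the behavioural-state and arousal
  fits.

## Coupled-oscillator battery

Under coupled-oscillator dynamics, the delay of a partner's response should
shift the timing of the caller's next call.  The battery tests this three
ways: interruption rate against a cross-session shuffle control (virtual
pairs preserve each train's marginal statistics exactly), onset cross- and
autocorrelograms against shuffled / ICI-permuted surrogates (rank-sum per
lag, Holm–Bonferroni across lags, default 1 s bins to 60 s), and the
phase-response-curve (PRC) analysis.

Per session the PRC statistics are: R, the mean responder delay; PR, the
mean own-call interval containing **exactly one** intervening partner call;
and T0, the **median** own-call interval containing none.  Pairs spanning
two or more partner calls enter neither statistic — this is the enumeration
under which the six-call hand example (R = 6, PR = 40, T0 = 20) reproduces,
and it matches the idea of a phase response to a single perturbation.  The
pooled correlation is Pearson's r over per-session `(R, PR − T0)` points,
also reported split at the grand-mean T0, with bias points (PR < R)
retained and flagged.

Two small-sample properties of this analysis are worth knowing.  First,
PR − T0 is positive even for independent callers: PR pairs are
length-biased (longer own-call gaps catch more partner calls), so the
pooled cloud sits above zero — visible in real data as PR − T0 never
crossing zero.  Second, both R and PR − T0 covary with the realized session
rate, giving the pooled r a small positive expectation (ρ ≈ 0.1 on
ten-session null corpora).  At α = 0.05 this makes "significantly positive"
fire on roughly 5% of null corpora.  The operational rule for a sample that
*spuriously supports* coupling is therefore the stricter p < 10⁻⁴ with
r > 0, the same rule the subset-resampling analysis uses to count outlier
subsamples; the coupled-oscillator positive control passes at p far below
either threshold.

## Response-probability models

Each call yields 12 predictors (calling rates as cumulative means scaled to
calls/session, position in conversation, partner ICI and call length, and —
when audio is available — start/max/end frequency, ending slope, pulse
count, last-pulse length, session-normalized loudness) plus an odd/even
position flag.  Acoustic features come from an STFT f0 track (10 ms frames,
2.5 ms hop, argmax-power bin, 40 dB energy floor) and an RMS-envelope pulse
segmenter.  The response model is a mixed-effects logistic regression with
caller and partner random intercepts, fitted by variational Bayes;
predictors are z-scored so odds ratios are per SD, per-predictor
significance is Holm-corrected across the 12 fixed effects, and the
marginal R² uses the latent-scale variance partition
`var(Xβ) / (var(Xβ) + σ²_caller + σ²_partner + π²/3)`.  Response delay uses
the same structure with an identity link.  Classifiers (logistic
regression; random forest with permutation importance on held-out folds)
are trained on per-session counterbalanced rows and tested against chance
with a one-sample t-test over fold accuracies.

## The four-factor conversation model

Calling is a Bernoulli process on 0.2 s bins (9000 per session).  A
caller's base probability per bin is

    p = rate / (n_bins − rate · mean_call_length_bins) × correction ×
        arousal(t) × state(t)

The denominator compensates for the caller's own busy time: a caller
cannot start a call during its own ongoing call, and with this base
probability the identity-factor expectation of the output count equals the
input rate exactly (renewal argument), which anchors the calibration.

- **Behavioural state** — an AR(5) model of the rolling rate (five windows
  predict the next, OLS pooled over sessions and callers; innovation sd
  from the residuals).  Generation seeds five values from a Gaussian fit to
  the observed window rates, recurses, discards 70 burn-in values, cuts the
  rest into a bank of 200 traces of 70 values normalized to mean 1 (values
  floored just above zero), and pchip-interpolates a randomly drawn trace
  to a 1 s grid, dropping values beyond the session span.  Traces are drawn
  independently per caller — the state-covariation control in the
  validation suite is the check that partners' slow rate fluctuations do
  not in fact covary beyond shuffle.
- **Arousal (volubility decay)** — a two-term exponential
  `a·e^{bt} + c·e^{dt}` fitted to the grand-mean rolling rate, renormalized
  to mean 1 over the session.  The fit multi-starts over decade-separated
  decay scales.  The parameterization is only identified as a curve —
  amplitude/rate pairs trade off along a flat ridge, so recovery is judged
  pointwise on the curve, not coefficient-by-coefficient.
- **Interruption curve** — `exp(−kt)` (origin fixed at 1) for the
  probability multiplier applied to *other* callers while a call is
  ongoing, estimated from partner-onset hazards in 0.2 s bins over 5 s.
  The estimator is exposure-corrected (a bin counts only while the focal
  call is ongoing and the partner is free), uses only focal calls without a
  preceding own call within 5 s (stacked curves would bias the decay
  upward), and fits with Poisson weights and a free amplitude — the lag-0
  bin carries a covocalization excess (both callers starting before either
  can hear the other) that would otherwise corrupt the scale.  In
  simulation the curve applies from a call's onset until its offset only
  (holding its last value for calls longer than 5 s): applying it past the
  offset would suppress exactly the window where responses are generated.
- **Response curves** — mean calls per 1 s bin over the 30 s after each
  own-call offset, for the caller (refractory then rebound) and the partner
  (facilitation peak), smoothed by local quadratic least squares
  (Savitzky–Golay, 5-bin span) and normalized to the base rate defined as
  the mean of the last 10 bins.
- **Correction factor** — event-driven modulators change the realized rate,
  so the *relative* discrepancy `(input − output)/input` is fitted linearly
  on (own rate, partner rate) from uncorrected runs over the 0–300
  calls/session grid in steps of 10 — both-callers-swept pairs anchor the
  operating regime and rotated pairings separate the two coefficients —
  by weighted least squares (variance of a relative discrepancy scales as
  1/rate).  The relative (multiplicative) form matters: the absolute
  discrepancy is strongly nonlinear in rate.  Applying the correction
  solves the fixed point `input = target / (1 − D̂(input, partner))`; the
  same inversion maps observed outputs to input-equivalent rates (the
  model-corrected calling rate used for trio volubility analysis, with the
  partner term taken as the mean of the other callers' rates).

Per bin, in time order, each caller draws a uniform variate and calls when
it falls below the (clipped to [0, 1]) probability; call lengths are
Gaussian, fitted from data and floored at one bin.  Event modulators
multiply the affected later bins and stack multiplicatively where supports
overlap.  In trios, a caller outside an ongoing conversation between the
other two (an active segment, not yet closed by the response window, that
does not include the caller) has its probability multiplied by
`1 − suppression`, with suppression swept over 0–20% in 2.5% steps.

**Response delays** are modelled mechanistically as ramp-to-threshold first
passage: activity starts at a base level, drifts upward with additive
Gaussian noise, and the response fires at the first threshold crossing
(crossing time interpolated within a step, so the zero-noise delay is
exactly `(threshold − base)/drift`).  Higher base activity — a more voluble
animal — yields shorter delays.  The parameterization is one realization of
the concept and is tested for direction, not for specific values.

## Validation suite

Data and simulated sessions are interchangeable objects, and every
statistic is computed by one code path applied to both sides.  ICI
densities use 0.5 s bins over 0–30 s.  Corpus comparisons report a paired
test on per-session mean ICIs when sessions are matched by id (falling
back to rank-sum otherwise), per-session peak-ICI times, and a per-bin
density battery with Holm correction.  Conversation count and mean length
are compared per session the same way.

Ablations replace one factor with the identity and **recalibrate the
correction model for the ablated factor set**, so every condition
reproduces the data's calling rates and comparisons isolate timing
structure rather than a bulk rate change.  The scalar "ICI shift" used to
rank ablations is the total-variation distance between pooled *same-caller*
(self) ICI histograms: the response factor's refractory/rebound signature
lives in self intervals, whereas a pooled any-caller metric is dominated by
the covocalization mass that appears when interruption avoidance is
removed.  The pooled-ICI distance is reported alongside.

Cross-validation splits sessions five-fold, fits all factors on four folds
and simulates the held-out sessions from their own measured rates.  The
suppression sweep drives all nine levels with common random numbers (level
0 is bit-identical to the base trio model) and scores each level by the
absolute dyad-proportion difference plus standardized differences in
conversation count and mean length, reported separately.  Monotonicity of
the dyad proportion in the suppression level is a Monte-Carlo property:
the test requires a positive overall trend and no adjacent-level decrease
beyond twice the paired sampling error, since exact sample monotonicity of
a noisy proportion over 2.5% steps is a measure-zero event at any feasible
session count.

## Synthetic study conditions

The generators default to the scale of the behaviour they emulate:
1800 s sessions, volubility around 60 calls/session per caller (typical of
recorded marmoset pair sessions), phee lengths Gaussian with mean 2.5 s and sd
0.5 s truncated at 0.5 s, 1–3 pulses with f0 rising to ~8 kHz and
descending at a few kHz/s.  The coupled-oscillator control builds in a
linear phase advance (`next own onset += coupling_gain × response delay`),
so the planted gain is recoverable exactly as a regression slope; the
planted four-factor truth uses an AR(5) state with lag-1-dominant
coefficients, a two-scale arousal decay, interruption decay 1.5 s⁻¹, a 2 s
refractory and a 3 s response peak.  What the generators do *not* emulate:
acoustic variation tied to behaviour (synthetic phees are clean and
deterministic given the spec), demographic structure (age, sex,
relatedness), movement, and background noise.  Passing tests therefore
show that the pipeline's estimators and simulator are correct and
internally consistent at realistic scale — not that the fitted values for
any particular colony equal those reported elsewhere.

## Numerical choices and degenerate inputs

Time is float seconds; simulated onsets lie on the 0.2 s bin grid, so
estimators bin lag differences by `floor(lag/bin + 1e-9)` rather than
histogram edges (grid-aligned values on edges would otherwise scatter by
float error).  Call-table I/O round-trips exactly
(`float_precision="round_trip"`).  Sessions without usable PRC pairs are
dropped from pooling with a count; corpora with no overlaps at all yield a
degenerate interruption curve (total avoidance) that is flagged rather
than fitted; a non-invertible correction fit is clipped away from the pole
in the fixed-point solve.  All stochastic steps consume
`numpy.random.Generator` objects derived from a single seed;
per-stage/per-session substreams come from `SeedSequence.spawn`, so any
stage can be re-run independently and two runs with the same configuration
and seed are identical.

## Known limitations

The simulator's probabilities are clipped, not renormalized, so extreme
parameter combinations (rates far above 300 with strong facilitation) can
saturate; the linear correction model is accurate to a few percent over
the calibrated 0–300 grid but is an approximation to a curved discrepancy
surface; the PRC pooled correlation carries the small positive
finite-sample expectation discussed above; and the mixed-effects logistic
fit is variational (posterior sds, hence CIs, are mildly optimistic).
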