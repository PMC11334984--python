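"""Per-call predictors of response probability.

Twelve features are computed per call — timing/behavioural features from the
call table (calling rates, position in conversation, partner ICI, partner
call length) and acoustic features from the fundamental-frequency track
(start/max/end frequency, ending slope, pulse count, last-pulse length,
loudness) — plus a binary odd/even conversation-position flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from vocalturns.corpus import (
    DEFAULT_RESPONSE_WINDOW,
    Session,
    label_events,
    segment_conversations,
)
from vocalturns.synth import FEATURE_NAMES

#: STFT defaults: 10 ms frames, 2.5 ms hop; frames more than 40 dB below the
#: peak frame are treated as silence.
DEFAULT_FRAME_S = 0.010
DEFAULT_HOP_S = 0.0025
ENERGY_FLOOR_DB = 40.0


def extract_f0_track(waveform: np.ndarray, sample_rate: float,
                     frame_length: float = DEFAULT_FRAME_S,
                     hop: float = DEFAULT_HOP_S,
                     floor_db: float = ENERGY_FLOOR_DB,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Fundamental-frequency track: per STFT frame, the frequency of maximum
    spectral power.  Returns ``(times, f0)`` with NaN for frames below the
    energy floor."""
    waveform = np.asarray(waveform, float)
    if waveform.size == 0:
        raise ValueError("empty waveform")
    if frame_length < 2 * hop:
        raise ValueError("frame_length must be >= 2 * hop")
    nperseg = max(16, int(round(frame_length * sample_rate)))
    nhop = max(1, int(round(hop * sample_rate)))
    freqs, times, Z = signal.stft(waveform, fs=sample_rate, nperseg=nperseg,
                                  noverlap=nperseg - nhop, padded=False,
                                  boundary=None)
    power = np.abs(Z) ** 2
    frame_energy = power.sum(axis=0)
    f0 = freqs[np.argmax(power, axis=0)].astype(float)
    peak = frame_energy.max()
    if peak <= 0:
        f0[:] = np.nan
    else:
        f0[frame_energy < peak * 10 ** (-floor_db / 10)] = np.nan
    return times, f0


def detect_pulses(waveform: np.ndarray, sample_rate: float,
                  threshold: float = 0.1, min_gap: float = 0.03,
                  frame_length: float = DEFAULT_FRAME_S,
                  hop: float = DEFAULT_HOP_S,
                  ) -> list[tuple[float, float]]:
    """Segment a call into phee pulses by its energy envelope.

    Maximal runs of frames whose RMS exceeds ``threshold`` (fraction of the
    peak RMS) are pulses; runs separated by less than ``min_gap`` s merge.
    Returns half-open ``[onset, offset)`` intervals in seconds.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if min_gap <= 0:
        raise ValueError("min_gap must be > 0")
    waveform = np.asarray(waveform, float)
    nperseg = max(16, int(round(frame_length * sample_rate)))
    nhop = max(1, int(round(hop * sample_rate)))
    n_frames = max(0, 1 + (len(waveform) - nperseg) // nhop)
    if n_frames == 0:
        return []
    idx = np.arange(n_frames)[:, None] * nhop + np.arange(nperseg)
    rms = np.sqrt(np.mean(waveform[idx] ** 2, axis=1))
    peak = rms.max()
    if peak <= 0:
        return []
    above = rms >= threshold * peak
    times = idx[:, 0] / sample_rate
    intervals: list[list[float]] = []
    for i, a in enumerate(above):
        if not a:
            continue
        t0, t1 = times[i], times[i] + nperseg / sample_rate
        if intervals and t0 - intervals[-1][1] < min_gap:
            intervals[-1][1] = t1
        else:
            intervals.append([t0, t1])
    return [(a, b) for a, b in intervals]


def acoustic_fields_from_track(times: np.ndarray, f0: np.ndarray,
                               pulses: list[tuple[float, float]] | None = None,
                               ) -> dict:
    """Start/max/end frequency and ending slope from an f0 track, plus pulse
    count and last-pulse length when pulse intervals are given."""
    valid = ~np.isnan(f0)
    out: dict = {}
    if valid.any():
        tv, fv = times[valid], f0[valid]
        i_max = int(np.argmax(fv))
        out["start_frequency"] = float(fv[0])
        out["max_frequency"] = float(fv[i_max])
        out["end_frequency"] = float(fv[-1])
        dt = tv[-1] - tv[i_max]
        out["ending_slope"] = float((fv[-1] - fv[i_max]) / dt) if dt > 0 else 0.0
    if pulses:
        out["n_pulses"] = len(pulses)
        out["last_pulse_length"] = float(pulses[-1][1] - pulses[-1][0])
    return out


# ---------------------------------------------------------------------------
# Model-row assembly


def compute_features(session: Session,
                     response_window: float = DEFAULT_RESPONSE_WINDOW,
                     acoustic: dict[int, dict] | None = None,
                     cumulative_rate: bool = True) -> pd.DataFrame:
    """One model row per call: the 12 predictors, odd/even flag, response
    label and responder delay.

    Timing features come from the call table; acoustic features (keyed by
    call index in ``acoustic``) are merged in when available and left NaN
    otherwise.  ``monkey_calling_rate`` / ``partner_calling_rate`` are
    cumulative mean rates (calls so far, scaled to calls/session) up to the
    call; pass ``cumulative_rate=False`` for whole-session rates.
    ``call_number_in_conversation`` is the call's 1-based position within its
    conversation segment (0 outside any segment).  Rows whose partner-derived
    predictors are undefined (first calls) carry NaN and are dropped by the
    modelling stage.
    """
    labels = label_events(session, response_window)
    segments = segment_conversations(session, response_window)
    conv_pos = np.zeros(len(session.calls), int)
    for seg in segments:
        for pos, ci in enumerate(seg.call_indices, start=1):
            conv_pos[ci] = pos
    calls = session.calls
    rows = []
    for i, c in enumerate(calls):
        own_prev = [x for x in calls[: i + 1] if x.caller_id == c.caller_id]
        partner_prev = [x for x in calls[:i] if x.caller_id != c.caller_id]
        if cumulative_rate and c.onset > 0:
            own_rate = len(own_prev) / c.onset * session.duration
            partner_rate = len(partner_prev) / c.onset * session.duration
        else:
            own_rate = session.call_rate(c.caller_id)
            partner_rate = float(len([x for x in calls
                                      if x.caller_id != c.caller_id]))
        last_partner = partner_prev[-1] if partner_prev else None
        # response label: did any other caller respond to THIS call?
        responded = any(
            o.caller_id != c.caller_id and 0 < o.onset - c.offset <= response_window
            for o in calls[i + 1:]
        )
        resp_delay = np.nan
        if responded:
            resp_delay = min(
                o.onset - c.offset for o in calls[i + 1:]
                if o.caller_id != c.caller_id
                and 0 < o.onset - c.offset <= response_window
            )
        row = {
            "session_id": session.session_id,
            "caller_id": c.caller_id,
            "call_index": i,
            "monkey_calling_rate": own_rate,
            "call_number_in_conversation": int(conv_pos[i]),
            "partner_call_length": (last_partner.duration if last_partner
                                    else np.nan),
            "partner_calling_rate": partner_rate,
            "partner_ici": (c.onset - last_partner.onset if last_partner
                            else np.nan),
            "odd_even": int(conv_pos[i] % 2),
            "response": int(responded),
            "delay": resp_delay,
            "is_interrupting": bool(labels["is_interrupting"][i]),
        }
        for name in ("max_frequency", "loudness", "n_pulses", "ending_slope",
                     "start_frequency", "last_pulse_length", "end_frequency"):
            row[name] = np.nan
        if acoustic and i in acoustic:
            row.update(acoustic[i])
        rows.append(row)
    df = pd.DataFrame(rows)
    # loudness is relative to the caller's session mean, so normalize here
    if acoustic and df["loudness"].notna().any():
        for cid, grp in df.groupby("caller_id"):
            m = grp["loudness"].mean()
            if m > 0:
                df.loc[grp.index, "loudness"] = grp["loudness"] / m
    return df


def corpus_model_rows(corpus: list[Session],
                      response_window: float = DEFAULT_RESPONSE_WINDOW,
                      timing_only: bool = True) -> pd.DataFrame:
    """Stack model rows over a corpus and attach partner ids (pair sessions).

    With ``timing_only`` the acoustic columns are dropped; rows with
    undefined partner-derived predictors are removed and the removal count is
    recorded in ``df.attrs['n_dropped']``.
    """
    frames = []
    for s in corpus:
        df = compute_features(s, response_window)
        if s.context == "pair":
            other = {s.roster[0]: s.roster[1], s.roster[1]: s.roster[0]}
            df["partner_id"] = df["caller_id"].map(other)
        else:
            df["partner_id"] = "none"
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    predictors = ["monkey_calling_rate", "call_number_in_conversation",
                  "partner_call_length", "partner_calling_rate", "partner_ici"]
    if timing_only:
        out = out.drop(columns=["max_frequency", "loudness", "n_pulses",
                                "ending_slope", "start_frequency",
                                "last_pulse_length", "end_frequency"])
    else:
        predictors = predictors + [n for n in FEATURE_NAMES
                                   if n not in predictors]
    n0 = len(out)
    out = out.dropna(subset=predictors).reset_index(drop=True)
    out.attrs["n_dropped"] = n0 - len(out)
    out.attrs["predictors"] = predictors
    return out
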