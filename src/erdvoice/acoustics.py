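"""Acoustic descriptors and vocal-imitation accuracy scoring.

Imitation accuracy is scored on *intervals*, not absolute pitch: for a
five-note melody the four produced intervals (cents between median f0 of
consecutive notes) are compared with the four target intervals, and a
participant's score is the mean absolute deviation in cents.  Scoring on
intervals makes the measure invariant to global transposition, so a singer
who renders the contour perfectly a third too low still scores 0.

Voice-quality descriptors (local jitter, local shimmer, per-cycle f0 SD in
cents, median note duration) are measured cycle-by-cycle from interpolated
zero crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .melody import Melody


def cents(f1: float, f2: float) -> float:
    """Signed interval from f1 to f2 in cents: 1200 * log2(f2 / f1)."""
    if f1 <= 0 or f2 <= 0:
        raise ValueError("frequencies must be positive")
    return 1200.0 * np.log2(f2 / f1)


@dataclass
class F0Track:
    """Per-frame fundamental-frequency estimates with note boundaries."""

    times: np.ndarray                 # frame centers, s
    f0: np.ndarray                    # Hz (np.nan where unvoiced)
    voiced: np.ndarray                # bool per frame
    note_boundaries: list = field(default_factory=list)  # (start_s, end_s)

    def note_median_f0(self) -> np.ndarray:
        """Median f0 of voiced frames within each note (nan if none)."""
        out = []
        for s, e in self.note_boundaries:
            sel = (self.times >= s) & (self.times < e) & self.voiced
            out.append(float(np.median(self.f0[sel])) if sel.any() else np.nan)
        return np.asarray(out)


@dataclass
class AccuracyScore:
    """Interval-deviation score for one melody rendition."""

    produced_cents: np.ndarray
    target_cents: np.ndarray
    deviations: np.ndarray            # absolute, cents
    excluded: bool = False            # fewer than 5 voiced notes detected

    @property
    def mean_abs_deviation(self) -> float:
        return float(np.mean(self.deviations)) if not self.excluded else np.nan


def _autocorr(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Positive-lag autocorrelation via FFT (linear, zero-padded)."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    return ac if max_lag is None else ac[:max_lag + 1]


def _refine_lag(r: np.ndarray, lag: int) -> float:
    """Parabolic interpolation of an autocorrelation peak position."""
    if not 0 < lag < len(r) - 1:
        return float(lag)
    y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
    return lag + float(np.clip(delta, -0.5, 0.5))


def estimate_f0(
    audio,
    frame_ms: float = 40.0,
    hop_ms: float = 10.0,
    range_hz=(80.0, 500.0),
    voicing_threshold: float = 0.5,
    silence_rms: float = 1e-4,
) -> F0Track:
    """Autocorrelation pitch tracker with parabolic peak interpolation.

    A frame is voiced when its normalized autocorrelation peak inside the
    search range exceeds ``voicing_threshold`` and its RMS exceeds
    ``silence_rms`` (relative measure on [-1, 1] audio).  Deterministic.
    """
    x = np.asarray(audio.samples, float)
    sr = audio.sample_rate
    frame = int(round(frame_ms * 1e-3 * sr))
    hop = int(round(hop_ms * 1e-3 * sr))
    if len(x) < frame:
        raise ValueError("audio shorter than one analysis frame")
    lag_min = max(2, int(np.floor(sr / range_hz[1])))
    lag_max = int(np.ceil(sr / range_hz[0]))
    times, f0s, voiced = [], [], []
    for start in range(0, len(x) - frame + 1, hop):
        seg = x[start:start + frame]
        seg = seg - seg.mean()
        rms = np.sqrt(np.mean(seg**2))
        t_center = (start + frame / 2) / sr
        times.append(t_center)
        if rms < silence_rms or lag_max >= frame:
            f0s.append(np.nan)
            voiced.append(False)
            continue
        ac = _autocorr(seg)
        # normalize by the shrinking overlap so long lags are not penalized
        norm = ac[0] * (1.0 - np.arange(frame) / frame)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(norm > 0, ac / norm, 0.0)
        rr = r[lag_min:lag_max + 1]
        best = float(rr.max())
        if best < voicing_threshold:
            f0s.append(np.nan)
            voiced.append(False)
            continue
        # octave protection: earliest local maximum within 5% of the best
        # peak wins, so multiples of the true period are not preferred
        is_peak = np.r_[False, (rr[1:-1] >= rr[:-2]) & (rr[1:-1] >= rr[2:]), False]
        cand = np.flatnonzero(is_peak & (rr >= best - 0.05))
        lag = lag_min + (int(cand[0]) if len(cand) else int(np.argmax(rr)))
        lag_f = _refine_lag(r, lag)
        # sub-cent accuracy: re-estimate at the largest whole multiple of
        # the period that fits, dividing the interpolation error by k
        k = int((frame - 2) // lag_f)
        if k > 1:
            k = min(k, 4)
            approx = k * lag_f
            w = max(2, int(lag_f / 4))
            j0 = max(1, int(round(approx)) - w)
            j1 = min(frame - 2, int(round(approx)) + w)
            lag_k = j0 + int(np.argmax(r[j0:j1 + 1]))
            lag_f = _refine_lag(r, lag_k) / k
        f0s.append(sr / lag_f)
        voiced.append(True)
    return F0Track(
        times=np.asarray(times),
        f0=np.asarray(f0s),
        voiced=np.asarray(voiced, bool),
        note_boundaries=list(audio.note_boundaries),
    )


def score_accuracy(produced: F0Track, target: Melody) -> AccuracyScore:
    """Score one rendition against its target melody, interval by interval.

    Produced interval k = cents(median f0 of note k, median f0 of note k+1);
    the score is the mean absolute deviation from the target intervals.  A
    rendition with fewer than five voiced notes is flagged ``excluded`` and
    carries no deviations.
    """
    med = produced.note_median_f0()
    n_target = len(target.pitches)
    tgt = 100.0 * np.diff(np.asarray(target.pitches))
    if len(med) < n_target or np.isnan(med[:n_target]).any():
        return AccuracyScore(
            produced_cents=np.full(n_target - 1, np.nan),
            target_cents=tgt,
            deviations=np.full(n_target - 1, np.nan),
            excluded=True,
        )
    med = med[:n_target]
    prod = 1200.0 * np.diff(np.log2(med))
    dev = np.abs(prod - tgt)
    return AccuracyScore(produced_cents=prod, target_cents=tgt, deviations=dev)


def _cycle_marks(x: np.ndarray, sr: int, f0_hint: float | None = None):
    """Times of positive-going zero crossings, linearly interpolated.

    Crossings closer than 0.5 / f0_hint are merged (keep the first) to
    protect against ripple-induced double crossings.
    """
    s = np.signbit(x)
    idx = np.flatnonzero(s[:-1] & ~s[1:])
    if len(idx) < 2:
        return np.empty(0)
    frac = -x[idx] / (x[idx + 1] - x[idx])
    t = (idx + frac) / sr
    if f0_hint:
        min_gap = 0.5 / f0_hint
        keep = [0]
        for i in range(1, len(t)):
            if t[i] - t[keep[-1]] >= min_gap:
                keep.append(i)
        t = t[keep]
    return t


def jitter_shimmer(audio, note_bounds=None, trim_s: float = 0.010):
    """Cycle-level voice descriptors of a quasi-periodic clip.

    Returns ``(jitter_pct, shimmer_pct, f0_sd_cents, median_note_dur_s)``:

    * jitter  = mean |T_i - T_{i-1}| / mean T * 100   (local jitter)
    * shimmer = mean |A_i - A_{i-1}| / mean A * 100   (local shimmer, cycle
      peak amplitudes, parabolically interpolated)
    * f0 SD   = SD of per-cycle f0 in cents around the note median
    * duration from the note bounds

    ``trim_s`` seconds at each note edge are excluded so onset/offset ramps
    do not contaminate the cycle statistics.
    """
    x = np.asarray(audio.samples, float)
    sr = audio.sample_rate
    bounds = note_bounds if note_bounds is not None else audio.note_boundaries
    if not bounds:
        raise ValueError("note boundaries required")
    jit_num, jit_den, shi_num, shi_den = [], [], [], []
    cents_dev = []
    durs = []
    for s_t, e_t in bounds:
        durs.append(e_t - s_t)
        i0 = int(round((s_t + trim_s) * sr))
        i1 = int(round((e_t - trim_s) * sr))
        seg = x[i0:i1]
        if len(seg) < 8:
            continue
        # rough f0 from autocorrelation to set the crossing merge gap
        lag_min = max(2, int(sr / 600))
        lag_max = min(len(seg) - 1, int(sr / 70))
        ac = _autocorr(seg - seg.mean(), lag_max)
        lag = lag_min + int(np.argmax(ac[lag_min:lag_max + 1]))
        f0_hint = sr / lag
        marks = _cycle_marks(seg, sr, f0_hint)
        if len(marks) < 4:
            raise ValueError("fewer than 3 detected cycles in a note")
        periods = np.diff(marks)
        # per-cycle peak amplitude with parabolic refinement
        amps = []
        for a_t, b_t in zip(marks[:-1], marks[1:]):
            ia, ib = int(np.ceil(a_t * sr)), int(np.floor(b_t * sr))
            if ib - ia < 3:
                amps.append(np.nan)
                continue
            cyc = np.abs(seg[ia:ib])
            p = int(np.argmax(cyc))
            if 0 < p < len(cyc) - 1:
                y0, y1, y2 = cyc[p - 1], cyc[p], cyc[p + 1]
                denom = y0 - 2 * y1 + y2
                amps.append(y1 - 0.25 * (y0 - y2) ** 2 / denom if denom < 0 else y1)
            else:
                amps.append(cyc[p])
        amps = np.asarray(amps, float)
        ok = ~np.isnan(amps)
        jit_num.extend(np.abs(np.diff(periods)))
        jit_den.extend(periods)
        if ok.sum() >= 2:
            aa = amps[ok]
            shi_num.extend(np.abs(np.diff(aa)))
            shi_den.extend(aa)
        f0_cyc = 1.0 / periods
        cents_dev.extend(1200.0 * np.log2(f0_cyc / np.median(f0_cyc)))
    if not jit_den:
        raise ValueError("no analyzable cycles")
    jitter_pct = 100.0 * np.mean(jit_num) / np.mean(jit_den)
    shimmer_pct = 100.0 * np.mean(shi_num) / np.mean(shi_den)
    f0_sd_cents = float(np.std(cents_dev, ddof=1)) if len(cents_dev) > 1 else 0.0
    return float(jitter_pct), float(shimmer_pct), f0_sd_cents, float(np.median(durs))
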