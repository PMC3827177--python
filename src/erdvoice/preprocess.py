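"""EEG preprocessing: high-pass filter, mastoid re-reference, blink
removal, epoching and artifact rejection.

The rejection stage applies three rules across the epoch dimension:

* amplitude: any sample with |x| above a fixed threshold (default 100 µV);
* improbability: per channel, a Gaussian is fit to all samples pooled
  across epochs; each epoch's statistic is the mean negative log-density of
  its samples, z-scored across epochs — epochs far in the tails of the
  pooled distribution stand out;
* kurtosis: per-channel sample excess kurtosis per epoch, z-scored across
  epochs (two-sided).

A trial failing any rule is dropped; the recorded reason is the first rule
(in the order above) that triggered.
"""

from __future__ import annotations

import numpy as np
from scipy import signal, stats

from .recording import EpochSet, RawRecording


def highpass(raw: RawRecording, cutoff_hz: float = 1.0, order: int = 4) -> RawRecording:
    """Zero-phase Butterworth high-pass (forward-backward) on all channels."""
    nyq = raw.sfreq / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError("cutoff must be positive and below Nyquist")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=raw.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, raw.data, axis=1).astype(raw.data.dtype)
    return raw.copy_with(out)


def reref_mastoids(raw: RawRecording, mastoids=("M1", "M2")) -> RawRecording:
    """Re-reference to the algebraic average of the two mastoids.

    Every non-mastoid channel gets mean(M1, M2) subtracted; the mastoid
    channels themselves are dropped from the output.
    """
    for m in mastoids:
        if m not in raw.ch_names:
            raise ValueError(f"mastoid channel {m!r} missing")
    ref = 0.5 * (raw.get(mastoids[0]) + raw.get(mastoids[1]))
    keep = [i for i, c in enumerate(raw.ch_names) if c not in mastoids]
    out = raw.data[keep] - ref[None, :]
    return raw.copy_with(out, ch_names=[raw.ch_names[i] for i in keep])


def remove_blinks(
    raw: RawRecording,
    eog_channel: str,
    lowpass_hz: float = 6.0,
    exclude=("EMG",),
) -> RawRecording:
    """Regression-based blink removal.

    A blink reference is built by low-pass filtering the frontal/EOG
    channel below ``lowpass_hz`` (blinks are slow, large deflections; 6 Hz
    keeps >99% of a typical 350 ms blink template while leaving the mu and
    beta bands untouched); each scalp channel then has its least-squares
    projection onto that reference subtracted.  Channels in ``exclude``
    (default: the EMG electrode) are passed through unchanged.
    """
    if eog_channel not in raw.ch_names:
        raise ValueError(f"EOG/reference channel {eog_channel!r} missing")
    sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=raw.sfreq, output="sos")
    ref = signal.sosfiltfilt(sos, np.asarray(raw.get(eog_channel), np.float64))
    denom = float(ref @ ref)
    out = np.array(raw.data, dtype=np.float64, copy=True)
    if denom > 0:
        beta = (out @ ref) / denom
        for name in exclude:
            if name in raw.ch_names:
                beta[raw.channel_index(name)] = 0.0
        out -= np.outer(beta, ref)
    return raw.copy_with(out.astype(raw.data.dtype))


def epoch(raw: RawRecording, lock: str, window_s=(1.0, 5.0)) -> EpochSet:
    """Cut fixed-length epochs around every event whose label matches.

    ``lock`` may be an exact label or a prefix (``"stim"`` matches
    ``stim_vocal`` and ``stim_nonvocal``).  ``window_s = (pre, post)``
    yields exactly ``(pre + post) * sfreq`` samples per epoch.  Trials
    whose window exceeds the recording are kept but flagged with reason
    ``"edge"`` rather than silently dropped.
    """
    import warnings

    pre, post = window_s
    n_pre = int(round(pre * raw.sfreq))
    n_post = int(round(post * raw.sfreq))
    n_len = n_pre + n_post
    matches = [ev for ev in raw.events if ev.label == lock or ev.label.startswith(lock)]
    if not matches:
        warnings.warn(f"no events matching {lock!r}; empty epoch set")
        return EpochSet(
            data=np.empty((0, len(raw.ch_names), n_len), raw.data.dtype),
            ch_names=list(raw.ch_names), sfreq=raw.sfreq,
            times=(np.arange(n_len) - n_pre) / raw.sfreq,
            conditions=[], lock=lock,
        )
    data = np.zeros((len(matches), len(raw.ch_names), n_len), raw.data.dtype)
    kept = np.ones(len(matches), bool)
    reasons = ["none"] * len(matches)
    conds, tidx = [], []
    for k, ev in enumerate(matches):
        i0 = int(round(ev.onset_s * raw.sfreq)) - n_pre
        if i0 < 0 or i0 + n_len > raw.n_samples:
            kept[k] = False
            reasons[k] = "edge"
        else:
            data[k] = raw.data[:, i0:i0 + n_len]
        conds.append(ev.label.replace("stim_", "") if ev.label.startswith("stim_") else ev.label)
        tidx.append(ev.trial_index)
    return EpochSet(
        data=data, ch_names=list(raw.ch_names), sfreq=raw.sfreq,
        times=(np.arange(n_len) - n_pre) / raw.sfreq,
        conditions=conds, lock=lock, kept=kept, reasons=reasons,
        trial_indices=np.asarray(tidx),
    )


def reject_epochs(
    ep: EpochSet,
    amp_uv: float = 100.0,
    prob_sd: float = 5.0,
    kurt_sd: float = 5.0,
    channels=None,
) -> EpochSet:
    """Mark artifact epochs; surviving epochs are unchanged.

    ``channels`` restricts the rules to a channel subset (default: all
    channels in the epoch set).  Raising any threshold never increases the
    number of rejected epochs (each rule is a monotone exceedance test).
    """
    if ep.n_trials < 8:
        raise ValueError("need at least 8 epochs for across-epoch statistics")
    if channels is None:
        idx = np.arange(len(ep.ch_names))
    else:
        idx = np.array([ep.channel_index(c) for c in channels])
    x = ep.data[:, idx, :]  # trials x ch x samp
    valid = np.asarray(ep.kept, bool)

    # rule 1: extreme amplitude
    amp_bad = np.abs(x).max(axis=(1, 2)) > amp_uv

    # rule 2: joint improbability. Gaussian fit per channel over pooled
    # samples of valid epochs; epoch stat = mean NLL; z-score over epochs.
    mu = x[valid].mean(axis=(0, 2), dtype=np.float64)
    sd = np.sqrt((x[valid].astype(np.float64) ** 2).mean(axis=(0, 2)) - mu**2)
    sd = np.where(sd > 0, sd, 1.0)
    xc = x - mu[None, :, None].astype(x.dtype)
    x2 = (xc / sd[None, :, None].astype(x.dtype)) ** 2
    nll = 0.5 * x2.mean(axis=2, dtype=np.float64)
    z_prob = _zscore_epochs(nll, valid)
    prob_bad = np.nanmax(z_prob, axis=1) > prob_sd

    # rule 3: abnormal distribution (excess kurtosis per epoch, two-sided)
    em = x.mean(axis=2, dtype=np.float64)
    d = x - em[:, :, None].astype(x.dtype)
    d2 = d * d
    m2e = d2.mean(axis=2, dtype=np.float64)
    m4e = (d2 * d2).mean(axis=2, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        kurt = m4e / m2e**2 - 3.0
    z_kurt = _zscore_epochs(kurt, valid)
    kurt_bad = np.nanmax(np.abs(z_kurt), axis=1) > kurt_sd

    kept = np.array(ep.kept, copy=True)
    reasons = list(ep.reasons)
    for k in range(ep.n_trials):
        if not valid[k]:
            continue
        if amp_bad[k]:
            kept[k], reasons[k] = False, "amplitude"
        elif prob_bad[k]:
            kept[k], reasons[k] = False, "improbability"
        elif kurt_bad[k]:
            kept[k], reasons[k] = False, "kurtosis"
    return EpochSet(
        data=ep.data, ch_names=list(ep.ch_names), sfreq=ep.sfreq, times=ep.times,
        conditions=list(ep.conditions), lock=ep.lock, kept=kept, reasons=reasons,
        trial_indices=ep.trial_indices,
    )


def _zscore_epochs(stat: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """z-score a (trials x channels) statistic across valid trials."""
    m = stat[valid].mean(axis=0)
    s = stat[valid].std(axis=0)
    s = np.where(s > 0, s, np.inf)
    return (stat - m[None, :]) / s[None, :]


def preprocess_pipeline(
    raw: RawRecording,
    eog_channel: str = "Fpz",
    cutoff_hz: float = 1.0,
    amp_uv: float = 100.0,
    prob_sd: float = 5.0,
    kurt_sd: float = 5.0,
    perception_window=(1.0, 5.0),
    production_window=(1.0, 6.0),
    scalp_only: bool = True,
):
    """Fixed-order pipeline: highpass -> reref -> blink removal -> epoch ->
    reject.  Returns (perception EpochSet, production EpochSet).

    Rejection statistics are computed on scalp channels only (the EMG
    electrode legitimately carries high-amplitude, high-kurtosis bursts).
    """
    raw = highpass(raw, cutoff_hz)
    raw = reref_mastoids(raw)
    raw = remove_blinks(raw, eog_channel)
    scalp = [c for c in raw.ch_names if c != "EMG"] if scalp_only else None
    out = []
    for lock, win in (("stim", perception_window), ("go", production_window)):
        ep = epoch(raw, lock, win)
        out.append(reject_epochs(ep, amp_uv, prob_sd, kurt_sd, channels=scalp))
    return tuple(out)
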