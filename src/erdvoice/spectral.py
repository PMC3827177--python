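"""Welch band power and event-related desynchronization (ERD).

The core quantity: per trial and electrode, mean power spectral density in
a frequency band (mu 7.5–12 Hz, beta 14–21 Hz) inside an analysis window,
minus the same band's power in the pre-stimulus baseline (−500 to 0 ms).
Negative values mean desynchronization (ERD), positive synchronization
(ERS).  Trials are averaged within condition first, then electrodes within
each region of interest, then (by callers) participants.

Spectra use Welch's method with 512-sample Hann windows at 50% overlap —
0.5 Hz bins at 512 Hz — in density scaling (µV²/Hz).  The 0.5 s baseline
is shorter than one Welch window, so it is estimated with a single
256-point Hann periodogram (2 Hz bins) and compared in band-power units,
not bin-by-bin.  Note the subtractive ERD is not scale-invariant: doubling
the signal amplitude quadruples both terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .montage import DEFAULT_ROIS, FRONTOCENTRAL_6
from .recording import EpochSet

#: analysis bands, Hz (inclusive bin-center bounds)
DEFAULT_BANDS = {"mu": (7.5, 12.0), "beta": (14.0, 21.0)}

BASELINE_S = (-0.5, 0.0)
PERCEPTION_WINDOW_S = (0.0, 3.5)
PRODUCTION_WINDOW_S = (0.0, 5.0)

#: five 1-s windows tiling stimulus onset .. go signal
TIMECOURSE_WINDOWS = {f"w{i + 1}": (float(i), float(i + 1)) for i in range(5)}


@dataclass
class RoiSpec:
    """Named electrode groups for regional averaging."""

    regions: dict = field(default_factory=lambda: dict(DEFAULT_ROIS))
    frontocentral: tuple = FRONTOCENTRAL_6

    def __post_init__(self):
        seen = set()
        for name, els in self.regions.items():
            if seen & set(els):
                raise ValueError(f"ROI {name} overlaps another region")
            seen |= set(els)

    def electrodes(self) -> list:
        els = {e for group in self.regions.values() for e in group}
        return sorted(els | set(self.frontocentral))


def welch_psd(
    segment: np.ndarray,
    rate: float,
    win_len: int = 512,
    overlap_frac: float = 0.5,
    axis: int = -1,
    bin_hz: float = 0.5,
):
    """Welch PSD with Hann windows, density scaling, on a fixed bin grid.

    The transform is zero-padded so the output grid spacing is ``bin_hz``
    (0.5 Hz by default, i.e. nfft = 1024 at 512 Hz) regardless of the
    window length; zero-padding interpolates the spectrum without changing
    its resolution, so a 512-point analysis window and the shorter 256-
    point baseline window are sampled on the same grid.  A segment shorter
    than ``win_len`` is analyzed as a single shortened Hann window.
    """
    segment = np.asarray(segment)
    n = segment.shape[axis]
    if n == 0:
        raise ValueError("empty segment")
    nperseg = min(win_len, n)
    nfft = max(nperseg, int(round(rate / bin_hz)))
    freqs, psd = signal.welch(
        segment,
        fs=rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(overlap_frac * nperseg),
        nfft=nfft,
        detrend=False,
        scaling="density",
        axis=axis,
    )
    return freqs, psd


def band_power(psd: np.ndarray, freqs: np.ndarray, band, axis: int = -1) -> np.ndarray:
    """Mean spectral density over bins whose centers lie in [lo, hi]."""
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band}")
    return np.take(psd, np.flatnonzero(sel), axis=axis).mean(axis=axis)


def _window_samples(times: np.ndarray, t0: float, t1: float) -> slice:
    i0 = int(np.searchsorted(times, t0 - 1e-9))
    i1 = int(np.searchsorted(times, t1 - 1e-9))
    return slice(i0, i1)


def trial_band_powers(
    ep: EpochSet,
    electrodes,
    bands: dict = None,
    windows: dict = None,
    baseline=BASELINE_S,
    win_len: int = 512,
    baseline_mode: str = "per_trial",
) -> pd.DataFrame:
    """Per-trial baseline-subtracted band power for surviving epochs.

    Returns a tidy frame with one row per
    (trial, electrode, band, window): columns ``trial_index, condition,
    electrode, band, window, power, baseline, erd``.

    ``baseline_mode="per_trial"`` subtracts each trial's own pre-stimulus
    band power; ``"condition_mean"`` subtracts the mean baseline across
    the surviving trials of the same condition (per electrode and band).
    Cell means are identical either way; the per-trial form keeps the
    baseline's sampling noise inside the per-trial ERD, so across-trial
    standard errors reflect the full uncertainty of the mean ERD.
    """
    bands = bands if bands is not None else DEFAULT_BANDS
    windows = windows if windows is not None else {"analysis": PERCEPTION_WINDOW_S}
    surv = ep.surviving()
    if surv.n_trials == 0:
        return pd.DataFrame(
            columns=["trial_index", "condition", "electrode", "band", "window",
                     "power", "baseline", "erd"]
        )
    ei = [surv.channel_index(e) for e in electrodes]
    x = np.asarray(surv.data[:, ei, :], np.float64)

    # the 0.5 s baseline is one shortened Hann window, zero-padded onto
    # the same 0.5 Hz grid as the analysis windows so narrowband power is
    # sampled comparably
    bsl = x[:, :, _window_samples(surv.times, *baseline)]
    fb, pb = welch_psd(bsl, surv.sfreq, win_len=bsl.shape[-1])
    base = {b: band_power(pb, fb, rng) for b, rng in bands.items()}
    if baseline_mode == "condition_mean":
        conds = np.asarray(surv.conditions)
        for b in base:
            out = np.empty_like(base[b])
            for c in np.unique(conds):
                sel = conds == c
                out[sel] = base[b][sel].mean(axis=0, keepdims=True)
            base[b] = out
    elif baseline_mode != "per_trial":
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")

    rows = []
    for wname, (t0, t1) in windows.items():
        seg = x[:, :, _window_samples(surv.times, t0, t1)]
        fw, pw = welch_psd(seg, surv.sfreq, win_len=win_len)
        for bname, brange in bands.items():
            pwr = band_power(pw, fw, brange)  # trials x electrodes
            for j, e in enumerate(electrodes):
                for k in range(surv.n_trials):
                    rows.append(
                        (int(surv.trial_indices[k]), surv.conditions[k], e,
                         bname, wname, pwr[k, j], base[bname][k, j],
                         pwr[k, j] - base[bname][k, j])
                    )
    return pd.DataFrame(
        rows,
        columns=["trial_index", "condition", "electrode", "band", "window",
                 "power", "baseline", "erd"],
    )


def erd(
    ep: EpochSet,
    roi: RoiSpec = None,
    bands: dict = None,
    analysis_windows: dict = None,
    baseline=BASELINE_S,
) -> pd.DataFrame:
    """Region-level ERD table: trials → electrodes averaging.

    One row per (condition, band, region, window) with the trial-then-
    electrode averaged ERD (µV²/Hz), the average baseline band power, the
    across-trial standard error of the regional ERD, and the surviving
    trial count.  A condition with no surviving trials yields a row with
    NaN values (flagged missing, never zero).
    """
    roi = roi if roi is not None else RoiSpec()
    bands = bands if bands is not None else DEFAULT_BANDS
    analysis_windows = (
        analysis_windows if analysis_windows is not None
        else {"analysis": PERCEPTION_WINDOW_S}
    )
    conditions = sorted(set(ep.conditions))
    rows = []
    for region, electrodes in roi.regions.items():
        tbl = trial_band_powers(ep, list(electrodes), bands, analysis_windows, baseline)
        if len(tbl):
            # average electrodes within trial first so the SE is across trials
            per_trial = (
                tbl.groupby(["trial_index", "condition", "band", "window"], sort=False)
                .agg(erd=("erd", "mean"), baseline=("baseline", "mean"))
                .reset_index()
            )
        for cond in conditions:
            for bname in bands:
                for wname in analysis_windows:
                    if len(tbl):
                        cell = per_trial[
                            (per_trial.condition == cond)
                            & (per_trial.band == bname)
                            & (per_trial.window == wname)
                        ]
                    else:
                        cell = tbl
                    n = len(cell)
                    if n == 0:
                        rows.append((cond, bname, region, wname,
                                     np.nan, np.nan, np.nan, 0))
                    else:
                        se = cell.erd.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
                        rows.append((cond, bname, region, wname,
                                     cell.erd.mean(), cell.baseline.mean(), se, n))
    out = pd.DataFrame(
        rows,
        columns=["condition", "band", "region", "window",
                 "erd_uv2hz", "baseline_uv2hz", "se", "n_trials"],
    )
    out["region_class"] = out.region.str.split("_").str[0]
    out["hemisphere"] = out.region.str.split("_").str[1]
    return out


def emg_band_power(
    ep: EpochSet,
    channel: str = "EMG",
    band=(10.0, 100.0),
    window: tuple | None = None,
) -> np.ndarray:
    """Welch band power of the EMG channel per surviving epoch (µV²/Hz).

    No baseline subtraction; ``window`` defaults to the post-lock part of
    the epoch.
    """
    if band[1] > ep.sfreq / 2:
        raise ValueError("band extends above Nyquist")
    surv = ep.surviving()
    ci = surv.channel_index(channel)
    t0, t1 = window if window is not None else (0.0, float(surv.times[-1]))
    x = np.asarray(surv.data[:, ci, _window_samples(surv.times, t0, t1)], np.float64)
    f, p = welch_psd(x, surv.sfreq)
    return band_power(p, f, band)
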