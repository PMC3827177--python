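"""Synthetic study generator with known ground truth.

The simulator produces a full vocal-imitation session: a randomized trial
schedule (half vocal, half non-vocal models), 64-channel 512 Hz EEG with
1/f background and band-limited mu (~10 Hz) and beta (~17.5 Hz) sources
whose amplitude drops (ERD) with condition-dependent onset and depth, a
labial EMG channel with production-locked bursts, optional blink and
extreme-amplitude artifacts, and per-participant sung responses whose
interval errors are coupled to the participant's simulated fronto-central
beta "humanness" effect.

This is a forward model whose *observables* match the phenomena the
analysis pipeline measures; it makes no claim of biophysical realism (no
volume conduction, no dipole physics).  Every parameter is explicit and
documented so recovery tests have well-defined targets.  ERD acts
multiplicatively on source amplitude: a depth d reduces amplitude by
(1 - d), hence band power by 1 - (1 - d)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.special import expit

from .melody import Melody, semitone_to_hz
from .montage import DEFAULT_ROIS, Montage, default_montage
from .recording import Event, RawRecording
from .acoustics import F0Track

SFREQ = 512.0
STIM_DUR_S = 3.75
GO_DELAY_S = 5.0            # go signal, relative to stimulus onset
PRODUCTION_WINDOW_S = 5.0


# ---------------------------------------------------------------------------
# schedule

@dataclass
class TrialSchedule:
    """Stimulus onsets, conditions and go times for one session."""

    onsets_s: np.ndarray
    conditions: list                   # "vocal" | "nonvocal" per trial
    stim_dur_s: float = STIM_DUR_S
    go_delay_s: float = GO_DELAY_S
    production_window_s: float = PRODUCTION_WINDOW_S

    @property
    def go_times_s(self) -> np.ndarray:
        return self.onsets_s + self.go_delay_s

    @property
    def n_trials(self) -> int:
        return len(self.onsets_s)

    def duration_s(self, tail_s: float = 3.0) -> float:
        return float(self.go_times_s[-1] + 6.0 + tail_s)

    def validate(self) -> None:
        if len(self.conditions) != self.n_trials:
            raise ValueError("conditions must match trial count")
        # perception epoch [-1, +5] s and production epoch [-1, +6] s must
        # not overlap across consecutive trials
        next_starts = self.onsets_s[1:] - 1.0
        prod_ends = self.go_times_s[:-1] + 6.0
        if np.any(next_starts < prod_ends):
            raise ValueError("epochs of consecutive trials overlap")


def make_schedule(
    n_trials: int = 120,
    rng_seed=0,
    lead_in_s: float = 3.0,
    gap_s: float = 2.0,
) -> TrialSchedule:
    """Randomized balanced schedule: n_trials/2 per condition.

    Consecutive stimulus onsets are spaced ``go_delay + 6 + 1 + gap_s``
    apart so perception and production epochs never overlap.
    """
    if n_trials % 2:
        raise ValueError("n_trials must be even (balanced conditions)")
    rng = np.random.default_rng(rng_seed)
    conds = ["vocal"] * (n_trials // 2) + ["nonvocal"] * (n_trials // 2)
    rng.shuffle(conds)
    spacing = GO_DELAY_S + 6.0 + 1.0 + gap_s
    onsets = lead_in_s + 1.0 + spacing * np.arange(n_trials)
    sched = TrialSchedule(onsets_s=onsets, conditions=conds)
    sched.validate()
    return sched


# ---------------------------------------------------------------------------
# ERD ground truth

@dataclass(frozen=True)
class ErdWindowParams:
    """One amplitude-modulation episode: logistic drop then recovery."""

    onset_s: float      # relative to the window's lock (stim onset / go)
    depth: float        # fractional amplitude reduction; negative = ERS
    ramp_s: float = 0.5


@dataclass
class ErdGroundTruth:
    """Per (band, region-class, condition) modulation parameters.

    Keys: band in {"mu", "beta"}, region in {"fc", "cp", "po"}, condition
    in {"vocal", "nonvocal", "production"}.  Defaults encode the target
    phenomenology: at fronto-central sites the listening ERD is earlier
    (1.0 s vs 3.0 s post-onset) and deeper for vocal than non-vocal models;
    production ERD is strongest centro-parietally; parieto-occipital sites
    show a mild listening ERS (negative depth).
    """

    params: dict = field(default_factory=dict)

    def __post_init__(self):
        defaults = {
            ("mu", "fc", "vocal"): ErdWindowParams(1.0, 0.40),
            ("mu", "fc", "nonvocal"): ErdWindowParams(3.0, 0.25),
            ("mu", "fc", "production"): ErdWindowParams(0.3, 0.35),
            ("beta", "fc", "vocal"): ErdWindowParams(1.0, 0.30),
            ("beta", "fc", "nonvocal"): ErdWindowParams(3.0, 0.18),
            ("beta", "fc", "production"): ErdWindowParams(0.3, 0.30),
            ("mu", "cp", "vocal"): ErdWindowParams(2.5, 0.10),
            ("mu", "cp", "nonvocal"): ErdWindowParams(3.0, 0.10),
            ("mu", "cp", "production"): ErdWindowParams(0.3, 0.45),
            ("beta", "cp", "vocal"): ErdWindowParams(2.5, 0.08),
            ("beta", "cp", "nonvocal"): ErdWindowParams(3.0, 0.08),
            ("beta", "cp", "production"): ErdWindowParams(0.3, 0.45),
            ("mu", "po", "vocal"): ErdWindowParams(0.5, -0.20),
            ("mu", "po", "nonvocal"): ErdWindowParams(0.5, -0.20),
            ("mu", "po", "production"): ErdWindowParams(0.3, 0.0),
            ("beta", "po", "vocal"): ErdWindowParams(0.5, 0.0),
            ("beta", "po", "nonvocal"): ErdWindowParams(0.5, 0.0),
            ("beta", "po", "production"): ErdWindowParams(0.3, 0.0),
        }
        defaults.update(self.params)
        self.params = defaults
        for band in ("mu", "beta"):
            v, nv = self.params[(band, "fc", "vocal")], self.params[(band, "fc", "nonvocal")]
            if v.depth < nv.depth or v.onset_s >= nv.onset_s:
                raise ValueError(
                    "fronto-central listening ERD must be deeper and earlier "
                    "for vocal than non-vocal trials"
                )

    def get(self, band, region, condition) -> ErdWindowParams:
        return self.params[(band, region, condition)]

    def null(self) -> "ErdGroundTruth":
        """Copy with all depths zero (no modulation)."""
        p = {k: replace(v, depth=0.0) for k, v in self.params.items()}
        return ErdGroundTruth(params=p)


# ---------------------------------------------------------------------------
# cohort profiles

@dataclass(frozen=True)
class ParticipantProfile:
    id: str
    tessitura: str
    vocal_inaccuracy_cents: float   # mean absolute interval deviation target
    beta_humanness_effect: float    # extra fronto-central beta vocal depth
    noise_scale: float = 1.0

    def __post_init__(self):
        if self.vocal_inaccuracy_cents <= 0:
            raise ValueError("inaccuracy must be > 0")


def make_cohort(
    n_participants: int = 19,
    rng_seed=0,
    coupling_rho: float = 0.49,
    erd: ErdGroundTruth | None = None,
    inaccuracy_median_cents: float = 52.0,
    inaccuracy_log_sd: float = 0.35,
    effect_median: float = 0.15,
    effect_log_sd: float = 0.33,
) -> list:
    """Draw participant profiles with rank-coupled inaccuracy and effect.

    Singing inaccuracy and the fronto-central beta humanness effect are
    both log-normal; their latent normals follow a Gaussian copula whose
    Pearson correlation ``2 sin(pi * rho / 6)`` yields a population
    Spearman correlation of ``coupling_rho``.  With ``|coupling_rho| = 1``
    the link is made exactly monotone (zero copula noise).
    """
    if not -1.0 <= coupling_rho <= 1.0:
        raise ValueError("|coupling_rho| must be <= 1")
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    rng = np.random.default_rng(rng_seed)
    z1 = rng.standard_normal(n_participants)
    if abs(coupling_rho) == 1.0:
        z2 = np.sign(coupling_rho) * z1
    else:
        r = 2.0 * np.sin(np.pi * coupling_rho / 6.0)
        z2 = r * z1 + np.sqrt(1 - r**2) * rng.standard_normal(n_participants)
    inacc = inaccuracy_median_cents * np.exp(inaccuracy_log_sd * z1)
    effect = effect_median * np.exp(effect_log_sd * z2)
    tess = rng.permutation(
        ["female"] * (n_participants - n_participants // 2)
        + ["male"] * (n_participants // 2)
    )
    return [
        ParticipantProfile(
            id=f"p{i:02d}",
            tessitura=str(tess[i]),
            vocal_inaccuracy_cents=float(inacc[i]),
            beta_humanness_effect=float(effect[i]),
        )
        for i in range(n_participants)
    ]


# ---------------------------------------------------------------------------
# EEG forward model

@dataclass
class SimulationParams:
    """Nuisance/physics parameters of the forward model (µV, Hz, s)."""

    background_sd_uv: float = 6.0     # broadband 1/f background per channel
    one_over_f_exponent: float = 1.0  # PSD ~ 1/f^exponent
    mu_center_hz: float = 10.0
    mu_bandwidth_hz: float = 2.0
    beta_center_hz: float = 17.5
    beta_bandwidth_hz: float = 4.0
    source_sd_uv: float = 9.0         # band-limited source SD at its center
    footprint_sigma: float = 0.35     # Gaussian spatial footprint (coord units)
    mastoid_sd_uv: float = 5.0
    emg_background_sd_uv: float = 3.0
    emg_burst_sd_uv: float = 30.0     # 10-100 Hz, production windows only
    blink_rate_hz: float = 0.08       # Poisson rate of blink events
    blink_amp_uv: float = 120.0       # at the frontal pole
    blink_dur_s: float = 0.35
    spike_epoch_rate: float = 0.13    # P(an epoch carries a >100 µV spike)
    spike_amp_uv: tuple = (150.0, 300.0)


def _one_over_f_noise(rng, n_ch, n_samp, sfreq, sd_uv, exponent):
    """FFT-shaped 1/f^a noise, per channel, scaled to the requested SD.

    The scaling uses the analytic variance of the shaped spectrum rather
    than a per-channel empirical SD (cheaper, and unbiased).
    """
    freqs = np.fft.rfftfreq(n_samp, 1 / sfreq)
    shape = np.ones(len(freqs), dtype=np.float32)
    nz = freqs > 0
    shape[nz] = freqs[nz].astype(np.float32) ** np.float32(-exponent / 2.0)
    shape[0] = 0.0
    re = rng.standard_normal((n_ch, len(freqs)), dtype=np.float32)
    im = rng.standard_normal((n_ch, len(freqs)), dtype=np.float32)
    spec = (re + 1j * im) * shape
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    # Parseval: E sum x^2 = (1/n) * full-spectrum E|X|^2
    interior = shape[1:-1] if n_samp % 2 == 0 else shape[1:]
    var = (4.0 * np.sum(interior.astype(np.float64) ** 2)
           + (2.0 * shape[-1] ** 2 if n_samp % 2 == 0 else 0.0)) / n_samp**2
    x *= np.float32(sd_uv / np.sqrt(var))
    return x.astype(np.float32)


def _bandlimited_noise(rng, n_samp, sfreq, center, bw, sd):
    lo, hi = center - bw / 2.0, center + bw / 2.0
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n_samp, dtype=np.float32))
    return (x * (sd / x.std())).astype(np.float32)


def _modulation_envelope(t, segments, floor=0.05):
    """Multiplicative amplitude envelope from (t0, t1, depth, ramp) tuples.

    Each segment pulls the envelope from 1 toward (1 - depth): the drop
    *begins* at t0 and completes by ~t0 + ramp (logistic edge centered at
    t0 + ramp/2, width ramp/8); recovery begins at t1 symmetrically.  The
    logistic is evaluated only near each segment (it saturates a few
    widths out).
    """
    env = np.ones(len(t), dtype=np.float32)
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    for t0, t1, depth, ramp in segments:
        if depth == 0.0:
            continue
        w = max(ramp / 8.0, 1e-3)
        c0, c1 = t0 + ramp / 2.0, t1 + ramp / 2.0
        i0 = max(0, int((c0 - 8 * w) / dt))
        i1 = min(len(t), int((c1 + 8 * w) / dt) + 1)
        ts = t[i0:i1]
        env[i0:i1] += (-depth) * (expit((ts - c0) / w) - expit((ts - c1) / w))
    return np.maximum(env, floor)


def simulate_eeg(
    profile: ParticipantProfile,
    schedule: TrialSchedule,
    montage: Montage | None = None,
    erd: ErdGroundTruth | None = None,
    rng_seed=0,
    sim: SimulationParams | None = None,
    artifacts: bool = True,
    sfreq: float = SFREQ,
) -> RawRecording:
    """Simulate one participant's continuous EEG session.

    Channel order: 64 scalp sites, two mastoids, EMG.  Events are embedded
    for every stimulus onset (``stim_vocal`` / ``stim_nonvocal``) and go
    signal (``go``).
    """
    montage = montage if montage is not None else default_montage()
    montage.require([e for roi in DEFAULT_ROIS.values() for e in roi])
    erd = erd if erd is not None else ErdGroundTruth()
    sim = sim if sim is not None else SimulationParams()
    schedule.validate()
    rng = np.random.default_rng(rng_seed)

    n_samp = int(round(schedule.duration_s() * sfreq))
    t = np.arange(n_samp) / sfreq
    n_scalp = len(montage.scalp)
    coords = montage.coords()

    data = _one_over_f_noise(
        rng, n_scalp, n_samp, sfreq,
        sim.background_sd_uv * profile.noise_scale, sim.one_over_f_exponent,
    )

    # region sources: one per (region-class, hemisphere, band), projected
    # through a Gaussian spatial footprint centered on the ROI centroid
    band_specs = {
        "mu": (sim.mu_center_hz, sim.mu_bandwidth_hz),
        "beta": (sim.beta_center_hz, sim.beta_bandwidth_hz),
    }
    go = schedule.go_times_s
    onsets = schedule.onsets_s
    weights_all, sources_all = [], []
    for roi_name, electrodes in DEFAULT_ROIS.items():
        region = roi_name.split("_")[0]
        center = montage.coords(list(electrodes)).mean(axis=0)
        d2 = np.sum((coords - center) ** 2, axis=1)
        weights = np.exp(-d2 / (2 * sim.footprint_sigma**2)).astype(np.float32)
        for band, (fc, bw) in band_specs.items():
            src = _bandlimited_noise(rng, n_samp, sfreq, fc, bw, sim.source_sd_uv)
            segments = []
            for i in range(schedule.n_trials):
                p = erd.get(band, region, schedule.conditions[i])
                depth = p.depth
                if band == "beta" and region == "fc" and schedule.conditions[i] == "vocal":
                    depth = min(depth + profile.beta_humanness_effect, 0.95)
                segments.append((onsets[i] + p.onset_s, go[i], depth, p.ramp_s))
                pp = erd.get(band, region, "production")
                segments.append(
                    (go[i] + pp.onset_s, go[i] + schedule.production_window_s,
                     pp.depth, pp.ramp_s)
                )
            env = _modulation_envelope(t, segments)
            weights_all.append(weights)
            sources_all.append((src * env).astype(np.float32))
    # single projection: channels x sources @ sources x samples
    data += np.stack(weights_all, axis=1) @ np.stack(sources_all, axis=0)

    # mastoids: reference-site activity (no task modulation)
    mastoid = rng.standard_normal((2, n_samp), dtype=np.float32) * np.float32(sim.mastoid_sd_uv)
    # a common-mode signal shared by all channels; removed by re-referencing
    common = _bandlimited_noise(rng, n_samp, sfreq, 6.0, 8.0, 2.0).astype(np.float32)
    data += common
    mastoid += common

    # EMG: broadband background plus 10-100 Hz bursts in production windows
    sos = signal.butter(4, [10.0, 100.0], btype="bandpass", fs=sfreq, output="sos")
    emg = rng.standard_normal(n_samp, dtype=np.float32) * np.float32(sim.emg_background_sd_uv)
    burst_env = _modulation_envelope(
        t, [(g + 0.3, g + schedule.production_window_s, -1.0, 0.2) for g in go],
        floor=0.0,
    ) - 1.0
    emg += (signal.sosfiltfilt(sos, rng.standard_normal(n_samp, dtype=np.float32))
            * np.float32(sim.emg_burst_sd_uv) * burst_env)

    if artifacts:
        _add_blinks(rng, data, t, coords, sim, sfreq)
        _add_spikes(rng, data, schedule, sim, sfreq, n_samp)

    full = np.vstack([data, mastoid, emg[None, :]]).astype(np.float32)
    events = []
    for i in range(schedule.n_trials):
        events.append(Event(float(onsets[i]), f"stim_{schedule.conditions[i]}", i))
        events.append(Event(float(go[i]), "go", i))
    return RawRecording(
        data=full, ch_names=montage.all_channels, sfreq=sfreq, events=events
    )


def _add_blinks(rng, data, t, coords, sim, sfreq):
    """Poisson blink events: smooth <4 Hz frontal deflections."""
    duration = t[-1]
    n_blinks = rng.poisson(sim.blink_rate_hz * duration)
    n_tpl = int(sim.blink_dur_s * sfreq)
    template = np.hanning(n_tpl) ** 2
    front = np.array([0.0, 1.05])
    d2 = np.sum((coords - front) ** 2, axis=1)
    w = np.exp(-d2 / (2 * 0.45**2))
    times = rng.uniform(0, duration - sim.blink_dur_s, n_blinks)
    for bt in times:
        i0 = int(bt * sfreq)
        amp = sim.blink_amp_uv * rng.uniform(0.7, 1.3)
        data[:, i0:i0 + n_tpl] += np.outer(w * amp, template)


def _add_spikes(rng, data, schedule, sim, sfreq, n_samp):
    """Rare extreme-amplitude excursions inside epoch windows."""
    windows = []
    for i in range(schedule.n_trials):
        windows.append((schedule.onsets_s[i] - 1.0, schedule.onsets_s[i] + 5.0))
        windows.append((schedule.go_times_s[i] - 1.0, schedule.go_times_s[i] + 6.0))
    n_tpl = int(0.05 * sfreq)
    template = np.hanning(n_tpl)
    for w0, w1 in windows:
        if rng.random() >= sim.spike_epoch_rate:
            continue
        ch = rng.integers(0, data.shape[0])
        st = rng.uniform(w0 + 0.1, w1 - 0.2)
        i0 = int(st * sfreq)
        if i0 + n_tpl > n_samp:
            continue
        amp = rng.uniform(*sim.spike_amp_uv) * rng.choice([-1.0, 1.0])
        data[ch, i0:i0 + n_tpl] += amp * template


# ---------------------------------------------------------------------------
# sung responses

def simulate_sung_response(
    profile: ParticipantProfile,
    target: Melody,
    rng_seed=0,
    inaccuracy_cents: float | None = None,
    note_dur_s: float = 0.738,
    hop_ms: float = 10.0,
    frame_noise_cents: float = 0.5,
) -> F0Track:
    """Generate a 5-note f0 contour imitating ``target``.

    Per-note pitch errors are i.i.d. Gaussian in cents with SD
    ``m * sqrt(pi) / 2`` where ``m`` is the participant's target mean
    absolute interval deviation, so the produced-interval errors (pairwise
    differences) have mean absolute value converging to ``m``.  A global
    transposition offset (+-100 cents) is added; it does not affect
    interval-based scoring.
    """
    m = inaccuracy_cents if inaccuracy_cents is not None else profile.vocal_inaccuracy_cents
    rng = np.random.default_rng(rng_seed)
    sigma = m * np.sqrt(np.pi) / 2.0
    note_err = rng.normal(0.0, sigma, len(target.pitches))
    transpose = rng.uniform(-100.0, 100.0)
    hop = hop_ms * 1e-3
    times, f0s, bounds = [], [], []
    for i, p in enumerate(target.pitches):
        s, e = i * note_dur_s, (i + 1) * note_dur_s
        bounds.append((s, e))
        ft = np.arange(s + hop, e - hop / 2, hop)
        hz = semitone_to_hz(p) * 2.0 ** (
            (transpose + note_err[i] + rng.normal(0, frame_noise_cents, len(ft))) / 1200.0
        )
        times.extend(ft)
        f0s.extend(hz)
    times = np.asarray(times)
    f0s = np.asarray(f0s)
    return F0Track(
        times=times, f0=f0s, voiced=np.ones(len(times), bool), note_boundaries=bounds
    )
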