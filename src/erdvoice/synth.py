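"""Audio synthesis of melodic stimuli.

Two renditions are produced for each melody:

* a *non-vocal* timbre: a band-limited triangle wave (odd partials k in
  {1, 3, 5, 7} with amplitudes 1/k^2 and alternating sign), chosen over an
  instrument timbre so listeners bring no instrument-specific motor practice
  to it;
* a *vocal-like* timbre: the same additive core driven cycle-by-cycle with
  period jitter, amplitude shimmer and a slow Ornstein–Uhlenbeck drift of
  log-f0, calibrated to the acoustic descriptors of recorded sung stimuli
  (jitter 0.29%, shimmer 1.35%, f0 SD 8.5 cents, median note 0.738 s).
  This is a synthetic stand-in for sung recordings, not a voice model.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .melody import Melody, semitone_to_hz

DEFAULT_SR = 44100
TRIANGLE_NOTE_DUR_S = 0.750
ENV_RISE_FALL_MS = 5.0

#: target RMS (full scale) used by intensity normalization
TARGET_RMS = 0.1


@dataclass
class AudioClip:
    """Mono audio with note boundaries.

    ``note_boundaries`` is a list of (start_s, end_s) per note, aligned with
    the melody's pitches.
    """

    samples: np.ndarray
    sample_rate: int = DEFAULT_SR
    note_boundaries: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class PerturbationParams:
    """Cycle-level perturbation of the vocal-like synthesis.

    Defaults are the measured descriptors of the sung stimuli the vocal-like
    timbre emulates.
    """

    jitter_pct: float = 0.29
    shimmer_pct: float = 1.35
    f0_sd_cents: float = 8.5
    note_dur_s: float = 0.738

    def __post_init__(self):
        for name in ("jitter_pct", "shimmer_pct", "f0_sd_cents", "note_dur_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _triangle_partials(n_partials: int):
    """(harmonic numbers, signed amplitudes) of a band-limited triangle."""
    k = 2 * np.arange(n_partials) + 1  # 1, 3, 5, 7, ...
    amp = (-1.0) ** np.arange(n_partials) / k.astype(float) ** 2
    return k, amp


def _env(n: int, sr: int, env_ms: float) -> np.ndarray:
    """Linear rise/fall envelope."""
    ramp = max(1, int(round(env_ms * 1e-3 * sr)))
    env = np.ones(n)
    ramp = min(ramp, n // 2)
    env[:ramp] = np.linspace(0.0, 1.0, ramp, endpoint=False)
    env[n - ramp:] = np.linspace(1.0, 0.0, ramp)
    return env


def synth_triangle(
    m: Melody,
    sr: int = DEFAULT_SR,
    note_dur: float = TRIANGLE_NOTE_DUR_S,
    n_partials: int = 4,
    env_ms: float = ENV_RISE_FALL_MS,
) -> AudioClip:
    """Render a melody with the band-limited triangle timbre.

    Each note is the additive sum of ``n_partials`` odd partials with
    strictly decreasing amplitude, a linear ``env_ms`` rise/fall ramp and
    exactly ``note_dur`` seconds of audio; the clip is peak-normalized.
    Deterministic: identical inputs give identical samples.
    """
    if len(m.pitches) == 0:
        raise ValueError("cannot synthesize an empty melody")
    k, amp = _triangle_partials(n_partials)
    freqs = np.asarray(m.frequencies_hz)
    if freqs.max() * k.max() >= sr / 2:
        raise ValueError("highest partial would alias (f * k >= sr/2)")

    n_note = int(round(note_dur * sr))
    t = np.arange(n_note) / sr
    env = _env(n_note, sr, env_ms)
    notes, bounds = [], []
    for i, f in enumerate(freqs):
        wave = np.zeros(n_note)
        for kk, aa in zip(k, amp):
            wave += aa * np.sin(2 * np.pi * kk * f * t)
        notes.append(wave * env)
        bounds.append((i * note_dur, (i + 1) * note_dur))
    samples = np.concatenate(notes)
    samples /= np.max(np.abs(samples))
    return AudioClip(samples=samples, sample_rate=sr, note_boundaries=bounds)


def synth_vocal_like(
    m: Melody,
    p: PerturbationParams = PerturbationParams(),
    rng_seed=0,
    sr: int = DEFAULT_SR,
    n_partials: int = 4,
    env_ms: float = ENV_RISE_FALL_MS,
    drift_tau_cycles: float = 20.0,
) -> AudioClip:
    """Render a melody with cycle-level vocal-like perturbations.

    Synthesis is phase-accumulated cycle by cycle: cycle ``i`` of a note has
    period ``T0 * drift_i * (1 + sigma_j * eps_i)`` and peak amplitude
    ``1 + sigma_s * eta_i``, where ``drift`` is an Ornstein–Uhlenbeck process
    on log-f0 with stationary SD ``f0_sd_cents`` and correlation time
    ``drift_tau_cycles`` cycles.  ``sigma_j`` and ``sigma_s`` are set so the
    *measured* local jitter/shimmer (mean absolute consecutive difference
    over mean) match ``jitter_pct`` / ``shimmer_pct``: for i.i.d. Gaussian
    perturbations E|x_i - x_{i-1}| = 2 sigma / sqrt(pi).
    """
    if len(m.pitches) == 0:
        raise ValueError("cannot synthesize an empty melody")
    rng = np.random.default_rng(rng_seed)
    k, amp = _triangle_partials(n_partials)
    freqs = np.asarray(m.frequencies_hz)
    if freqs.max() * k.max() >= sr / 2:
        raise ValueError("highest partial would alias (f * k >= sr/2)")

    sigma_j = (p.jitter_pct / 100.0) * np.sqrt(np.pi) / 2.0
    sigma_s = (p.shimmer_pct / 100.0) * np.sqrt(np.pi) / 2.0
    a = np.exp(-1.0 / drift_tau_cycles)
    drift_innov_sd = (p.f0_sd_cents / 1200.0) * np.log(2) * np.sqrt(1 - a**2)

    notes, bounds = [], []
    t_cursor = 0.0
    for f0 in freqs:
        n_cycles = max(3, int(np.ceil(p.note_dur_s * f0)) + 1)
        # OU log-f0 drift (natural log units), stationary start
        logf = np.empty(n_cycles)
        logf[0] = rng.normal(0.0, (p.f0_sd_cents / 1200.0) * np.log(2)) if p.f0_sd_cents > 0 else 0.0
        for i in range(1, n_cycles):
            logf[i] = a * logf[i - 1] + rng.normal(0.0, drift_innov_sd) if drift_innov_sd > 0 else a * logf[i - 1]
        periods = (1.0 / (f0 * np.exp(logf))) * (1.0 + sigma_j * rng.standard_normal(n_cycles))
        amps = 1.0 + sigma_s * rng.standard_normal(n_cycles)

        # cut the cycle sequence to the requested note duration
        cum = np.cumsum(periods)
        n_keep = int(np.searchsorted(cum, p.note_dur_s)) + 1
        periods, amps = periods[:n_keep], amps[:n_keep]

        # phase-accumulated rendering: phase advances by 1/T per second
        n_note = int(round(periods.sum() * sr))
        tt = np.arange(n_note) / sr
        cyc_start = np.concatenate([[0.0], np.cumsum(periods)])
        idx = np.clip(np.searchsorted(cyc_start, tt, side="right") - 1, 0, len(periods) - 1)
        phase = idx + (tt - cyc_start[idx]) / periods[idx]
        wave = np.zeros(n_note)
        for kk, aa in zip(k, amp):
            wave += aa * np.sin(2 * np.pi * kk * phase)
        wave *= amps[idx] * _env(n_note, sr, env_ms)
        notes.append(wave)
        bounds.append((t_cursor, t_cursor + n_note / sr))
        t_cursor += n_note / sr
    samples = np.concatenate(notes)
    samples /= np.max(np.abs(samples))
    return AudioClip(samples=samples, sample_rate=sr, note_boundaries=bounds)


def normalize_intensity(clips: list) -> list:
    """Equalize RMS across clips (target 0.1 full scale).

    Relative within-clip dynamics are preserved (a single gain per clip).
    """
    if not clips:
        raise ValueError("no clips to normalize")
    out = []
    for c in clips:
        r = c.rms()
        if r == 0:
            raise ValueError("cannot normalize an all-zero clip")
        out.append(
            AudioClip(
                samples=c.samples * (TARGET_RMS / r),
                sample_rate=c.sample_rate,
                note_boundaries=list(c.note_boundaries),
            )
        )
    return out


def write_wav(clip: AudioClip, path, melody: Melody | None = None) -> None:
    """Write a clip as 32-bit float WAV plus a note-boundary CSV sidecar."""
    path = Path(path)
    wavfile.write(path, clip.sample_rate, clip.samples.astype(np.float32))
    side = path.with_suffix(".notes.csv")
    with open(side, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["note_index", "start_s", "end_s", "target_semitone"])
        for i, (s, e) in enumerate(clip.note_boundaries):
            tgt = melody.pitches[i] if melody is not None else ""
            w.writerow([i, f"{s:.6f}", f"{e:.6f}", tgt])


def read_wav(path) -> AudioClip:
    """Read a mono WAV (int or float) and its boundary sidecar if present."""
    path = Path(path)
    sr, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    bounds = []
    side = path.with_suffix(".notes.csv")
    if side.exists():
        with open(side) as fh:
            for row in csv.DictReader(fh):
                bounds.append((float(row["start_s"]), float(row["end_s"])))
    return AudioClip(samples=np.asarray(data, float), sample_rate=int(sr), note_boundaries=bounds)
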