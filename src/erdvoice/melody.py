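"""Melodic stimulus construction.

Melodies are short isochronous pitch sequences used as imitation models:
five notes drawn pseudo-randomly within a singer's comfortable range
(tessitura), with adjacent intervals capped at 10 semitones and a bias
toward small intervals, as is typical of song repertoire.

Pitches are integer (or fractional) semitone offsets relative to C4 = 0,
equal temperament, A4 = 440 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Hz, equal temperament with A4 = 440 (C4 = 440 * 2**(-9/12))
C4_HZ = 440.0 * 2.0 ** (-9.0 / 12.0)

#: semitone offsets from C4 for the two tessituras (inclusive ranges)
TESSITURA_RANGES = {
    "female": (-5, 7),   # G3 .. G4
    "male": (-12, 0),    # C3 .. C4
}

MALE_TRANSPOSITION = -7  # semitones, female -> male


def semitone_to_hz(semitones: float | np.ndarray) -> float | np.ndarray:
    """Frequency of a pitch given as semitones relative to C4."""
    return C4_HZ * 2.0 ** (np.asarray(semitones, dtype=float) / 12.0)


def hz_to_semitone(hz: float | np.ndarray) -> float | np.ndarray:
    """Semitones relative to C4 for a frequency in Hz."""
    return 12.0 * np.log2(np.asarray(hz, dtype=float) / C4_HZ)


@dataclass(frozen=True)
class Melody:
    """An ordered pitch sequence with its tessitura tag.

    Attributes
    ----------
    pitches : tuple of float
        Semitone values relative to C4 = 0.
    tessitura : str
        ``"female"`` (G3–G4) or ``"male"`` (C3–C4).
    id : str
        Opaque label used in filenames and score tables.
    """

    pitches: tuple
    tessitura: str
    id: str = ""

    def __post_init__(self):
        if self.tessitura not in TESSITURA_RANGES:
            raise ValueError(f"unknown tessitura {self.tessitura!r}")
        object.__setattr__(self, "pitches", tuple(float(p) for p in self.pitches))

    @property
    def intervals(self) -> tuple:
        """Adjacent intervals in semitones (length = len(pitches) - 1)."""
        p = np.asarray(self.pitches)
        return tuple(np.diff(p))

    @property
    def frequencies_hz(self) -> np.ndarray:
        return semitone_to_hz(np.asarray(self.pitches))

    def validate(self, max_interval: float = 10.0) -> None:
        lo, hi = TESSITURA_RANGES[self.tessitura]
        p = np.asarray(self.pitches)
        if p.min() < lo - 1e-9 or p.max() > hi + 1e-9:
            raise ValueError(f"pitches outside {self.tessitura} range [{lo}, {hi}]")
        if len(p) and np.max(np.abs(np.diff(p)), initial=0.0) > max_interval + 1e-9:
            raise ValueError(f"interval exceeds {max_interval} semitones")


def generate_melody(
    rng_seed,
    tessitura: str = "female",
    n_notes: int = 5,
    max_interval: int = 10,
    small_interval_bias: float = 0.35,
    id: str = "",
) -> Melody:
    """Draw one melody by pseudo-random concatenation of pitches.

    Interval magnitudes follow a truncated geometric distribution on
    0..max_interval (success probability ``small_interval_bias``), favoring
    small steps over leaps; the sign is random and a step leaving the
    tessitura is rejected and redrawn.  Tone repetitions (interval 0) are
    allowed.

    Parameters
    ----------
    rng_seed : int or numpy.random.Generator
        Seed (same seed reproduces the same melody) or generator.
    tessitura : str
        ``"female"`` or ``"male"``.
    """
    if tessitura not in TESSITURA_RANGES:
        raise ValueError(f"unknown tessitura {tessitura!r}")
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    if not (0 < small_interval_bias < 1):
        raise ValueError("small_interval_bias must be in (0, 1)")
    rng = np.random.default_rng(rng_seed)
    lo, hi = TESSITURA_RANGES[tessitura]

    # truncated geometric pmf over magnitudes 0..max_interval
    mags = np.arange(max_interval + 1)
    pmf = (1 - small_interval_bias) ** mags * small_interval_bias
    pmf /= pmf.sum()

    pitches = [int(rng.integers(lo, hi + 1))]
    while len(pitches) < n_notes:
        step = int(rng.choice(mags, p=pmf))
        if step and rng.random() < 0.5:
            step = -step
        nxt = pitches[-1] + step
        if lo <= nxt <= hi:
            pitches.append(nxt)
    m = Melody(pitches=tuple(pitches), tessitura=tessitura, id=id)
    m.validate(max_interval=max_interval)
    return m


def transpose_to_male(m: Melody) -> Melody:
    """Transpose a female-tessitura melody down 7 semitones to C3–C4.

    Intervals are unchanged; transposing an already-male melody is an error.
    """
    if m.tessitura != "female":
        raise ValueError("transpose_to_male requires a female-tessitura melody")
    return Melody(
        pitches=tuple(p + MALE_TRANSPOSITION for p in m.pitches),
        tessitura="male",
        id=m.id,
    )


def generate_melody_set(n: int, rng_seed, tessitura: str = "female", **kw) -> list:
    """Generate ``n`` melodies from independent child seeds of ``rng_seed``."""
    ss = np.random.SeedSequence(rng_seed)
    return [
        generate_melody(np.random.default_rng(child), tessitura, id=f"mel{i:03d}", **kw)
        for i, child in enumerate(ss.spawn(n))
    ]
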