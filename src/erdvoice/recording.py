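"""In-memory containers for continuous and epoched EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Event:
    onset_s: float
    label: str
    trial_index: int = -1


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts.

    data has shape (n_channels, n_samples); events mark stimulus onsets and
    go signals.
    """

    data: np.ndarray
    ch_names: list
    sfreq: float
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError("data rows must match ch_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def get(self, name: str) -> np.ndarray:
        return self.data[self.channel_index(name)]

    def copy_with(self, data: np.ndarray, ch_names=None) -> "RawRecording":
        return RawRecording(
            data=data,
            ch_names=list(ch_names) if ch_names is not None else list(self.ch_names),
            sfreq=self.sfreq,
            events=list(self.events),
        )


#: rejection reason codes, in rule-evaluation order
REASONS = ("amplitude", "improbability", "kurtosis")


@dataclass
class EpochSet:
    """Epoched data: trials x channels x samples, with a rejection mask.

    ``times`` is the per-sample axis relative to the lock event; ``kept`` is
    True for surviving trials; ``reasons`` holds the first-triggered
    rejection rule per trial ("none" for kept trials, "edge" for trials
    whose window exceeded the recording bounds).
    """

    data: np.ndarray
    ch_names: list
    sfreq: float
    times: np.ndarray
    conditions: list
    lock: str = ""
    kept: np.ndarray = None
    reasons: list = None
    trial_indices: np.ndarray = None

    def __post_init__(self):
        n = self.data.shape[0]
        if self.kept is None:
            self.kept = np.ones(n, dtype=bool)
        if self.reasons is None:
            self.reasons = ["none"] * n
        if self.trial_indices is None:
            self.trial_indices = np.arange(n)
        if len(self.conditions) != n or len(self.reasons) != n or len(self.kept) != n:
            raise ValueError("per-trial metadata must match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def surviving(self) -> "EpochSet":
        """Subset of kept epochs."""
        sel = np.asarray(self.kept, bool)
        return EpochSet(
            data=self.data[sel],
            ch_names=list(self.ch_names),
            sfreq=self.sfreq,
            times=self.times,
            conditions=[c for c, k in zip(self.conditions, sel) if k],
            lock=self.lock,
            kept=np.ones(int(sel.sum()), bool),
            reasons=["none"] * int(sel.sum()),
            trial_indices=self.trial_indices[sel],
        )

    def channel_index(self, name: str) -> int:
        try:
            return self.ch_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None
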