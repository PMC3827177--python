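"""64-channel scalp montage with idealized 2-D coordinates.

Channel names follow the extended 10/20 (BioSemi-64) layout.  Coordinates
are an idealized top-view projection (x: left negative to right positive,
y: front positive to back negative, head radius ~ 1) derived from the row
and index of each label; they exist to give simulated sources smooth
spatial footprints, not to model a real head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCALP_64 = [
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7", "FC5", "FC3", "FC1",
    "C1", "C3", "C5", "T7", "TP7", "CP5", "CP3", "CP1", "P1", "P3", "P5",
    "P7", "P9", "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz", "Fpz",
    "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4", "F6", "F8", "FT8", "FC6",
    "FC4", "FC2", "FCz", "Cz", "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4",
    "CP2", "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
]

MASTOIDS = ("M1", "M2")
EMG_CHANNEL = "EMG"  # superior orbicularis (labial) electromyogram

_ROW_Y = {
    "Fp": 1.0, "AF": 0.78, "F": 0.55, "FT": 0.30, "FC": 0.30, "T": 0.0,
    "C": 0.0, "TP": -0.28, "CP": -0.28, "P": -0.55, "PO": -0.78,
    "O": -1.0, "I": -1.15,
}
_NUM_X = {1: 0.18, 2: 0.18, 3: 0.42, 4: 0.42, 5: 0.65, 6: 0.65,
          7: 0.88, 8: 0.88, 9: 1.05, 10: 1.05}


def _label_position(name: str):
    """Idealized (x, y) from a 10/20-style label."""
    if name in ("Iz",):
        return (0.0, _ROW_Y["I"])
    row = "".join(c for c in name if c.isalpha() and c != "z")
    num = "".join(c for c in name if c.isdigit())
    if name.endswith("z"):
        return (0.0, _ROW_Y[row])
    n = int(num)
    x = _NUM_X[n]
    if row in ("FT", "TP"):
        x = 0.95
    if row == "T":
        x = 1.0
    if n % 2 == 1:
        x = -x
    return (x, _ROW_Y[row])


@dataclass
class Montage:
    """Scalp channels + mastoid references + one EMG channel."""

    scalp: list = field(default_factory=lambda: list(SCALP_64))
    mastoids: tuple = MASTOIDS
    emg: str = EMG_CHANNEL

    def __post_init__(self):
        names = self.all_channels
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        self.positions = {ch: _label_position(ch) for ch in self.scalp}
        self.positions[self.mastoids[0]] = (-1.05, -0.95)
        self.positions[self.mastoids[1]] = (1.05, -0.95)

    @property
    def all_channels(self) -> list:
        return self.scalp + list(self.mastoids) + [self.emg]

    def require(self, channels) -> None:
        missing = [c for c in channels if c not in self.scalp]
        if missing:
            raise ValueError(f"montage is missing channels: {missing}")

    def coords(self, channels=None) -> np.ndarray:
        channels = channels if channels is not None else self.scalp
        return np.array([self.positions[c] for c in channels])


#: the six analysis regions: electrode triplets per hemisphere
DEFAULT_ROIS = {
    "fc_l": ("F1", "F3", "FC1"),
    "fc_r": ("F2", "F4", "FC2"),
    "cp_l": ("C1", "C3", "CP1"),
    "cp_r": ("C2", "C4", "CP2"),
    "po_l": ("PO3", "PO7", "O1"),
    "po_r": ("PO4", "PO8", "O2"),
}

#: six-electrode fronto-central set used for the time-course analysis
FRONTOCENTRAL_6 = ("F1", "F2", "F3", "F4", "FC1", "FC2")


def default_montage() -> Montage:
    m = Montage()
    m.require([e for roi in DEFAULT_ROIS.values() for e in roi])
    return m
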