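"""Minimal European Data Format (EDF) I/O for continuous recordings.

Writes standard 16-bit EDF with one-second data records and a per-channel
physical range taken from the data; events travel in a CSV sidecar
(columns ``onset_s, label, trial_index``) so they round-trip exactly.
The reader parses the same subset of the format; files are also readable
by standard EDF tools.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .recording import Event, RawRecording

def _pad(s: str, n: int) -> bytes:
    b = str(s)[:n].encode("ascii")
    return b + b" " * (n - len(b))


def write_edf(raw: RawRecording, path, events_path=None, patient_id="X", recording_id="synthetic") -> None:
    """Write a recording as 16-bit EDF (1 s records; trailing partial
    record is dropped) plus an event CSV sidecar."""
    path = Path(path)
    sfreq = raw.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per record per channel
    n_rec = raw.n_samples // spr
    n_ch = len(raw.ch_names)
    data = np.asarray(raw.data[:, : n_rec * spr], np.float64)

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(patient_id, 80))
        fh.write(_pad(recording_id, 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 + 256 * n_ch), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))          # record duration, s
        fh.write(_pad(str(n_ch), 4))
        for ch in raw.ch_names:
            fh.write(_pad(ch, 16))
        for _ in raw.ch_names:
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in raw.ch_names:
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        fh.write(_pad(str(dig_min), 8) * n_ch)
        fh.write(_pad(str(dig_max), 8) * n_ch)
        fh.write(_pad("HP:1Hz", 80) * n_ch)
        fh.write(_pad(str(spr), 8) * n_ch)
        fh.write(_pad("", 32) * n_ch)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())

    ev_path = Path(events_path) if events_path else path.with_suffix(".events.csv")
    write_events_csv(raw.events, ev_path)


def read_edf(path, events_path=None) -> RawRecording:
    """Read an EDF file written by :func:`write_edf` (or compatible)."""
    path = Path(path)
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_rec = int(hdr[236:244].decode().strip())
        rec_dur = float(hdr[244:252].decode().strip())
        n_ch = int(hdr[252:256].decode().strip())
        chdr = fh.read(256 * n_ch)

        # channel header layout: label16 transducer80 dim8 pmin8 pmax8
        #                        dmin8 dmax8 prefilt80 spr8 reserved32
        off = 0
        def take(width):
            nonlocal off
            out = [
                chdr[off + i * width: off + (i + 1) * width].decode().strip()
                for i in range(n_ch)
            ]
            off += width * n_ch
            return out

        labels = take(16)
        take(80)
        take(8)
        pmin = np.array([float(v) for v in take(8)])
        pmax = np.array([float(v) for v in take(8)])
        dmin = np.array([float(v) for v in take(8)])
        dmax = np.array([float(v) for v in take(8)])
        take(80)
        spr = np.array([int(v) for v in take(8)])
        take(32)

        if len(set(spr)) != 1:
            raise ValueError("mixed samples-per-record not supported")
        spr0 = int(spr[0])
        body = np.frombuffer(fh.read(n_rec * n_ch * spr0 * 2), dtype="<i2")
    body = body.reshape(n_rec, n_ch, spr0)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (body.transpose(1, 0, 2).reshape(n_ch, -1) - dmin[:, None]) * gain[:, None] + pmin[:, None]
    sfreq = spr0 / rec_dur

    ev_path = Path(events_path) if events_path else path.with_suffix(".events.csv")
    events = read_events_csv(ev_path) if ev_path.exists() else []
    return RawRecording(
        data=data.astype(np.float32), ch_names=labels, sfreq=sfreq, events=events
    )


def write_events_csv(events, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["onset_s", "label", "trial_index"])
        for ev in events:
            w.writerow([repr(float(ev.onset_s)), ev.label, ev.trial_index])


def read_events_csv(path) -> list:
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out.append(Event(float(row["onset_s"]), row["label"], int(row["trial_index"])))
    return out
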