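"""ECG record I/O and episode slicing.

Reads single-channel ECG from plain CSV files or WFDB-style records
(header + signal formats 16 and 212, MIT annotation files), and slices a
record into overlapping fixed-length decision frames ("episodes") on which
the sequential classifier operates.

The WFDB reader here is deliberately minimal: enough to ingest records laid
out like the MIT-BIH / Creighton University arrhythmia databases (one or two
signal channels, formats 16 or 212, optional rhythm annotations).
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .sequential_classifier import RhythmLabel

__all__ = [
    "EcgRecord",
    "Episode",
    "read_record",
    "write_record",
    "slice_episodes",
    "DEFAULT_RHYTHM_MAP",
]


# WFDB-style rhythm annotation strings -> coarse truth class used when
# labelling episodes.  "vf"/"vt" feed the positive classes; "noise" marks
# episodes to exclude; everything else is nonVTVF.
DEFAULT_RHYTHM_MAP = {
    "(VF": "vf",
    "(VFL": "vf",
    "(VFIB": "vf",
    "(VT": "vt",
    "(NOISE": "noise",
    "(N": "other",
    "(NSR": "other",
    "(AFIB": "other",
    "(B": "other",
    "(SVTA": "other",
    "(BI": "other",
    "(HGEA": "other",
    "(PM": "other",
    "(SBR": "other",
}


@dataclass
class EcgRecord:
    """A raw sampled single-channel ECG trace.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in record units (ADC units unless already calibrated).
    fs : float
        Sampling frequency, samples/s.
    gain : float, optional
        Calibration in record units per microvolt. ``None`` means the
        physical amplitude is unknown and the coarse/fine VF split is
        unavailable downstream.
    channel_id : str
        Free-text channel name.
    annotations : list of (time_s, code)
        Rhythm/beat marks; times are seconds from the start of the record.
    """

    samples: np.ndarray
    fs: float
    gain: Optional[float] = None
    channel_id: str = ""
    annotations: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("EcgRecord requires at least one sample")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if self.gain is not None and self.gain <= 0:
            raise ValueError(f"gain must be positive, got {self.gain}")
        for t, _code in self.annotations:
            if not (0.0 <= t <= self.duration):
                raise ValueError(
                    f"annotation at t={t:.3f}s lies outside [0, {self.duration:.3f}]"
                )

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs


@dataclass
class Episode:
    """An ``le``-second decision frame sliced out of a record.

    One classification decision is made per episode.  ``le`` must be at
    least 2 s because both discrimination indices operate on 2-s analysis
    windows inside the episode.
    """

    samples: np.ndarray
    fs: float
    le: int
    start_time: float = 0.0
    truth_label: Optional[RhythmLabel] = None
    gain: Optional[float] = None
    excluded: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.le < 2:
            raise ValueError(f"episode length must be >= 2 s, got {self.le}")
        expected = int(np.floor(self.le * self.fs))
        if abs(self.samples.size - expected) > 1:
            raise ValueError(
                f"episode has {self.samples.size} samples, expected "
                f"{expected} for le={self.le}s at fs={self.fs}"
            )


def read_record(
    path,
    format: str = "csv",
    fs_override: Optional[float] = None,
    gain_override: Optional[float] = None,
    channel: int = 0,
) -> EcgRecord:
    """Read an ECG record from disk.

    ``format="csv"`` expects one sample per row (optionally ``time,value``
    pairs; optional header row); the sampling rate is never inferred from a
    CSV and ``fs_override`` is mandatory.  ``format="wfdb"`` reads the
    header for fs and gain, the signal file (formats 16 and 212), and a
    ``.atr`` annotation file when present.
    """
    path = Path(path)
    if format == "csv":
        if fs_override is None:
            raise ValueError("fs_override is required for csv records")
        samples = _read_csv_samples(path)
        return EcgRecord(samples=samples, fs=fs_override, gain=gain_override,
                         channel_id=path.stem)
    if format == "wfdb":
        rec = _read_wfdb(path, channel=channel)
        if fs_override is not None:
            rec.fs = fs_override
        if gain_override is not None:
            rec.gain = gain_override
        return rec
    raise ValueError(f"unknown record format: {format!r}")


def write_record(record: EcgRecord, path) -> None:
    """Write samples as a single-column CSV (one sample per row)."""
    np.savetxt(path, record.samples, fmt="%.12g")


def _read_csv_samples(path: Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.replace("\t", ",").split(",")
            token = fields[-1].strip()  # value column is last
            try:
                values.append(float(token))
            except ValueError:
                if lineno == 1:  # tolerate a single header row
                    continue
                raise ValueError(
                    f"{path}: non-numeric sample {token!r} on line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    return np.asarray(values, dtype=float)


# ---------------------------------------------------------------------------
# Minimal WFDB support (header + formats 16/212 + MIT annotations)
# ---------------------------------------------------------------------------

def _parse_header(hea_path: Path):
    lines = [ln.strip() for ln in hea_path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    rec_fields = lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else None
    signals = []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fname, fmt = f[0], f[1]
        # gain spec may look like "200", "200(0)/mV", "200/mV"
        gain_tok = f[2] if len(f) > 2 else "200"
        gain_tok = gain_tok.split("/")[0].split("(")[0]
        gain_per_mv = float(gain_tok) if float(gain_tok) != 0 else 200.0
        desc = " ".join(f[8:]) if len(f) > 8 else fname
        signals.append({
            "file": fname,
            "fmt": int(fmt.split("x")[0].split(":")[0].split("+")[0]),
            "gain_per_mv": gain_per_mv,
            "baseline": 0,
            "desc": desc,
        })
    return fs, n_samp, signals


def _read_signal_16(path: Path, n_sig: int) -> np.ndarray:
    raw = np.fromfile(path, dtype="<i2")
    raw = raw[: (raw.size // n_sig) * n_sig]
    return raw.reshape(-1, n_sig).astype(float)


def _read_signal_212(path: Path, n_sig: int) -> np.ndarray:
    """Format 212: two 12-bit samples packed into 3 bytes."""
    raw = np.fromfile(path, dtype=np.uint8)
    raw = raw[: (raw.size // 3) * 3].reshape(-1, 3)
    s1 = (raw[:, 0].astype(np.int32) | ((raw[:, 1].astype(np.int32) & 0x0F) << 8))
    s2 = (raw[:, 2].astype(np.int32) | ((raw[:, 1].astype(np.int32) & 0xF0) << 4))
    # sign-extend 12-bit two's complement
    s1[s1 > 2047] -= 4096
    s2[s2 > 2047] -= 4096
    flat = np.empty(raw.shape[0] * 2, dtype=float)
    flat[0::2] = s1
    flat[1::2] = s2
    flat = flat[: (flat.size // n_sig) * n_sig]
    return flat.reshape(-1, n_sig)


def _read_annotations(atr_path: Path, fs: float) -> list:
    """Decode a MIT-format annotation file into (time_s, mnemonic) pairs.

    Rhythm changes are reported with their aux string (e.g. ``(VT``);
    ordinary beat annotations are reported with a one-letter mnemonic.
    """
    data = atr_path.read_bytes()
    out = []
    t = 0
    i = 0
    beat_codes = {1: "N", 2: "L", 3: "R", 4: "a", 5: "V", 6: "F", 7: "J",
                  8: "A", 9: "S", 10: "E", 11: "j", 12: "/", 13: "Q",
                  34: "f", 38: "!", 31: "["}
    while i + 1 < len(data):
        lo, hi = data[i], data[i + 1]
        i += 2
        code = hi >> 2
        interval = ((hi & 0x03) << 8) | lo
        if code == 0 and interval == 0:
            break  # end of file
        if code == 59:  # SKIP: next 4 bytes are a long interval
            if i + 3 < len(data):
                t += struct.unpack("<i", bytes([data[i + 2], data[i + 3],
                                                data[i], data[i + 1]]))[0]
            i += 4
            continue
        if code == 63:  # AUX: interval = byte count of aux string
            n = interval
            aux = data[i : i + n].split(b"\x00")[0].decode("ascii", "replace")
            i += n + (n % 2)
            if out:  # aux string qualifies the preceding mark (rhythm label)
                out[-1] = (out[-1][0], aux)
            continue
        if code in (60, 61, 62):  # NUM / SUB / CHN modifiers
            continue
        t += interval
        out.append((t / fs, beat_codes.get(code, f"#{code}")))
    return out


def _read_wfdb(path: Path, channel: int = 0) -> EcgRecord:
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"WFDB header not found: {hea}")
    fs, n_samp, signals = _parse_header(hea)
    if channel >= len(signals):
        raise ValueError(f"record has {len(signals)} channels, asked for {channel}")
    sig_file = hea.parent / signals[channel]["file"]
    fmt = signals[channel]["fmt"]
    if fmt == 212:
        matrix = _read_signal_212(sig_file, len(signals))
    elif fmt == 16:
        matrix = _read_signal_16(sig_file, len(signals))
    else:
        raise ValueError(f"unsupported WFDB signal format {fmt}")
    samples = matrix[:, channel]
    if n_samp is not None:
        samples = samples[:n_samp]
    atr = hea.with_suffix(".atr")
    annotations = _read_annotations(atr, fs) if atr.exists() else []
    # WFDB gain is ADC units per mV; EcgRecord wants units per uV
    gain_uv = signals[channel]["gain_per_mv"] / 1000.0
    return EcgRecord(samples=samples, fs=fs, gain=gain_uv,
                     channel_id=signals[channel]["desc"], annotations=annotations)


# ---------------------------------------------------------------------------
# Episode slicing
# ---------------------------------------------------------------------------

def _truth_from_annotations(record: EcgRecord, start: float, le: float,
                            rhythm_map: dict) -> tuple:
    """Majority-rule truth class for [start, start+le), plus a noise flag.

    Rhythm annotations are step functions: the class in force at time t is
    the last rhythm mark at or before t. The class covering >50% of the
    episode wins; ties go to the class at the episode midpoint.
    """
    marks = [(t, rhythm_map[c]) for t, c in record.annotations if c in rhythm_map]
    if not marks:
        return None, False
    marks.sort()
    end = start + le
    # build the piecewise-constant class over the episode
    current = None
    for t, cls in marks:
        if t <= start:
            current = cls
        else:
            break
    bounds = [start] + [t for t, _ in marks if start < t < end] + [end]
    cls_at = current
    idx = 0
    cover = {}
    for a, b in zip(bounds[:-1], bounds[1:]):
        while idx < len(marks) and marks[idx][0] <= a:
            cls_at = marks[idx][1]
            idx += 1
        if cls_at is not None:
            cover[cls_at] = cover.get(cls_at, 0.0) + (b - a)
    noisy = cover.get("noise", 0.0) > 0.0
    cover.pop("noise", None)
    if not cover:
        return None, noisy
    best_cls, best_cov = max(cover.items(), key=lambda kv: kv[1])
    if best_cov <= le / 2.0:
        # no majority: use the class in force at the midpoint
        mid = start + le / 2.0
        cls_at = None
        for t, cls in marks:
            if t <= mid and cls != "noise":
                cls_at = cls
        best_cls = cls_at if cls_at is not None else best_cls
    label = {"vf": RhythmLabel.COARSE_VF, "vt": RhythmLabel.VT_LO,
             "other": RhythmLabel.NON_VTVF}.get(best_cls)
    return label, noisy


def slice_episodes(
    record: EcgRecord,
    le: int = 8,
    step: int = 1,
    rhythm_map: Optional[dict] = None,
) -> list:
    """Slice a record into overlapping ``le``-second episodes at ``step``-s
    strides.

    A record of integer duration D yields D - le + 1 episodes for step=1
    (start positions at whole seconds 0, 1, ..., D-le). Episodes overlapping
    annotated noise are flagged ``excluded`` rather than dropped.
    """
    if rhythm_map is None:
        rhythm_map = DEFAULT_RHYTHM_MAP
    n = record.samples.size
    win = int(np.floor(le * record.fs))
    stride = int(np.floor(step * record.fs))
    if n < win:
        warnings.warn(
            f"record duration {record.duration:.1f}s shorter than episode "
            f"length {le}s; no episodes produced"
        )
        return []
    episodes = []
    start = 0
    while start + win <= n:
        t0 = start / record.fs
        truth, noisy = _truth_from_annotations(record, t0, le, rhythm_map)
        episodes.append(Episode(
            samples=record.samples[start : start + win],
            fs=record.fs, le=le, start_time=t0,
            truth_label=truth, gain=record.gain, excluded=noisy,
        ))
        start += stride
    return episodes
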