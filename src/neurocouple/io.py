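"""Recording container and file I/O.

The package-internal representation of any uniformly sampled multichannel
signal is :class:`MultichannelRecording`; EEG is stored in microvolts, fNIRS
chromophores in micromolar concentration change.  EEG travels as EDF (16-bit)
with a JSON sidecar carrying channel geometry and resting-state annotations;
fNIRS travels as SNIRF (HDF5).  Time is seconds from record start, sample
index 0-based, annotation spans half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import datetime
import json
import struct
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "MultichannelRecording",
    "read_eeg",
    "write_eeg",
    "read_fnirs",
    "write_fnirs",
    "crop_to_annotations",
    "resample_recording",
]

MODALITIES = ("EEG", "HbO", "HbR")


@dataclass
class MultichannelRecording:
    """A uniformly sampled multichannel time series.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal values; µV for EEG, µmol/L change for HbO/HbR.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names, one per column.
    modality : {"EEG", "HbO", "HbR"}
    channel_positions : ndarray, shape (n_channels, 3), optional
        3-D coordinates in mm.
    annotations : list of (onset_s, duration_s, label)
        Marked spans, e.g. resting-state periods.
    segments : list of (start, stop) sample indices, half-open
        Contiguity boundaries; sequence construction never crosses one.
        Defaults to the whole record.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    modality: str = "EEG"
    channel_positions: np.ndarray | None = None
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    segments: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [time points x channels]")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        labels = list(self.channel_labels)
        if len(labels) != self.data.shape[1]:
            raise ValueError("channel label count must match data columns")
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        self.channel_labels = labels
        if self.channel_positions is not None:
            pos = np.asarray(self.channel_positions, dtype=float)
            if pos.shape != (len(labels), 3):
                raise ValueError("channel_positions must be (n_channels, 3)")
            self.channel_positions = pos
        dur = self.duration
        for onset, length, _label in self.annotations:
            if onset < -1e-9 or onset + length > dur + 1.0 / self.fs:
                raise ValueError("annotation outside the record")
        if self.segments is None:
            self.segments = [(0, self.n_samples)]

    # -- derived quantities -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self, **changes) -> "MultichannelRecording":
        """Shallow copy with field overrides (data is copied)."""
        if "data" not in changes:
            changes["data"] = self.data.copy()
        out = replace(self, **changes)
        return out

    def pick(self, labels: list[str]) -> "MultichannelRecording":
        idx = [self.channel_labels.index(l) for l in labels]
        pos = None
        if self.channel_positions is not None:
            pos = self.channel_positions[idx]
        return self.copy(
            data=self.data[:, idx], channel_labels=list(labels), channel_positions=pos
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _record_duration(fs: float) -> tuple[float, int]:
    """Smallest record duration (s) giving an integer sample count."""
    frac = Fraction(fs).limit_denominator(10_000)
    dur = Fraction(frac.denominator)
    # prefer 1 s when fs is integral
    for d in range(1, frac.denominator + 1):
        if (frac * d).denominator == 1:
            dur = Fraction(d)
            break
    n = int(frac * dur)
    return float(dur), n


def write_eeg(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write an EEG recording as 16-bit EDF plus a JSON sidecar.

    The sidecar (``<stem>.json``) carries sampling rate, exact sample count,
    channel positions and annotations, none of which plain EDF represents.
    Values are quantized to the 16-bit digital range per channel.
    """
    path = Path(path)
    if rec.modality != "EEG":
        raise ValueError("write_eeg expects an EEG recording")
    rec_dur, spr = _record_duration(rec.fs)
    n_records = int(np.ceil(rec.n_samples / spr))
    n_ch = rec.n_channels

    data = np.asarray(rec.data, dtype=float)
    phys_min = data.min(axis=0)
    phys_max = data.max(axis=0)
    # guard degenerate constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767
    gain = (dig_max - dig_min) / (phys_max - phys_min)

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field("X X X X", 80),
            _edf_field("Startdate X", 80),
            _edf_field(datetime.date(2000, 1, 1).strftime("%d.%m.%y"), 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (n_ch + 1)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field(f"{rec_dur:g}", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig = b""
    for fields, width in [
        (rec.channel_labels, 16),
        (["" for _ in range(n_ch)], 80),
        (["uV" for _ in range(n_ch)], 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([str(dig_min)] * n_ch, 8),
        ([str(dig_max)] * n_ch, 8),
        (["" for _ in range(n_ch)], 80),
        ([str(spr)] * n_ch, 8),
        (["" for _ in range(n_ch)], 32),
    ]:
        sig += b"".join(_edf_field(f, width) for f in fields)

    padded = np.zeros((n_records * spr, n_ch))
    padded[: rec.n_samples] = data
    digital = np.clip(
        np.round((padded - phys_min) * gain + dig_min), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        for r in range(n_records):
            block = digital[r * spr : (r + 1) * spr]  # (spr, n_ch)
            f.write(block.T.tobytes())

    sidecar = {
        "fs": rec.fs,
        "n_samples": rec.n_samples,
        "modality": rec.modality,
        "channel_labels": rec.channel_labels,
        "channel_positions_mm": None
        if rec.channel_positions is None
        else rec.channel_positions.tolist(),
        "annotations": [list(a) for a in rec.annotations],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def _validate_edf_size(path: Path) -> None:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"truncated EDF header in {path}")
        header_bytes = int(head[184:192].decode("ascii").strip())
        n_records = int(head[236:244].decode("ascii").strip())
        n_ch = int(head[252:256].decode("ascii").strip())
        sig = f.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError(f"truncated EDF signal headers in {path}")
        f.seek(0, 2)
        size = f.tell()
    spr_field = sig[n_ch * 216 : n_ch * 216 + 8 * n_ch]
    spr = sum(
        int(spr_field[i * 8 : (i + 1) * 8].decode("ascii").strip())
        for i in range(n_ch)
    )
    expected = header_bytes + n_records * spr * 2
    if size < expected:
        raise ValueError(
            f"truncated EDF file {path}: {size} bytes, expected {expected}"
        )


def read_eeg(path: str | Path) -> MultichannelRecording:
    """Read an EEG recording from EDF (sidecar-aware).

    Parsing is delegated to MNE; amplitudes are returned in µV regardless of
    whether the file declares µV or mV.  A truncated file raises instead of
    silently shortening the record.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_edf_size(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    units = {
        ch["ch_name"]: ch["unit"] for ch in raw.info["chs"]
    }
    data = raw.get_data().T  # SI units (V) for eeg-typed channels
    kinds = raw.get_channel_types()
    scale = np.ones(data.shape[1])
    for i, kind in enumerate(kinds):
        if kind in ("eeg", "misc"):
            scale[i] = 1e6  # V -> µV (MNE scales uV/mV dimensions to V)
        else:
            raise ValueError(f"unsupported channel unit/type: {kind}")
    data = data * scale

    labels = list(raw.ch_names)
    fs = float(raw.info["sfreq"])
    positions = None
    annotations: list[tuple[float, float, str]] = []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        data = data[: meta["n_samples"]]
        fs = float(meta["fs"])
        labels = meta["channel_labels"]
        if meta.get("channel_positions_mm") is not None:
            positions = np.asarray(meta["channel_positions_mm"], dtype=float)
        annotations = [tuple(a) for a in meta.get("annotations", [])]
    else:
        annotations = [
            (float(on), float(du), str(de))
            for on, du, de in zip(
                raw.annotations.onset, raw.annotations.duration,
                raw.annotations.description,
            )
        ]
    return MultichannelRecording(
        data=data,
        fs=fs,
        channel_labels=labels,
        modality="EEG",
        channel_positions=positions,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def write_fnirs(
    hbo: MultichannelRecording, hbr: MultichannelRecording, path: str | Path
) -> Path:
    """Write paired HbO/HbR recordings as a SNIRF (HDF5) file.

    Uses processed-concentration measurement lists (dataType 99999 with
    ``dataTypeLabel`` HbO/HbR); channel positions are stored as co-located
    source/detector pairs in mm.  Resting-state annotations become stim
    groups.
    """
    if hbo.modality != "HbO" or hbr.modality != "HbR":
        raise ValueError("write_fnirs expects (HbO, HbR) recordings")
    if hbo.data.shape != hbr.data.shape or hbo.fs != hbr.fs:
        raise ValueError("HbO and HbR must share shape and sampling rate")
    path = Path(path)
    n_ch = hbo.n_channels
    series = np.concatenate([hbo.data, hbr.data], axis=1)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=np.bytes_("1.0"))
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for key, val in [
            ("SubjectID", "synthetic"),
            ("MeasurementDate", "2000-01-01"),
            ("MeasurementTime", "00:00:00"),
            ("LengthUnit", "mm"),
            ("TimeUnit", "s"),
            ("FrequencyUnit", "Hz"),
        ]:
            meta.create_dataset(key, data=np.bytes_(val))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=series.astype(np.float64))
        d1.create_dataset("time", data=np.array([0.0, 1.0 / hbo.fs]))
        for col in range(2 * n_ch):
            ml = d1.create_group(f"measurementList{col + 1}")
            ch = col % n_ch
            ml.create_dataset("sourceIndex", data=np.int32(ch + 1))
            ml.create_dataset("detectorIndex", data=np.int32(ch + 1))
            ml.create_dataset("wavelengthIndex", data=np.int32(1))
            ml.create_dataset("dataType", data=np.int32(99999))
            ml.create_dataset("dataTypeIndex", data=np.int32(1))
            label = "HbO" if col < n_ch else "HbR"
            ml.create_dataset("dataTypeLabel", data=np.bytes_(label))
        probe = nirs.create_group("probe")
        if hbo.channel_positions is not None:
            probe.create_dataset("sourcePos3D", data=hbo.channel_positions)
            probe.create_dataset("detectorPos3D", data=hbo.channel_positions)
        probe.create_dataset("wavelengths", data=np.array([690.0, 830.0]))
        probe.create_dataset(
            "sourceLabels",
            data=np.array([np.bytes_(l) for l in hbo.channel_labels]),
        )
        for k, (onset, duration, label) in enumerate(hbo.annotations):
            stim = nirs.create_group(f"stim{k + 1}")
            stim.create_dataset("name", data=np.bytes_(label))
            stim.create_dataset(
                "data", data=np.array([[onset, duration, 1.0]])
            )
    return path


def _h5_str(node) -> str:
    v = node[()]
    if isinstance(v, bytes):
        return v.decode()
    return str(v)


def read_fnirs(path: str | Path) -> tuple[MultichannelRecording, MultichannelRecording]:
    """Read a SNIRF file into (HbO, HbR) recordings.

    Raises if either chromophore is absent or the time axis is non-uniform.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        series = np.asarray(d1["dataTimeSeries"])
        t = np.asarray(d1["time"]).ravel()
        if t.size == 2:
            fs = 1.0 / (t[1] - t[0])
        else:
            dt = np.diff(t)
            if dt.size == 0 or np.ptp(dt) > 1e-6 * dt.mean():
                raise ValueError("non-uniform SNIRF time axis")
            fs = 1.0 / dt.mean()
        cols: dict[str, list[tuple[int, int]]] = {"HbO": [], "HbR": []}
        for name in sorted(
            (k for k in d1 if k.startswith("measurementList")),
            key=lambda s: int(s[len("measurementList"):]),
        ):
            ml = d1[name]
            label = _h5_str(ml["dataTypeLabel"]) if "dataTypeLabel" in ml else ""
            src = int(ml["sourceIndex"][()])
            col = int(name[len("measurementList"):]) - 1
            if label in cols:
                cols[label].append((src, col))
        for chrom in ("HbO", "HbR"):
            if not cols[chrom]:
                raise ValueError(f"SNIRF file lacks {chrom} measurements")
        positions = None
        if "nirs/probe/sourcePos3D" in f:
            positions = np.asarray(f["nirs/probe/sourcePos3D"], dtype=float)
        if "nirs/probe/sourceLabels" in f:
            labels = [
                v.decode() if isinstance(v, bytes) else str(v)
                for v in np.asarray(f["nirs/probe/sourceLabels"]).ravel()
            ]
        else:
            labels = [f"CH{i + 1}" for i in range(len(cols["HbO"]))]
        annotations = []
        for k in sorted(k for k in f["nirs"] if k.startswith("stim")):
            stim = f["nirs"][k]
            name = _h5_str(stim["name"])
            for onset, duration, _amp in np.atleast_2d(np.asarray(stim["data"])):
                annotations.append((float(onset), float(duration), name))

    out = []
    for chrom in ("HbO", "HbR"):
        order = sorted(cols[chrom])  # by source index
        idx = [col for _src, col in order]
        out.append(
            MultichannelRecording(
                data=series[:, idx],
                fs=fs,
                channel_labels=list(labels),
                modality=chrom,
                channel_positions=positions,
                annotations=list(annotations),
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Span handling / resampling
# ---------------------------------------------------------------------------

def crop_to_annotations(
    rec: MultichannelRecording, label: str
) -> MultichannelRecording:
    """Concatenate the spans annotated with ``label``.

    The returned recording carries segment boundaries so that downstream
    sequence construction never builds a window across the junction of two
    non-contiguous spans.
    """
    spans = [
        (onset, duration)
        for onset, duration, lab in rec.annotations
        if lab == label
    ]
    if not spans:
        raise ValueError(f"no annotation labelled {label!r}")
    pieces = []
    segments = []
    cursor = 0
    new_annotations = []
    for onset, duration in sorted(spans):
        i0 = int(round(onset * rec.fs))
        i1 = int(round((onset + duration) * rec.fs))
        i1 = min(i1, rec.n_samples)
        pieces.append(rec.data[i0:i1])
        segments.append((cursor, cursor + (i1 - i0)))
        new_annotations.append((cursor / rec.fs, (i1 - i0) / rec.fs, label))
        cursor += i1 - i0
    return rec.copy(
        data=np.concatenate(pieces, axis=0),
        annotations=new_annotations,
        segments=segments,
    )


def concatenate_recordings(
    recs: list[MultichannelRecording],
) -> MultichannelRecording:
    """Join recordings end to end, preserving segment boundaries.

    All inputs must share rate, modality and channel labels.  Annotations
    are shifted onto the concatenated time base; each input's segments are
    carried over, so windowing never bridges the junctions.
    """
    if not recs:
        raise ValueError("nothing to concatenate")
    first = recs[0]
    for rec in recs[1:]:
        if (
            rec.fs != first.fs
            or rec.modality != first.modality
            or rec.channel_labels != first.channel_labels
        ):
            raise ValueError("recordings are not compatible")
    data = np.concatenate([rec.data for rec in recs], axis=0)
    segments = []
    annotations = []
    offset = 0
    for rec in recs:
        segments.extend((a + offset, b + offset) for a, b in rec.segments)
        annotations.extend(
            (onset + offset / first.fs, duration, label)
            for onset, duration, label in rec.annotations
        )
        offset += rec.n_samples
    return first.copy(
        data=data, annotations=annotations, segments=segments
    )


def resample_recording(
    rec: MultichannelRecording, fs_new: float
) -> MultichannelRecording:
    """Polyphase resampling to ``fs_new`` (exact rational rate change)."""
    from scipy.signal import resample_poly

    if abs(fs_new - rec.fs) < 1e-12:
        return rec.copy()
    ratio = Fraction(fs_new) / Fraction(rec.fs)
    ratio = ratio.limit_denominator(10_000)
    data = resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=0)
    scale = fs_new / rec.fs
    segments = [
        (int(round(a * scale)), int(round(b * scale))) for a, b in rec.segments
    ]
    segments = [(a, min(b, data.shape[0])) for a, b in segments]
    return rec.copy(data=data, fs=fs_new, segments=segments)
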