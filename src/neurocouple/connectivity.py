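"""Seed-based functional connectivity on fNIRS channels.

Given a resting-state-filtered recording, the connectivity field of a
seed channel is the Pearson correlation of the seed's time series with
every channel (Fisher z alongside).  A cross-modal variant correlates
the experimental seed with a model's predicted channels.  Fields can be
projected onto a spherical head-surface grid with inverse-cube-distance
weights, and two fields are compared by the RMSE of their channel-wise
correlation values,

    RMSE_FC = sqrt( sum_i (fc_i - fchat_i)^2 / C ).

The seed's own r = 1 entry is excluded from projection by default since
it would dominate voxels near the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MultichannelRecording
from .synthetic import ChannelGeometry

__all__ = [
    "ConnectivityField",
    "SurfaceGrid",
    "quality_filter",
    "seed_fc",
    "cross_fc",
    "project_to_surface",
    "fc_rmse",
    "make_surface_grid",
]

_R_CLIP = 1.0 - 1e-12


@dataclass
class ConnectivityField:
    """Per-channel seed correlations (r and Fisher z)."""

    seed_channel: str
    channel_labels: list[str]
    r: np.ndarray
    z: np.ndarray
    excluded_channels: list[tuple[str, str]] = field(default_factory=list)
    voxel_map: np.ndarray | None = None


@dataclass
class SurfaceGrid:
    """Quasi-uniform points on the head sphere."""

    positions: np.ndarray  # (n_voxels, 3) mm
    resolution_mm: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.resolution_mm <= 0:
            raise ValueError("resolution must be positive")


def make_surface_grid(
    head_radius: float = 85.0, resolution_mm: float = 5.0,
    superior_only: bool = True,
) -> SurfaceGrid:
    """Fibonacci-lattice surface grid at roughly ``resolution_mm`` spacing."""
    area = 4 * np.pi * head_radius**2
    n = max(8, int(np.ceil(area / resolution_mm**2)))
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.clip(1 - z**2, 0, None))
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    pts = head_radius * np.stack(
        [r * np.cos(theta), r * np.sin(theta), z], axis=1
    )
    if superior_only:
        pts = pts[pts[:, 2] > 0]
    return SurfaceGrid(positions=pts, resolution_mm=resolution_mm)


# ---------------------------------------------------------------------------

def quality_filter(
    rec: MultichannelRecording, seed_channel: str | None = None
) -> tuple[MultichannelRecording, list[tuple[str, str]]]:
    """Drop channels failing the amplitude/SNR quality gates.

    A channel is excluded if its mean absolute amplitude lies outside the
    cross-channel mean +/- 2 SD, or if its RMS is below 30 % of the
    cross-channel mean RMS.  Excluding the requested seed channel is a
    hard error.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    amp = np.mean(np.abs(rec.data), axis=0)
    rms = np.sqrt(np.mean(np.square(rec.data), axis=0))
    lo, hi = amp.mean() - 2 * amp.std(), amp.mean() + 2 * amp.std()
    excluded: list[tuple[str, str]] = []
    keep = []
    for i, label in enumerate(rec.channel_labels):
        if not lo <= amp[i] <= hi:
            excluded.append((label, "amplitude outside mean +/- 2 SD"))
        elif rms[i] < 0.30 * rms.mean():
            excluded.append((label, "RMS below 30% of mean"))
        else:
            keep.append(label)
    if seed_channel is not None and any(
        l == seed_channel for l, _ in excluded
    ):
        raise ValueError(
            f"seed channel {seed_channel!r} failed the quality filter"
        )
    return rec.pick(keep), excluded


def _pearson_with(seed_ts: np.ndarray, data: np.ndarray) -> np.ndarray:
    seed = seed_ts - seed_ts.mean()
    x = data - data.mean(axis=0)
    denom = np.sqrt(np.sum(seed**2) * np.sum(x**2, axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x.T @ seed) / denom
    return r


def _field_from_r(
    seed_channel: str, labels: list[str], r: np.ndarray
) -> ConnectivityField:
    excluded = [
        (labels[i], "zero-variance channel") for i in np.flatnonzero(~np.isfinite(r))
    ]
    r = np.clip(np.nan_to_num(r, nan=0.0), -_R_CLIP, _R_CLIP)
    return ConnectivityField(
        seed_channel=seed_channel,
        channel_labels=list(labels),
        r=r,
        z=np.arctanh(r),
        excluded_channels=excluded,
    )


def seed_fc(
    rec: MultichannelRecording, seed_channel: str
) -> ConnectivityField:
    """Pearson r (and Fisher z) of the seed channel against all channels."""
    if seed_channel not in rec.channel_labels:
        raise ValueError(f"seed channel {seed_channel!r} not in recording")
    seed_ts = rec.data[:, rec.channel_labels.index(seed_channel)]
    r = _pearson_with(seed_ts, rec.data)
    return _field_from_r(seed_channel, rec.channel_labels, r)


def cross_fc(
    experimental: MultichannelRecording,
    predicted: MultichannelRecording,
    seed_channel: str,
) -> ConnectivityField:
    """Correlate the experimental seed with every *predicted* channel."""
    if experimental.channel_labels != predicted.channel_labels:
        raise ValueError("channel labels of the two recordings must align")
    n = min(experimental.n_samples, predicted.n_samples)
    if abs(experimental.n_samples - predicted.n_samples) > 1:
        raise ValueError("recording durations differ by more than one sample")
    seed_ts = experimental.data[
        :n, experimental.channel_labels.index(seed_channel)
    ]
    r = _pearson_with(seed_ts, predicted.data[:n])
    return _field_from_r(seed_channel, predicted.channel_labels, r)


def project_to_surface(
    fc: ConnectivityField,
    geometry: ChannelGeometry,
    grid: SurfaceGrid,
    include_seed: bool = False,
    distance_floor_mm: float = 1.0,
) -> ConnectivityField:
    """Inverse-cube-distance weighted projection of r onto the grid.

    Voxel value v = sum_i w_i r_i / sum_i w_i with w_i = 1 / d_i^3 and d_i
    the voxel-to-channel Euclidean distance floored at
    ``distance_floor_mm``.  The seed's own r = 1 is left out unless
    ``include_seed``.
    """
    label_to_pos = dict(zip(geometry.fnirs_labels, geometry.fnirs_positions))
    excluded_names = {l for l, _ in fc.excluded_channels}
    sel = [
        i
        for i, l in enumerate(fc.channel_labels)
        if l not in excluded_names
        and (include_seed or l != fc.seed_channel)
    ]
    if not sel:
        raise ValueError("no channels left to project")
    missing = [fc.channel_labels[i] for i in sel
               if fc.channel_labels[i] not in label_to_pos]
    if missing:
        raise ValueError(f"no position for channel(s) {missing}")
    pos = np.array([label_to_pos[fc.channel_labels[i]] for i in sel])
    r = fc.r[sel]
    d = np.linalg.norm(
        grid.positions[:, None, :] - pos[None, :, :], axis=2
    )
    w = 1.0 / np.maximum(d, distance_floor_mm) ** 3
    voxels = (w @ r) / w.sum(axis=1)
    return ConnectivityField(
        seed_channel=fc.seed_channel,
        channel_labels=list(fc.channel_labels),
        r=fc.r.copy(),
        z=fc.z.copy(),
        excluded_channels=list(fc.excluded_channels),
        voxel_map=voxels,
    )


def fc_rmse(fc_exp: ConnectivityField, fc_pred: ConnectivityField) -> float:
    """Root mean squared channel-wise difference of two r fields."""
    if fc_exp.channel_labels != fc_pred.channel_labels:
        raise ValueError("channel sets must match")
    diff = fc_exp.r - fc_pred.r
    return float(np.sqrt(np.mean(np.square(diff))))
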