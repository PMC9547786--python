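"""Windowing of paired recordings into model-ready sequence tensors.

An *element* is one second of recording: 500 EEG samples, 20 fNIRS
samples.  A training sample is ``seq_len`` consecutive elements of EEG
paired with the fNIRS elements shifted ``shift_elems`` ahead, so the
network learns the hemodynamic lead-lag rather than having it imposed.
Windows never cross a resting-segment boundary and windows intersecting
an artifact mask are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import MultichannelRecording

__all__ = ["SequencePair", "make_sequences", "stitch_predictions"]


@dataclass
class SequencePair:
    """Aligned (EEG input, fNIRS target) window tensors.

    ``eeg`` has shape (samples, seq_len, eeg_points, n_eeg_channels) and
    ``fnirs`` (samples, seq_len, fnirs_points * n_fnirs_channels); the
    fNIRS window of sample *k* starts ``delay_elems`` seconds after the
    EEG window.  ``target_starts_s`` records where each fNIRS window sits
    in the source recording so predictions can be stitched back into a
    time series.
    """

    eeg: np.ndarray
    fnirs: np.ndarray
    delay_elems: int
    fnirs_points: int
    n_fnirs_channels: int
    target_starts_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[0]


def _elem_rate(fs: float, what: str) -> int:
    pts = int(round(fs))
    if abs(fs - pts) > 1e-9:
        raise ValueError(
            f"{what} rate {fs} Hz does not give an integer number of points "
            f"per 1-s element; resample first (e.g. 19.5 -> 20 Hz)"
        )
    return pts


def make_sequences(
    eeg: MultichannelRecording,
    fnirs: MultichannelRecording,
    seq_len: int = 10,
    shift_elems: int = 1,
    eeg_mask: np.ndarray | None = None,
    fnirs_mask: np.ndarray | None = None,
) -> SequencePair:
    """Cut paired recordings into non-overlapping sequence windows.

    Both recordings must carry the same segment structure in seconds
    (e.g. both produced by :func:`~neurocouple.io.crop_to_annotations`).
    Masks are boolean arrays over samples (1-D) or samples x channels
    (2-D) in each modality's own sampling grid; any flagged sample inside
    a window's span discards the window.
    """
    p_eeg = _elem_rate(eeg.fs, "EEG")
    p_f = _elem_rate(fnirs.fs, "fNIRS")
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")

    def _collapse(mask, n):
        if mask is None:
            return np.zeros(n, dtype=bool)
        mask = np.asarray(mask)
        return mask.any(axis=1) if mask.ndim == 2 else mask.astype(bool)

    m_eeg = _collapse(eeg_mask, eeg.n_samples)
    m_f = _collapse(fnirs_mask, fnirs.n_samples)

    seg_eeg = [(a / eeg.fs, b / eeg.fs) for a, b in eeg.segments]
    seg_f = [(a / fnirs.fs, b / fnirs.fs) for a, b in fnirs.segments]
    if len(seg_eeg) != len(seg_f) or any(
        abs(ea - fa) > 1.0 / p_f or abs(eb - fb) > 1.0 + 1.0 / p_f
        for (ea, eb), (fa, fb) in zip(seg_eeg, seg_f)
    ):
        raise ValueError("EEG and fNIRS segment structures do not match")

    xs, ys, starts = [], [], []
    for (t0, t1), (f0, _f1) in zip(seg_eeg, seg_f):
        n_elems = int(np.floor(t1 - t0 + 1e-9))
        e = 0
        while e + seq_len + shift_elems <= n_elems:
            i0 = int(round(t0 * eeg.fs)) + e * p_eeg
            j0 = int(round(f0 * fnirs.fs)) + (e + shift_elems) * p_f
            i1 = i0 + seq_len * p_eeg
            j1 = j0 + seq_len * p_f
            if not (m_eeg[i0:i1].any() or m_f[j0:j1].any()):
                xs.append(
                    eeg.data[i0:i1].reshape(seq_len, p_eeg, eeg.n_channels)
                )
                ys.append(
                    fnirs.data[j0:j1].reshape(seq_len, p_f * fnirs.n_channels)
                )
                starts.append(j0 / fnirs.fs)
            e += seq_len
    if not xs:
        raise ValueError("recording too short for a single sequence window")
    return SequencePair(
        eeg=np.stack(xs),
        fnirs=np.stack(ys),
        delay_elems=shift_elems,
        fnirs_points=p_f,
        n_fnirs_channels=fnirs.n_channels,
        target_starts_s=np.asarray(starts),
    )


def stitch_predictions(
    pair: SequencePair, pred: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble per-window predictions into a continuous channel matrix.

    Returns ``(times_s, data)`` where ``data`` is (n_samples, n_channels)
    covering exactly the fNIRS target spans of the windows, in window
    order.  With the default non-overlapping windows this is a gap-free
    time series per contiguous run of windows.
    """
    p, c = pair.fnirs_points, pair.n_fnirs_channels
    n_w, s = pred.shape[0], pred.shape[1]
    blocks = pred.reshape(n_w, s * p, c)
    data = blocks.reshape(n_w * s * p, c)
    times = np.concatenate(
        [t0 + np.arange(s * p) / fs for t0 in pair.target_starts_s]
    )
    return times, data
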