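"""Signal conditioning for the EEG/fNIRS pipeline.

EEG is broadband filtered to 0.1–100 Hz and decomposed into the five
canonical bands (delta 1–4, theta 4–8, alpha 8–12, beta 12–30,
gamma 30–100 Hz) with zero-phase windowed-sinc FIR filters.  fNIRS is
band-limited to the resting-state range 0.01–0.1 Hz (with an auxiliary
0.2 Hz low-pass for cardiac/respiratory components).  Channel rejection,
PCA motion correction, artifact masking, per-channel min-max scaling with
mean centering, and Welch spectral estimation round out the chain.

Numerical conventions: FIR design is Hamming windowed-sinc with a
transition bandwidth of 25 % of the band's lower edge (floored at 0.5 Hz),
applied forward-backward (zero phase); the slow fNIRS filters are 4th-order
Butterworth sections applied forward-backward, since an equally sharp FIR
at a 0.01 Hz edge would be longer than a typical resting record.  Edge
padding is odd reflection with a pad length capped at one sample short of
the record, so outputs are reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import MultichannelRecording

__all__ = [
    "BandDefinition",
    "CANONICAL_BANDS",
    "BAND_NAMES",
    "PSDResult",
    "bandpass_fir",
    "band_filter",
    "resting_state_filter",
    "cardiac_respiratory_filter",
    "reject_low_snr_channels",
    "remove_motion_pca",
    "artifact_reject",
    "scale_minmax",
    "ScaleParams",
    "welch_psd",
    "band_power",
]

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """A named EEG frequency interval in Hz."""

    name: str
    lowcut: float
    highcut: float

    def __post_init__(self) -> None:
        if not 0 <= self.lowcut < self.highcut:
            raise ValueError("require 0 <= lowcut < highcut")


CANONICAL_BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 1.0, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
    "beta": BandDefinition("beta", 12.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 100.0),
}


@dataclass
class PSDResult:
    """One-sided Welch power spectral density per channel."""

    freqs: np.ndarray
    power: np.ndarray  # (channels, bins)
    window_s: float
    overlap: float


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _fir_bandpass_taps(lowcut: float, highcut: float, fs: float) -> np.ndarray:
    transition = max(0.25 * lowcut, 0.5)
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    return signal.firwin(
        numtaps, [lowcut, highcut], pass_zero=False, window="hamming", fs=fs
    )


def _filtfilt_fir(taps: np.ndarray, data: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), data.shape[0] - 1)
    return signal.filtfilt(taps, [1.0], data, axis=0, padlen=padlen)


def bandpass_fir(
    rec: MultichannelRecording, lowcut: float, highcut: float
) -> MultichannelRecording:
    """Zero-phase FIR bandpass copy of a recording.

    Forward-backward application squares the Hamming-window frequency
    response: passband ripple stays well under 1 dB and stopband
    attenuation exceeds 100 dB one octave outside the band.
    """
    nyq = rec.fs / 2.0
    if highcut >= nyq:
        raise ValueError(f"highcut {highcut} Hz >= Nyquist {nyq} Hz")
    taps = _fir_bandpass_taps(lowcut, highcut, rec.fs)
    if rec.n_samples <= len(taps):
        raise ValueError(
            f"record too short for the filter ({rec.n_samples} samples, "
            f"{len(taps)} taps)"
        )
    return rec.copy(data=_filtfilt_fir(taps, rec.data))


def band_filter(rec: MultichannelRecording, band: str) -> MultichannelRecording:
    """Filter to one of the five canonical EEG bands by name."""
    if band not in CANONICAL_BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {BAND_NAMES}")
    b = CANONICAL_BANDS[band]
    return bandpass_fir(rec, b.lowcut, b.highcut)


def resting_state_filter(rec: MultichannelRecording) -> MultichannelRecording:
    """Band-limit an fNIRS recording to the resting-state range 0.01–0.1 Hz.

    A warning (not an error) is emitted for records shorter than three
    cycles of the 0.01 Hz edge, where the filter transient dominates.
    """
    if rec.duration < 3 / 0.01:
        warnings.warn(
            "record shorter than ~3 cycles of 0.01 Hz; transient dominates",
            stacklevel=2,
        )
    sos = signal.butter(4, [0.01, 0.1], btype="bandpass", fs=rec.fs, output="sos")
    return rec.copy(data=signal.sosfiltfilt(sos, rec.data, axis=0))


def cardiac_respiratory_filter(
    rec: MultichannelRecording, cutoff: float = 0.2
) -> MultichannelRecording:
    """Low-pass removing cardiac (~1 Hz) and respiratory (~0.25 Hz) components."""
    sos = signal.butter(4, cutoff, btype="lowpass", fs=rec.fs, output="sos")
    return rec.copy(data=signal.sosfiltfilt(sos, rec.data, axis=0))


# ---------------------------------------------------------------------------
# Channel / sample rejection
# ---------------------------------------------------------------------------

def reject_low_snr_channels(
    rec: MultichannelRecording, fraction: float = 0.30
) -> tuple[MultichannelRecording, list[str]]:
    """Drop channels whose RMS amplitude falls below ``fraction`` of the mean.

    Channel SNR is operationalized as RMS amplitude relative to the
    cross-channel mean, so a channel dominated by sensor noise floors out.
    Returns the surviving recording and the rejected labels.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    rms = np.sqrt(np.mean(np.square(rec.data), axis=0))
    keep = rms >= fraction * rms.mean()
    if not keep.any():
        raise ValueError("all channels rejected; nothing left to analyze")
    rejected = [l for l, k in zip(rec.channel_labels, keep) if not k]
    kept = [l for l, k in zip(rec.channel_labels, keep) if k]
    return rec.pick(kept), rejected


def remove_motion_pca(
    rec: MultichannelRecording, n_remove: int = 1
) -> MultichannelRecording:
    """Zero the top-variance principal components (motion correction).

    The channel count is unchanged: data are reconstructed from the
    remaining components plus the channel means.
    """
    if n_remove < 0:
        raise ValueError("n_remove must be nonnegative")
    if n_remove >= rec.n_channels:
        raise ValueError("n_remove must be smaller than the channel count")
    if n_remove == 0:
        return rec.copy()
    mean = rec.data.mean(axis=0)
    centered = rec.data - mean
    # right singular vectors = principal axes over channels
    _u, _s, vt = np.linalg.svd(centered, full_matrices=False)
    v_top = vt[:n_remove]  # (n_remove, n_channels)
    cleaned = centered - (centered @ v_top.T) @ v_top
    return rec.copy(data=cleaned + mean)


def artifact_reject(
    rec: MultichannelRecording, threshold: float = 0.10
) -> tuple[MultichannelRecording, np.ndarray]:
    """Flag samples deviating > ``threshold`` from the channel median.

    Expects min-max normalized data (range [0, 1]); the reference point is
    the per-channel median, a robust stand-in for "normalized intensity".
    The data are returned untouched together with a boolean mask
    (time x channels); masked spans are excluded downstream rather than
    interpolated.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    med = np.median(rec.data, axis=0)
    mask = np.abs(rec.data - med) > threshold
    return rec.copy(), mask


# ---------------------------------------------------------------------------
# Scaling
# ---------------------------------------------------------------------------

@dataclass
class ScaleParams:
    """Per-channel affine map to [0,1] plus the post-scale channel means."""

    mins: np.ndarray
    ranges: np.ndarray
    means: np.ndarray

    def transform(self, data: np.ndarray) -> np.ndarray:
        return (data - self.mins) / self.ranges - self.means

    def inverse(self, data: np.ndarray) -> np.ndarray:
        return (data + self.means) * self.ranges + self.mins


def scale_minmax(
    rec: MultichannelRecording,
) -> tuple[MultichannelRecording, ScaleParams]:
    """Map each channel to [0, 1] and mean-center it.

    Constant channels map to 0.5 (with a warning) so the inverse is still
    defined.  The returned parameters invert predictions back to physical
    units.
    """
    mins = rec.data.min(axis=0)
    maxs = rec.data.max(axis=0)
    ranges = maxs - mins
    flat = ranges < 1e-12
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant channel(s) mapped to 0.5",
                      stacklevel=2)
        ranges = np.where(flat, 1.0, ranges)
        mins = np.where(flat, mins - 0.5, mins)
    unit = (rec.data - mins) / ranges
    means = unit.mean(axis=0)
    params = ScaleParams(mins=mins, ranges=ranges, means=means)
    return rec.copy(data=unit - means), params


# ---------------------------------------------------------------------------
# Spectral estimation
# ---------------------------------------------------------------------------

def welch_psd(
    rec: MultichannelRecording, window_s: float = 4.0, overlap: float = 0.5
) -> PSDResult:
    """Welch averaged-periodogram PSD, one-sided, Hann windowed."""
    nperseg = int(round(window_s * rec.fs))
    if nperseg < 8:
        raise ValueError("window must cover at least 8 samples")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if rec.n_samples < nperseg:
        raise ValueError("record shorter than one Welch window")
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=0,
        detrend=False,
    )
    return PSDResult(freqs=freqs, power=power.T, window_s=window_s,
                     overlap=overlap)


def band_power(psd: PSDResult, lowcut: float, highcut: float) -> np.ndarray:
    """Integrate a PSD over [lowcut, highcut] Hz, per channel."""
    sel = (psd.freqs >= lowcut) & (psd.freqs <= highcut)
    return np.trapezoid(psd.power[:, sel], psd.freqs[sel], axis=1)
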