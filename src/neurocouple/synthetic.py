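"""Synthetic paired EEG/fNIRS with a known neurovascular coupling.

The generator emulates the physiological premise that slow hemodynamic
(fNIRS) fluctuations are driven by the power envelope of band-limited
neural oscillations: each fNIRS channel mixes the smoothed Hilbert power
envelopes of its nearest EEG channels per band, weights them by a
configurable band-coupling gain (gamma-dominant by default), convolves
with a double-gamma hemodynamic response function delayed by ~3 s, and
adds Mayer-wave (~0.1 Hz), respiratory (~0.25 Hz) and cardiac (~1 Hz)
oscillations plus sensor noise.  HbR is a negatively scaled copy of the
HbO physiology with independent noise.

All stochastic draws descend from a single integer seed, in a fixed
stream order (EEG band noise per band, then nuisance phases, then HbO
noise, then HbR noise), so partial regeneration is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import MultichannelRecording
from .preprocessing import BAND_NAMES, CANONICAL_BANDS, _fir_bandpass_taps, _filtfilt_fir

__all__ = [
    "ChannelGeometry",
    "CouplingConfig",
    "EEG_LABELS_1020",
    "generate_montage",
    "generate_eeg",
    "generate_fnirs_from_eeg",
    "double_gamma_hrf",
]

EEG_FS = 500.0
FNIRS_FS = 19.5
FNIRS_FS_MODEL = 20.0

#: The 21 scalp sites of the extended 10-20 montage used throughout.
EEG_LABELS_1020 = [
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8", "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]


@dataclass
class ChannelGeometry:
    """EEG and fNIRS channel coordinates on a spherical head."""

    eeg_labels: list[str]
    eeg_positions: np.ndarray  # (n_eeg, 3) mm
    fnirs_labels: list[str]
    fnirs_positions: np.ndarray  # (n_fnirs, 3) mm
    head_radius: float  # mm

    def __post_init__(self) -> None:
        self.eeg_positions = np.asarray(self.eeg_positions, dtype=float)
        self.fnirs_positions = np.asarray(self.fnirs_positions, dtype=float)
        for pos, labels in [
            (self.eeg_positions, self.eeg_labels),
            (self.fnirs_positions, self.fnirs_labels),
        ]:
            if pos.shape != (len(labels), 3):
                raise ValueError("positions must be (n_channels, 3)")
            if len(set(labels)) != len(labels):
                raise ValueError("labels must be unique")
            radii = np.linalg.norm(pos, axis=1)
            if not np.allclose(radii, self.head_radius, atol=0.01):
                raise ValueError("all positions must lie on the head sphere")


@dataclass
class CouplingConfig:
    """Parameters of the simulated neurovascular coupling.

    ``band_weights`` maps each canonical band name to a nonnegative gain;
    the default is gamma-dominant so that gamma-band EEG carries the
    predictive information.  Times are seconds, frequencies Hz, amplitudes
    in the µmol/L scale of the output.
    """

    band_weights: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0,
            "gamma": 1.0,
        }
    )
    hrf_peak_s: float = 5.0
    hrf_undershoot_s: float = 15.0
    hrf_ratio: float = 1.0 / 6.0
    neural_delay_s: float = 3.0
    mayer_amp: float = 0.5
    mayer_freq: float = 0.1
    resp_amp: float = 0.25
    resp_freq: float = 0.25
    cardiac_amp: float = 0.25
    cardiac_freq: float = 1.0
    noise_sd: float = 0.25
    hbr_gain: float = -0.4
    n_neighbors: int = 3
    envelope_lowpass_hz: float = 0.4
    fnirs_fs: float = FNIRS_FS
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.band_weights) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown band name(s): {sorted(unknown)}")
        for name, w in self.band_weights.items():
            if w < 0:
                raise ValueError(f"negative coupling gain for {name}")
        for amp in (self.mayer_amp, self.resp_amp, self.cardiac_amp,
                    self.noise_sd):
            if amp < 0:
                raise ValueError("amplitudes and noise_sd must be >= 0")
        nyq = self.fnirs_fs / 2.0
        for f in (self.mayer_freq, self.resp_freq, self.cardiac_freq):
            if not 0 < f < nyq:
                raise ValueError(
                    f"nuisance frequency {f} Hz outside (0, {nyq}) Hz"
                )


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def generate_montage(
    n_fnirs: int = 20, head_radius: float = 85.0, seed: int = 0
) -> ChannelGeometry:
    """Deterministic spherical-head montage.

    EEG sites are the 21 canonical 10-20 positions radially projected onto
    a sphere of ``head_radius`` mm; fNIRS channel midpoints cover the
    superior hemisphere quasi-uniformly on a Fibonacci lattice whose
    azimuthal origin is drawn from ``seed``.
    """
    if n_fnirs < 2:
        raise ValueError("need at least 2 fNIRS channels (seed + one other)")
    import mne

    import warnings

    with warnings.catch_warnings():
        # montage naming churn in MNE; the coordinates are what matters
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos_m = montage.get_positions()["ch_pos"]
    eeg_positions = np.array([pos_m[l] for l in EEG_LABELS_1020]) * 1000.0
    eeg_positions *= head_radius / np.linalg.norm(
        eeg_positions, axis=1, keepdims=True
    )

    rng = np.random.default_rng(seed)
    phase0 = rng.uniform(0, 2 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_fnirs)
    # superior hemisphere: z/R from 0.15 to ~0.95
    z = 0.15 + 0.8 * (k + 0.5) / n_fnirs
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    theta = phase0 + golden * k
    fnirs_positions = head_radius * np.stack(
        [r * np.cos(theta), r * np.sin(theta), z], axis=1
    )
    return ChannelGeometry(
        eeg_labels=list(EEG_LABELS_1020),
        eeg_positions=eeg_positions,
        fnirs_labels=[f"CH{i + 1}" for i in range(n_fnirs)],
        fnirs_positions=fnirs_positions,
        head_radius=head_radius,
    )


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

DEFAULT_BAND_POWERS = {
    "delta": 20.0, "theta": 10.0, "alpha": 15.0, "beta": 8.0, "gamma": 5.0,
}  # µV² per band, loosely 1/f-shaped as in resting scalp EEG


def _slow_modulators(
    rng: np.random.Generator,
    n: int,
    n_ch: int,
    shared_fraction: float,
    band_hz: tuple[float, float] = (0.01, 0.1),
) -> np.ndarray:
    """Standardized slow processes, one per channel, partially shared.

    Generated at 2 Hz (band-limited to ``band_hz`` with a Butterworth
    section) and linearly interpolated up to the EEG rate.
    """
    fs_lo = 2.0
    n_lo = max(int(np.ceil(n / EEG_FS * fs_lo)) + 8, 32)
    raw = rng.standard_normal((n_lo, n_ch + 1))
    sos = sps.butter(2, band_hz, btype="bandpass", fs=fs_lo, output="sos")
    slow = sps.sosfiltfilt(sos, raw, axis=0)
    slow /= slow.std(axis=0, keepdims=True)
    mixed = (
        np.sqrt(shared_fraction) * slow[:, :1]
        + np.sqrt(1 - shared_fraction) * slow[:, 1:]
    )
    t_lo = np.arange(n_lo) / fs_lo
    t_hi = np.arange(n) / EEG_FS
    return np.stack(
        [np.interp(t_hi, t_lo, mixed[:, c]) for c in range(n_ch)], axis=1
    )


def generate_eeg(
    geometry: ChannelGeometry,
    duration_s: float,
    band_powers: dict[str, float] | None = None,
    seed: int = 0,
    shared_fraction: float = 0.4,
    broadband_noise_sd: float = 1.0,
    modulation_depth: float = 0.5,
) -> MultichannelRecording:
    """Band-structured multichannel EEG at 500 Hz.

    Each channel sums, over the five canonical bands, band-filtered
    Gaussian noise scaled to the requested per-band variance, plus
    broadband sensor noise.  A fraction ``shared_fraction`` of each band's
    variance comes from a source common to all channels, giving the
    nontrivial cross-channel correlation a scalp montage shows.

    Each band's amplitude is further multiplied by a slow log-normal
    modulator ``exp(d*s - d^2/2)`` with ``s`` a standardized 0.01–0.1 Hz
    process (partially shared across channels) and ``d`` the
    ``modulation_depth``.  This is the infra-slow power modulation of
    cortical rhythms that resting-state hemodynamics track; without it a
    stationary band process carries no recoverable slow envelope.
    The whole record is annotated as one resting-state span.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    powers = dict(DEFAULT_BAND_POWERS if band_powers is None else band_powers)
    unknown = set(powers) - set(BAND_NAMES)
    if unknown:
        raise ValueError(f"unknown band name(s): {sorted(unknown)}")

    n = int(round(duration_s * EEG_FS))
    n_ch = len(geometry.eeg_labels)
    rng = np.random.default_rng(seed)
    data = np.zeros((n, n_ch))
    for band in BAND_NAMES:  # fixed stream order
        power = powers.get(band, 0.0)
        shared = rng.standard_normal((n, 1))
        indep = rng.standard_normal((n, n_ch))
        modulator = _slow_modulators(rng, n, n_ch, shared_fraction)
        if power <= 0:
            continue
        raw = (
            np.sqrt(shared_fraction) * shared
            + np.sqrt(1 - shared_fraction) * indep
        )
        b = CANONICAL_BANDS[band]
        taps = _fir_bandpass_taps(b.lowcut, b.highcut, EEG_FS)
        filtered = _filtfilt_fir(taps, raw)
        if modulation_depth > 0:
            filtered = filtered * np.exp(
                modulation_depth * modulator - modulation_depth**2 / 2
            )
        var = filtered.var(axis=0)
        scale = np.sqrt(power / np.where(var < 1e-30, 1.0, var))
        scale[var < 1e-30] = 0.0
        data += filtered * scale
    if broadband_noise_sd > 0:
        data += broadband_noise_sd * rng.standard_normal((n, n_ch))

    return MultichannelRecording(
        data=data,
        fs=EEG_FS,
        channel_labels=list(geometry.eeg_labels),
        modality="EEG",
        channel_positions=geometry.eeg_positions,
        annotations=[(0.0, n / EEG_FS, "rest")],
    )


# ---------------------------------------------------------------------------
# Hemodynamics
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t: np.ndarray,
    peak_s: float = 5.0,
    undershoot_s: float = 15.0,
    ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, peak-normalized.

    The positive lobe peaks at ``peak_s``; the undershoot peaks at
    ``undershoot_s`` with relative amplitude ``ratio``.
    """
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    # shape a, scale b with mode (a-1)*b = peak; dispersion fixed at 1 s
    h1 = gamma_dist.pdf(t, peak_s + 1.0, scale=1.0)
    h2 = gamma_dist.pdf(t, undershoot_s + 1.0, scale=1.0)
    h = h1 - ratio * h2
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _band_envelopes(
    eeg: MultichannelRecording, bands: list[str], lowpass_hz: float
) -> dict[str, np.ndarray]:
    """Smoothed Hilbert power envelope of each band, per EEG channel."""
    out = {}
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=eeg.fs, output="sos")
    for band in bands:
        b = CANONICAL_BANDS[band]
        taps = _fir_bandpass_taps(b.lowcut, b.highcut, eeg.fs)
        filtered = _filtfilt_fir(taps, eeg.data)
        env = np.abs(sps.hilbert(filtered, axis=0)) ** 2
        out[band] = sps.sosfiltfilt(sos, env, axis=0)
    return out


def generate_fnirs_from_eeg(
    eeg: MultichannelRecording,
    geometry: ChannelGeometry,
    coupling: CouplingConfig | None = None,
) -> tuple[MultichannelRecording, MultichannelRecording]:
    """Drive synthetic HbO/HbR from the band-power envelopes of an EEG record.

    For each fNIRS channel the envelopes of its ``n_neighbors`` nearest EEG
    channels are mixed with inverse-distance weights, mean-removed and
    combined across bands by the coupling gains (the gains carry the
    µmol-per-µV² scale, so the response is exactly linear in each gain and
    a band with no spectral content contributes nothing), convolved with
    the delayed double-gamma HRF at the fNIRS rate, and contaminated with
    nuisance sinusoids and white noise.

    Returns ``(hbo, hbr)`` where HbR is ``hbr_gain`` times the HbO
    physiology (response + nuisance) plus independent noise.
    """
    coupling = coupling or CouplingConfig()
    if abs(eeg.fs - EEG_FS) > 1e-9:
        raise ValueError("EEG must be sampled at 500 Hz")
    if list(eeg.channel_labels) != list(geometry.eeg_labels):
        raise ValueError("EEG channels do not match the montage geometry")

    fs_out = coupling.fnirs_fs
    n_out = int(round(eeg.n_samples / eeg.fs * fs_out))
    n_fnirs = len(geometry.fnirs_labels)
    rng = np.random.default_rng(coupling.seed)

    active = [b for b in BAND_NAMES if coupling.band_weights.get(b, 0.0) > 0]
    envelopes = _band_envelopes(eeg, active, coupling.envelope_lowpass_hz)

    # resample envelopes to the fNIRS rate (they are < 0.4 Hz by design)
    from fractions import Fraction

    ratio = (Fraction(fs_out) / Fraction(eeg.fs)).limit_denominator(10_000)
    env_lo = {
        b: sps.resample_poly(env, ratio.numerator, ratio.denominator, axis=0)[
            :n_out
        ]
        for b, env in envelopes.items()
    }

    # delayed HRF kernel sampled at the fNIRS rate
    t = np.arange(0.0, coupling.neural_delay_s + 32.0, 1.0 / fs_out)
    kernel = np.where(
        t >= coupling.neural_delay_s,
        double_gamma_hrf(
            t - coupling.neural_delay_s,
            coupling.hrf_peak_s,
            coupling.hrf_undershoot_s,
            coupling.hrf_ratio,
        ),
        0.0,
    )

    dist = np.linalg.norm(
        geometry.fnirs_positions[:, None, :] - geometry.eeg_positions[None, :, :],
        axis=2,
    )
    dist = np.maximum(dist, 1.0)

    response = np.zeros((n_out, n_fnirs))
    for j in range(n_fnirs):
        order = np.argsort(dist[j])[: coupling.n_neighbors]
        w = 1.0 / dist[j, order]
        w /= w.sum()
        drive = np.zeros(n_out)
        for band in active:
            mix = env_lo[band][:, order] @ w
            drive += coupling.band_weights[band] * (mix - mix.mean())
        # dt factor approximates the continuous convolution integral
        response[:, j] = sps.fftconvolve(drive, kernel)[:n_out] / fs_out

    # nuisance oscillations: common phase per component, per-channel jitter
    times = np.arange(n_out) / fs_out
    nuisance = np.zeros((n_out, n_fnirs))
    for amp, freq in [
        (coupling.mayer_amp, coupling.mayer_freq),
        (coupling.resp_amp, coupling.resp_freq),
        (coupling.cardiac_amp, coupling.cardiac_freq),
    ]:
        phases = rng.uniform(0, 2 * np.pi, size=n_fnirs)
        if amp > 0:
            nuisance += amp * np.sin(
                2 * np.pi * freq * times[:, None] + phases[None, :]
            )

    noise_hbo = rng.standard_normal((n_out, n_fnirs))
    noise_hbr = rng.standard_normal((n_out, n_fnirs))

    physiology = response + nuisance
    hbo_data = physiology + coupling.noise_sd * noise_hbo
    hbr_data = coupling.hbr_gain * physiology + coupling.noise_sd * noise_hbr

    annotations = [
        (onset, min(duration, n_out / fs_out - onset), label)
        for onset, duration, label in eeg.annotations
    ]
    common = dict(
        fs=fs_out,
        channel_labels=list(geometry.fnirs_labels),
        channel_positions=geometry.fnirs_positions,
        annotations=annotations,
    )
    hbo = MultichannelRecording(data=hbo_data, modality="HbO", **common)
    hbr = MultichannelRecording(data=hbr_data, modality="HbR", **common)
    return hbo, hbr
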