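"""From raw electrograms to wrapped instantaneous phase frames.

The pipeline mirrors standard intracardiac phase-mapping practice for
atrial fibrillation: cubic-spline resampling to 512 Hz, dominant-frequency
(DF) estimation per channel, sinusoidal recomposition with the local cycle
length 1/DF, and the Hilbert-transform analytic signal, whose four-quadrant
angle

    phi(t) = atan2(h(t), f(t))

is the instantaneous phase, wrapped to (-pi, pi].

Sinusoidal recomposition rebuilds each electrogram as a superposition of
single-cycle sinusoidal wavelets, one inserted at every sample with a
negative slope and with amplitude proportional to |dV/dt| there.  The
wavelet is a centered single negative *sine* cycle of period 1/DF: with
this (odd) shape the recomposition of a sinusoid is phase-neutral, so the
Hilbert phase of the recomposed signal aligns with the phase of the
underlying activation without any constant offset.  A constant phase
offset would move no singularity, but phase-neutrality makes round trips
(phase -> electrogram -> phase) directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import fftconvolve, hilbert

from .detect import wrap_phase


class PhaseError(ValueError):
    """Raised for degenerate signals (constant channels, missing spectral peaks)."""


@dataclass
class EgmSet:
    """A multichannel electrogram recording: channels x time samples at ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    node_map: np.ndarray = None  # channel -> mesh node

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("electrograms must be finite")
        if self.node_map is None:
            self.node_map = np.arange(self.samples.shape[0], dtype=np.int64)
        self.node_map = np.asarray(self.node_map, dtype=np.int64)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class AnalyticSignal:
    """Hilbert analytic decomposition: f + j h = A exp(j phi)."""

    real_part: np.ndarray
    imag_part: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.hypot(self.real_part, self.imag_part)

    @property
    def phase(self) -> np.ndarray:
        return wrap_phase(np.arctan2(self.imag_part, self.real_part))


@dataclass
class PhaseSequence:
    """Frames x nodes of wrapped instantaneous phase at ``frame_rate`` Hz."""

    phase: np.ndarray
    frame_rate: float
    mesh: object = None
    projection: object = None
    failed_channels: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self):
        self.phase = np.atleast_2d(np.asarray(self.phase, dtype=float))

    @property
    def n_frames(self) -> int:
        return self.phase.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.phase.shape[1]

    def frame_grid(self, t: int) -> np.ndarray:
        if self.projection is None:
            raise ValueError("no grid projection attached")
        return self.projection.frame_to_grid(self.phase[t])


@dataclass
class PhaseConfig:
    """Pipeline settings: resampling rate, DF search band, edge flagging."""

    fs_out: float = 512.0
    df_band: tuple[float, float] = (3.0, 15.0)  # physiological AF range, Hz
    df_resolution: float = 0.05  # Hz, via zero padding
    edge_fraction: float = 0.05  # leading/trailing frames flagged as edge-affected
    max_failed_fraction: float = 0.10


def resample_cubic(egm: EgmSet, fs_out: float) -> EgmSet:
    """Cubic-spline resampling of every channel to ``fs_out`` Hz.

    The first sample is preserved exactly and the new time base never
    extrapolates beyond the recording.
    """
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out == egm.fs:
        return EgmSet(egm.samples.copy(), egm.fs, egm.node_map.copy())
    n = egm.n_samples
    t_in = np.arange(n) / egm.fs
    n_out = int(np.floor(t_in[-1] * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    spline = CubicSpline(t_in, egm.samples, axis=1)
    return EgmSet(spline(t_out), fs_out, egm.node_map.copy())


def _spectrum(samples: np.ndarray, fs: float, resolution: float):
    x = np.atleast_2d(samples).astype(float)
    x = x - x.mean(axis=1, keepdims=True)
    # linear detrend
    t = np.arange(x.shape[1])
    t = t - t.mean()
    slope = (x @ t) / (t @ t)
    x = x - slope[:, None] * t[None, :]
    window = np.hanning(x.shape[1])
    nfft = int(2 ** np.ceil(np.log2(max(fs / resolution, x.shape[1]))))
    mag = np.abs(np.fft.rfft(x * window, n=nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, mag


def dominant_frequency(
    signal: np.ndarray, fs: float, band: tuple[float, float] = (3.0, 15.0)
) -> float:
    """Frequency of the largest spectral-magnitude peak inside ``band`` (Hz)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("dominant_frequency takes a single channel")
    if len(signal) < fs:
        raise ValueError("need at least 1 s of data for a dominant frequency")
    if not (0.0 < band[0] < band[1] < fs / 2):
        raise ValueError("band must lie inside (0, fs/2)")
    if np.ptp(signal) == 0:
        raise PhaseError("no dominant peak in a constant signal")
    freqs, mag = _spectrum(signal, fs, 0.05)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    m = mag[0, sel]
    if not np.any(m > 0):
        raise PhaseError("no dominant peak inside the band")
    return float(freqs[sel][np.argmax(m)])


def sinusoidal_recomposition(signal: np.ndarray, fs: float, cycle_length: float) -> np.ndarray:
    """Rebuild a signal as a sum of single-cycle sinusoidal wavelets.

    One wavelet of period ``cycle_length`` (seconds) is centered at every
    sample, with amplitude proportional to the negative slope of the input
    there (zero where the slope is >= 0).  The wavelet is a single negative
    sine cycle, which preserves the Hilbert phase of sinusoidal input.
    """
    signal = np.asarray(signal, dtype=float)
    one_d = signal.ndim == 1
    x = np.atleast_2d(signal)
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    L = int(round(cycle_length * fs))
    if L > x.shape[1]:
        raise PhaseError("cycle_length exceeds the record length")
    L = max(L, 3)
    tau = (np.arange(L) - (L - 1) / 2.0) / fs
    wavelet = -np.sin(2.0 * np.pi * tau / cycle_length)
    slopes = np.diff(x, axis=1)
    amps = np.where(slopes < 0, -slopes, 0.0)
    amps = np.concatenate([amps, np.zeros((x.shape[0], 1))], axis=1)
    out = fftconvolve(amps, wavelet[None, :], mode="same", axes=1)
    return out[0] if one_d else out


def instantaneous_phase(signal: np.ndarray) -> AnalyticSignal:
    """Analytic signal of the mean-subtracted input (frequency-domain Hilbert)."""
    signal = np.asarray(signal, dtype=float)
    one_d = signal.ndim == 1
    x = np.atleast_2d(signal)
    if x.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    if np.any(np.ptp(x, axis=1) == 0):
        raise PhaseError("phase undefined for a constant signal")
    x = x - x.mean(axis=1, keepdims=True)
    analytic = hilbert(x, axis=1)
    if one_d:
        analytic = analytic[0]
    return AnalyticSignal(real_part=np.real(analytic), imag_part=np.imag(analytic))


def phase_field(egm: EgmSet, config: PhaseConfig | None = None) -> PhaseSequence:
    """Full pipeline: resample -> DF -> recomposition -> Hilbert phase.

    Channels that fail (constant signal, no spectral peak) are recorded in
    ``failed_channels`` with their phase set to zero; if more than
    ``config.max_failed_fraction`` of channels fail the whole pipeline
    raises :class:`PhaseError` listing them.
    """
    config = config or PhaseConfig()
    egm = resample_cubic(egm, min(config.fs_out, egm.fs))
    x = egm.samples
    n_ch, n_t = x.shape
    failed: list[int] = []
    dfs = np.zeros(n_ch)
    lo, hi = config.df_band
    freqs, mag = _spectrum(x, egm.fs, config.df_resolution)
    sel = (freqs >= lo) & (freqs <= hi)
    fsel = freqs[sel]
    msel = mag[:, sel]
    for ch in range(n_ch):
        if np.ptp(x[ch]) == 0 or not np.any(msel[ch] > 0):
            failed.append(ch)
        else:
            dfs[ch] = fsel[np.argmax(msel[ch])]
    ok = np.setdiff1d(np.arange(n_ch), failed)
    if len(failed) > config.max_failed_fraction * n_ch:
        raise PhaseError(f"phase pipeline failed on channels {failed}")
    recomposed = np.zeros_like(x)
    # group channels by identical wavelet length so each group convolves in one call
    lengths = np.round(egm.fs / np.where(dfs > 0, dfs, 1.0)).astype(int)
    for L in np.unique(lengths[ok]):
        chans = ok[lengths[ok] == L]
        recomposed[chans] = sinusoidal_recomposition(x[chans], egm.fs, L / egm.fs)
    phases = np.zeros_like(x)
    if len(ok):
        phases[ok] = instantaneous_phase(recomposed[ok]).phase
    n_nodes = int(egm.node_map.max()) + 1
    out = np.zeros((n_t, n_nodes))
    out[:, egm.node_map] = phases.T
    return PhaseSequence(
        phase=out,
        frame_rate=egm.fs,
        failed_channels=np.array(failed, dtype=np.int64),
    )


def edge_frame_mask(n_frames: int, edge_fraction: float = 0.05) -> np.ndarray:
    """Boolean mask of interior frames (edge-affected leading/trailing frames False)."""
    k = int(np.ceil(edge_fraction * n_frames))
    mask = np.ones(n_frames, dtype=bool)
    if k:
        mask[:k] = False
        mask[-k:] = False
    return mask
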