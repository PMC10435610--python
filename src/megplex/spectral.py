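"""Band-limited phase-lag-index (PLI) connectivity from multichannel time series.

The processing chain mirrors standard resting-state MEG practice: a recording
is cut into fixed-length epochs, each epoch is band-filtered by masking its
discrete Fourier transform, instantaneous phases are taken from the analytic
signal, and the PLI — the absolute mean sign of the pairwise phase
difference — is computed per epoch and averaged, yielding one symmetric
weighted connectivity matrix per frequency band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "TimeSeries",
    "Epoch",
    "BandDefinition",
    "PhaseSeries",
    "ConnectivityMatrix",
    "DEFAULT_BANDS",
    "segment_epochs",
    "bandpass_fft",
    "instantaneous_phase",
    "pli_pair",
    "pli_matrix",
]


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency interval [f_lo, f_hi) in Hz.

    A DFT bin falling exactly on a shared band edge belongs to the higher
    band, so adjacent bands never double-count a bin.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got "
                f"[{self.f_lo}, {self.f_hi})"
            )


#: The six canonical resting-state bands used throughout the pipeline.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("lower_alpha", 8.0, 10.0),
    BandDefinition("upper_alpha", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)


@dataclass
class TimeSeries:
    """Region-level recording: a (time x regions) sample matrix at ``fs`` Hz."""

    samples: np.ndarray
    fs: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (time x regions) array")
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        n_time, n_regions = self.samples.shape
        if n_regions < 2:
            raise ValueError(f"need at least 2 regions, got {n_regions}")
        if n_time < 1:
            raise ValueError("need at least 1 sample")
        if np.isnan(self.samples).any():
            raise ValueError("samples contain missing values (NaN)")
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(n_regions)]
        if len(self.region_labels) != n_regions:
            raise ValueError(
                f"{len(self.region_labels)} labels for {n_regions} regions"
            )

    @property
    def n_regions(self) -> int:
        return self.samples.shape[1]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


@dataclass
class Epoch:
    """One fixed-length contiguous segment of a recording."""

    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("epoch samples must be 2-D (time x regions)")

    @property
    def epoch_length(self) -> int:
        return self.samples.shape[0]

    @property
    def n_regions(self) -> int:
        return self.samples.shape[1]


@dataclass
class PhaseSeries:
    """Instantaneous phase per sample and region, wrapped to (-pi, pi]."""

    phases: np.ndarray


@dataclass
class ConnectivityMatrix:
    """Epoch-averaged PLI weights for one frequency band.

    Symmetric, zero diagonal, entries in [0, 1].
    """

    weights: np.ndarray
    band: BandDefinition
    n_epochs_averaged: int
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = self.weights.shape[0]
        if self.weights.shape != (n, n):
            raise ValueError("connectivity weights must be square")
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


def segment_epochs(
    ts: TimeSeries, epoch_length: int = 4096, max_epochs: int = 60
) -> list[Epoch]:
    """Cut a recording into its first consecutive non-overlapping epochs.

    Returns the first ``min(max_epochs, floor(T / epoch_length))`` epochs in
    temporal order.

    Raises
    ------
    ValueError
        If the recording is shorter than one epoch.
    """
    if epoch_length < 1:
        raise ValueError(f"epoch_length must be >= 1, got {epoch_length}")
    if ts.n_samples < epoch_length:
        raise ValueError(
            f"recording has {ts.n_samples} samples but one epoch requires "
            f"{epoch_length}"
        )
    n_epochs = min(max_epochs, ts.n_samples // epoch_length)
    return [
        Epoch(ts.samples[i * epoch_length : (i + 1) * epoch_length])
        for i in range(n_epochs)
    ]


def _band_mask(n_samples: int, band: BandDefinition, fs: float) -> np.ndarray:
    """Boolean keep-mask over rfft bins for the half-open interval [f_lo, f_hi)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return (freqs >= band.f_lo) & (freqs < band.f_hi)


def bandpass_fft(epoch: Epoch, band: BandDefinition, fs: float) -> Epoch:
    """Zero all spectral content outside ``band`` via DFT masking.

    Each channel is mean-centered first (removes the DC bin
    deterministically), transformed with a real FFT, bins outside
    [f_lo, f_hi) are zeroed, and the signal is inverse-transformed. Output
    has identical shape and is real by construction of the real FFT.
    """
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name!r} upper edge {band.f_hi} Hz is at or above the "
            f"Nyquist frequency {fs / 2} Hz"
        )
    x = epoch.samples - epoch.samples.mean(axis=0, keepdims=True)
    spectrum = np.fft.rfft(x, axis=0)
    mask = _band_mask(epoch.epoch_length, band, fs)
    spectrum[~mask, :] = 0.0
    filtered = np.fft.irfft(spectrum, n=epoch.epoch_length, axis=0)
    return Epoch(filtered)


def instantaneous_phase(epoch: Epoch) -> PhaseSeries:
    """Analytic-signal (Hilbert) phase per channel, wrapped to (-pi, pi].

    Raises
    ------
    ValueError
        If any channel is constant (phase undefined), naming the channel.
    """
    x = epoch.samples
    spans = np.ptp(x, axis=0)
    flat = np.flatnonzero(spans == 0)
    if flat.size:
        raise ValueError(
            f"constant channel(s) {flat.tolist()}: instantaneous phase is "
            "undefined for a zero-variance signal"
        )
    analytic = hilbert(x, axis=0)
    return PhaseSeries(np.angle(analytic))


def pli_pair(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """Phase lag index between two phase sequences.

    ``|mean over samples of sign(sin(phi_a - phi_b))|``; an exactly zero
    phase difference contributes 0 to the mean (zero-lag coupling is
    discounted, not counted as lagged). Bounded in [0, 1]; symmetric in its
    arguments.
    """
    phi_a = np.asarray(phi_a, dtype=float)
    phi_b = np.asarray(phi_b, dtype=float)
    if phi_a.shape != phi_b.shape:
        raise ValueError(
            f"phase sequences differ in shape: {phi_a.shape} vs {phi_b.shape}"
        )
    if phi_a.size == 0:
        raise ValueError("phase sequences must have length >= 1")
    return float(np.abs(np.mean(np.sign(np.sin(phi_a - phi_b)))))


def pli_matrix(
    epochs: list[Epoch],
    band: BandDefinition,
    fs: float,
    region_labels: list[str] | None = None,
) -> ConnectivityMatrix:
    """Epoch-averaged PLI matrix for one frequency band.

    Per epoch the channels are band-filtered, phases extracted, and the PLI
    evaluated for every unordered region pair; the per-epoch matrices are
    then averaged. The result is symmetric with a zero diagonal.
    """
    if not epochs:
        raise ValueError("need at least one epoch")
    shape = epochs[0].samples.shape
    for k, ep in enumerate(epochs):
        if ep.samples.shape != shape:
            raise ValueError(
                f"epoch {k} has shape {ep.samples.shape}, expected {shape}"
            )
    n = shape[1]
    acc = np.zeros((n, n))
    for ep in epochs:
        phi = instantaneous_phase(bandpass_fft(ep, band, fs)).phases
        sgn = np.empty((n, n))
        np.fill_diagonal(sgn, 0.0)
        for i in range(n - 1):
            diffs = np.sin(phi[:, i : i + 1] - phi[:, i + 1 :])
            row = np.abs(np.mean(np.sign(diffs), axis=0))
            sgn[i, i + 1 :] = row
            sgn[i + 1 :, i] = row
        acc += sgn
    acc /= len(epochs)
    labels = region_labels or [f"region_{i:03d}" for i in range(n)]
    return ConnectivityMatrix(
        weights=acc,
        band=band,
        n_epochs_averaged=len(epochs),
        region_labels=list(labels),
    )
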