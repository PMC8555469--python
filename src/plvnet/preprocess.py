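"""Spatial and spectral pre-processing of epoched EEG.

The pipeline order is fixed: common average reference (CAR), 8-30 Hz
zero-phase band-pass, spherical-spline surface Laplacian (current source
density), then analysis-window extraction.  Every stage is linear, keeps the
trial/channel/sample layout, and never touches trial labels or ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import legval
from scipy.signal import firwin, fftconvolve, freqz


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EpochSet:
    """Epoched multichannel EEG: trials x channels x samples.

    Attributes
    ----------
    data
        Array (n_trials, n_channels, n_samples), microvolts (CSD scale after
        the Laplacian).
    channel_names
        Ordered channel labels matching axis 1.
    positions
        (n_channels, 3) unit-sphere electrode coordinates.
    sfreq
        Sampling rate in Hz.
    t0
        Time of the first sample relative to trial start, seconds.
    labels
        Per-trial condition label, 'left' or 'right'.
    subject_id, run_index
        Bookkeeping carried through every stage untouched.
    """

    data: np.ndarray
    channel_names: tuple
    positions: np.ndarray
    sfreq: float
    t0: float = 0.0
    labels: np.ndarray | None = None
    subject_id: str | None = None
    run_index: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length does not match data")
        self.positions = np.asarray(self.positions, float)
        if self.positions.shape != (len(self.channel_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if self.sfreq <= 0:
            raise ValueError("sample rate must be positive")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise ValueError("labels length does not match trial count")
        if self.run_index is not None:
            self.run_index = np.asarray(self.run_index)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sfreq

    def with_data(self, data: np.ndarray, **kw) -> "EpochSet":
        """Copy of this EpochSet with new data (and optional field overrides)."""
        return replace(self, data=data, **kw)

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in EpochSet") from None


@dataclass(frozen=True)
class WindowDef:
    """Half-open analysis window [start_s, end_s) in trial-relative seconds."""

    name: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not self.end_s > self.start_s:
            raise ValueError(f"window {self.name}: end must exceed start")

    def sample_slice(self, sfreq: float) -> slice:
        return slice(int(np.floor(self.start_s * sfreq)),
                     int(np.floor(self.end_s * sfreq)))


#: Pre-cue rest phase of each trial.
REST_WINDOW = WindowDef("rest", 0.0, 3.0)
#: Motor-imagery phase, 1-4.5 s after the 3 s cue (engagement/feedback trimmed).
MI_WINDOW = WindowDef("mi", 4.0, 7.5)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the common average: subtract the instantaneous
    across-channel mean from every channel.  Output channel sums are zero at
    every sample."""
    if epochs.n_channels < 2:
        raise ValueError("CAR undefined for fewer than 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.with_data(data)


def design_bandpass(lo_hz: float, hi_hz: float, sfreq: float,
                    transition_hz: float = 1.0) -> np.ndarray:
    """Design the linear-phase FIR band-pass kernel (Hamming window).

    The number of taps follows the Hamming-window rule of thumb
    ``3.3 / (transition / sfreq)``, rounded up to an odd length so that
    same-mode convolution is exactly zero phase.
    """
    nyq = sfreq / 2.0
    if not 0 < lo_hz < hi_hz < nyq:
        raise ValueError(
            f"band edges must satisfy 0 < {lo_hz} < {hi_hz} < Nyquist {nyq}")
    ntaps = int(np.ceil(3.3 * sfreq / transition_hz))
    ntaps += 1 - ntaps % 2
    return firwin(ntaps, [lo_hz, hi_hz], pass_zero=False, fs=sfreq)


def bandpass(epochs: EpochSet, lo_hz: float = 8.0, hi_hz: float = 30.0,
             transition_hz: float = 1.0) -> EpochSet:
    """Zero-phase FIR band-pass per channel per trial (default 8-30 Hz).

    A linear-phase kernel applied with centered same-length convolution
    introduces no phase distortion, which matters because instantaneous
    phase is extracted downstream.
    """
    kernel = design_bandpass(lo_hz, hi_hz, epochs.sfreq, transition_hz)
    data = fftconvolve(epochs.data, kernel[None, None, :], mode="same", axes=2)
    return epochs.with_data(data)


def bandpass_response_db(lo_hz: float, hi_hz: float, sfreq: float,
                         freqs_hz: Sequence[float],
                         transition_hz: float = 1.0) -> np.ndarray:
    """Gain (dB) of the designed band-pass at the given frequencies."""
    kernel = design_bandpass(lo_hz, hi_hz, sfreq, transition_hz)
    _, h = freqz(kernel, worN=np.asarray(freqs_hz, float), fs=sfreq)
    return 20 * np.log10(np.maximum(np.abs(h), 1e-300))


def _legendre_series(cosang: np.ndarray, order: float, n_terms: int) -> np.ndarray:
    # sum_{n=1..N} (2n+1) / (4 pi (n(n+1))^order) P_n(cosang)
    n = np.arange(1, n_terms + 1)
    coef = np.concatenate(
        ([0.0], (2 * n + 1) / (4 * np.pi * (n * (n + 1.0)) ** order)))
    return legval(cosang, coef)


def laplacian_transform(positions: np.ndarray, stiffness: int = 4,
                        regularization: float = 1e-5,
                        n_legendre_terms: int = 50) -> np.ndarray:
    """Spherical-spline surface-Laplacian transform matrix (Perrin splines).

    A spline of order m (``stiffness``) is fitted to the potentials at the
    electrode sites on the unit sphere, with a ridge term
    (``regularization``) added to the diagonal of the spline matrix G, under
    the usual zero-sum constraint on the spline coefficients; the surface
    Laplacian of the fitted spline is then evaluated at the electrodes.  The
    result is a single (n, n) matrix applied to each sample's potential
    vector, yielding current-source-density values on the unit sphere.
    """
    pos = np.asarray(positions, float)
    n = pos.shape[0]
    if n < 5:
        raise ValueError("spherical-spline Laplacian needs at least 5 channels")
    pos = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    off = ~np.eye(n, dtype=bool)
    if np.any(cosang[off] > 1 - 1e-10):
        raise ValueError("duplicate electrode positions in montage")

    g = _legendre_series(cosang, float(stiffness), n_legendre_terms)
    h = -_legendre_series(cosang, float(stiffness) - 1.0, n_legendre_terms)
    g[np.diag_indices(n)] += regularization

    # bordered system enforces sum(c) = 0 with a free constant offset
    bordered = np.zeros((n + 1, n + 1))
    bordered[:n, :n] = g
    bordered[:n, n] = 1.0
    bordered[n, :n] = 1.0
    coef_map = np.linalg.solve(bordered, np.vstack([np.eye(n), np.zeros(n)]))
    # CSD_i = -sum_j c_j h(cos(x_i, x_j)); sign gives the Laplacian of the spline
    return -h @ coef_map[:n]


def surface_laplacian(epochs: EpochSet, stiffness: int = 4,
                      regularization: float = 1e-5,
                      n_legendre_terms: int = 50) -> EpochSet:
    """Apply the spherical-spline current-source-density estimate per sample.

    Defaults (spline order 4, ridge 1e-5) are the conventional choices for
    low-density montages.  The output is on a CSD scale (unit-sphere radius);
    downstream phase-locking values are amplitude-invariant, so the absolute
    scale is irrelevant.
    """
    transform = laplacian_transform(
        epochs.positions, stiffness, regularization, n_legendre_terms)
    data = np.einsum("ij,njt->nit", transform, epochs.data)
    return epochs.with_data(data)


def cut_windows(epochs: EpochSet, windows: Sequence[WindowDef]) -> dict:
    """Slice each analysis window out of the trials.

    Returns ``{window.name: EpochSet}`` with samples in [start, end), sample
    index = floor(t * sfreq) relative to trial start.
    """
    if abs(epochs.t0) > 0.5 / epochs.sfreq:
        raise ValueError("cut_windows expects trial-relative epochs (t0 = 0)")
    out = {}
    for w in windows:
        sl = w.sample_slice(epochs.sfreq)
        if sl.start < 0 or sl.stop > epochs.n_samples or sl.stop <= sl.start:
            raise ValueError(
                f"window {w.name} [{w.start_s}, {w.end_s}) outside trial "
                f"bounds or empty")
        out[w.name] = epochs.with_data(
            epochs.data[:, :, sl], t0=sl.start / epochs.sfreq)
    return out


def preprocess_epochs(epochs: EpochSet, lo_hz: float = 8.0, hi_hz: float = 30.0,
               stiffness: int = 4, regularization: float = 1e-5) -> EpochSet:
    """CAR -> band-pass -> surface Laplacian, in that order."""
    out = common_average_reference(epochs)
    out = bandpass(out, lo_hz, hi_hz)
    return surface_laplacian(out, stiffness, regularization)
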