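"""Phase extraction and phase-locking value (PLV) computation.

Instantaneous phase is obtained by convolving each trial and channel with a
complex Morlet wavelet (CMW)

    psi(t) = (pi * fb)^(-1/2) * exp(j 2 pi fc t) * exp(-t^2 / fb)

where fc is the center frequency and fb the bandwidth parameter.  The
inter-trial PLV of an electrode pair at time t is the mean resultant length
of the phase difference across the N trials,

    PLV(t) = | (1/N) sum_n exp(j (phi_i(t, n) - phi_j(t, n))) |,

and the reported per-pair value is the average of PLV(t) over the samples of
the analysis window (rest or motor imagery).  PLV ranges from 0 (no
consistent phase relation) to 1 (perfect locking) and is invariant to any
positive rescaling of either signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .preprocess import EpochSet, WindowDef

#: Tidy PLV table column order.
PLV_COLUMNS = ("subject_id", "condition", "window", "band",
               "channel_i", "channel_j", "plv")


@dataclass(frozen=True)
class BandSpec:
    """Complex-Morlet analysis band: center frequency fc (Hz) and bandwidth
    parameter fb (s^2, variance of the Gaussian envelope)."""

    name: str
    fc: float
    fb: float

    def __post_init__(self):
        if self.fc <= 0 or self.fb <= 0:
            raise ValueError("fc and fb must be positive")


#: Mu/alpha band: fc = 10.5 Hz, fb = 0.3.
ALPHA = BandSpec("alpha", 10.5, 0.3)
#: Beta band: fc = 21.5 Hz, fb = 0.13.
BETA = BandSpec("beta", 21.5, 0.13)
BANDS = {"alpha": ALPHA, "beta": BETA}


@dataclass
class PhaseTensor:
    """Instantaneous phase per trial/channel/sample for one band.

    ``valid_mask`` flags samples at least half a kernel length away from the
    trial edges; samples outside the mask are excluded from window averages
    because the centered convolution there mixes in zero padding.
    """

    phase: np.ndarray  # (n_trials, n_channels, n_samples), radians
    band: BandSpec
    valid_mask: np.ndarray  # (n_samples,), bool
    channel_names: tuple
    sfreq: float
    t0: float = 0.0
    labels: np.ndarray | None = None
    subject_id: str | None = None

    @property
    def n_trials(self) -> int:
        return self.phase.shape[0]

    def channel_index(self, name) -> int:
        if isinstance(name, (int, np.integer)):
            return int(name)
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in PhaseTensor") from None

    def window_sample_index(self, window: WindowDef) -> np.ndarray:
        """Sample indices of the window intersected with the valid mask."""
        sl = window.sample_slice(self.sfreq)
        if sl.start < 0 or sl.stop > self.phase.shape[2]:
            raise ValueError(f"window {window.name} outside trial bounds")
        idx = np.arange(sl.start, sl.stop)
        idx = idx[self.valid_mask[idx]]
        if idx.size == 0:
            raise ValueError(
                f"window {window.name} has no samples clear of wavelet edges")
        return idx


def cmw_kernel(band: BandSpec, sample_rate_hz: float,
               tail: float = 1e-6) -> np.ndarray:
    """Sampled complex Morlet wavelet for the band.

    The symmetric time grid extends until the Gaussian envelope falls below
    ``tail`` times its peak, so truncation effects are negligible.  Peak at
    t = 0; odd length.
    """
    if sample_rate_hz <= 2 * band.fc:
        raise ValueError("sample rate must exceed twice the center frequency")
    half_t = np.sqrt(band.fb * np.log(1.0 / tail))
    if half_t * sample_rate_hz < 1.0:
        raise ValueError("bandwidth too small: kernel shorter than 3 samples")
    n_half = int(np.ceil(half_t * sample_rate_hz))
    t = np.arange(-n_half, n_half + 1) / sample_rate_hz
    return ((np.pi * band.fb) ** -0.5
            * np.exp(2j * np.pi * band.fc * t)
            * np.exp(-t ** 2 / band.fb))


def extract_phase(epochs: EpochSet, band: BandSpec) -> PhaseTensor:
    """Instantaneous phase via centered complex convolution with the CMW."""
    kernel = cmw_kernel(band, epochs.sfreq)
    if epochs.n_samples < kernel.size:
        raise ValueError(
            f"trial ({epochs.n_samples} samples) shorter than the "
            f"{band.name} kernel ({kernel.size} samples)")
    analytic = fftconvolve(epochs.data.astype(complex),
                           kernel[None, None, :], mode="same", axes=2)
    half = kernel.size // 2
    valid = np.zeros(epochs.n_samples, bool)
    valid[half:epochs.n_samples - half] = True
    return PhaseTensor(phase=np.angle(analytic), band=band, valid_mask=valid,
                       channel_names=epochs.channel_names, sfreq=epochs.sfreq,
                       t0=epochs.t0, labels=epochs.labels,
                       subject_id=epochs.subject_id)


def _resultant(phase_diff: np.ndarray, aggregate: str) -> float:
    # phase_diff: (n_trials, n_window_samples)
    if aggregate == "samplewise":
        r_t = np.abs(np.exp(1j * phase_diff).mean(axis=0))
        return float(r_t.mean())
    if aggregate == "pooled":
        return float(np.abs(np.exp(1j * phase_diff).mean()))
    raise ValueError(f"unknown aggregate mode {aggregate!r}")


def plv_pair(phases: PhaseTensor, i, j, window: WindowDef,
             aggregate: str = "samplewise") -> float:
    """Inter-trial PLV of one electrode pair within a window.

    ``aggregate='samplewise'`` (default) computes the inter-trial resultant
    per sample and averages over the window; ``'pooled'`` treats all
    (trial, sample) phase differences of the window as one bin.
    """
    ii, jj = phases.channel_index(i), phases.channel_index(j)
    if ii == jj:
        raise ValueError("self-pair PLV is undefined")
    if phases.n_trials < 2:
        raise ValueError("PLV needs at least 2 trials")
    idx = phases.window_sample_index(window)
    diff = phases.phase[:, ii, idx] - phases.phase[:, jj, idx]
    return _resultant(diff, aggregate)


def plv_matrix(phases: PhaseTensor, window: WindowDef,
               trial_subset: str | None = None,
               aggregate: str = "samplewise") -> pd.DataFrame:
    """PLV for every unordered channel pair (i < j in montage order).

    Returns tidy rows (subject_id, condition, window, band, channel_i,
    channel_j, plv); 120 rows for 16 channels.
    """
    if trial_subset is not None:
        if phases.labels is None:
            raise ValueError("PhaseTensor has no labels to subset by")
        mask = phases.labels == trial_subset
        if not mask.any():
            raise ValueError(f"no trials with label {trial_subset!r}")
        phase = phases.phase[mask]
    else:
        phase = phases.phase
    if phase.shape[0] < 2:
        raise ValueError("PLV needs at least 2 trials")
    idx = phases.window_sample_index(window)
    z = np.exp(1j * phase[:, :, idx])  # (N, C, T)
    n = z.shape[0]
    zt = np.ascontiguousarray(z.transpose(2, 1, 0))  # (T, C, N)
    if aggregate == "samplewise":
        gram = zt @ zt.conj().transpose(0, 2, 1) / n  # (T, C, C)
        plv = np.abs(gram).mean(axis=0)
    elif aggregate == "pooled":
        gram = zt @ zt.conj().transpose(0, 2, 1)  # (T, C, C)
        plv = np.abs(gram.sum(axis=0)) / (n * zt.shape[0])
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    names = phases.channel_names
    rows = [(phases.subject_id, trial_subset, window.name, phases.band.name,
             names[a], names[b], plv[a, b])
            for a, b in combinations(range(len(names)), 2)]
    return pd.DataFrame(rows, columns=PLV_COLUMNS)


_KEY = ["subject_id", "condition", "band", "channel_i", "channel_j"]


def delta_plv(mi_rows: pd.DataFrame, rest_rows: pd.DataFrame) -> pd.DataFrame:
    """Task-induced connectivity change: delta = PLV_MI - PLV_Rest, matched
    on (subject, condition, band, pair).  Raises if keys do not align."""
    mi = mi_rows.set_index(_KEY)["plv"]
    rest = rest_rows.set_index(_KEY)["plv"]
    missing = mi.index.symmetric_difference(rest.index)
    if len(missing):
        raise ValueError(
            f"MI/rest key mismatch for {len(missing)} entries, e.g. "
            f"{list(missing[:5])}")
    delta = (mi - rest.reindex(mi.index)).reset_index()
    delta["window"] = "delta"
    return delta[list(PLV_COLUMNS)]
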