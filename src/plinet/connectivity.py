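"""Phase lag index (PLI) functional connectivity.

The PLI between two channels is the absolute mean sign of the sine of
their instantaneous phase difference,

    PLI = | < sign[ sin(dphi(t_k)) ] > |,

a number in [0, 1] that measures the *asymmetry* of the phase-difference
distribution around 0 mod pi. Phase differences of exactly 0 or pi — the
signature of volume conduction, where one source reaches two electrodes
instantaneously — contribute nothing, so PLI is insensitive to common
sources and to channel amplitude scaling. 0 means no coupling or coupling
centered at 0 mod pi; 1 means perfect locking at a nonzero lag.

Instantaneous phase comes from the Hilbert analytic signal of band-pass
filtered epochs (zero-phase FIR, forward-backward). A small fraction of
samples at each epoch edge is trimmed before evaluating the sign average
to suppress Hilbert boundary distortion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, hilbert
from sklearn.base import BaseEstimator, TransformerMixin

from .io_montage import EpochSet, Montage, Recording, REGIONS, region_channels
from .spectral import BAND_MAP, BandSpec

EDGE_TRIM = 0.05   # fraction of samples dropped at each epoch edge


@dataclass
class ConnectivityMatrix:
    """Symmetric per-epoch PLI matrix over channels."""

    values: np.ndarray
    band: str | None = None
    epoch_index: int | None = None
    labels: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("PLI values must lie in [0, 1]")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _design_bandpass(band: BandSpec, rate: float, n_samples: int):
    """Zero-phase FIR band-pass taps, order ~3 cycles of the low cutoff.

    The order is capped so that filtfilt's forward-backward padding fits in
    the signal; for low bands on short epochs the effective transition
    widens accordingly (filter the continuous recording instead when the
    full order matters).
    """
    if band.hi >= rate / 2:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz at or "
                         f"above Nyquist ({rate / 2} Hz)")
    ntaps = int(round(3 * rate / band.lo))
    ntaps = min(ntaps, max((n_samples - 2) // 3, 11))
    ntaps |= 1   # odd length -> integer group delay, type-I FIR
    taps = firwin(ntaps, [band.lo, band.hi], pass_zero=False, fs=rate,
                  window="hamming")
    return taps


def _filtfilt_fir(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering along the last axis, FFT-based.

    A forward pass with ``taps`` followed by a backward pass equals one
    centered convolution with the correlation kernel taps * reversed(taps)
    (zero net group delay, squared magnitude response). Odd boundary
    extension mirrors scipy's filtfilt padding; FFT convolution keeps long
    low-band filters on long recordings tractable.
    """
    n = x.shape[-1]
    padlen = min(3 * len(taps), n - 1)
    left = 2 * x[..., :1] - x[..., padlen:0:-1]
    right = 2 * x[..., -1:] - x[..., -2:-padlen - 2:-1]
    xp = np.concatenate([left, x, right], axis=-1)
    kernel = np.convolve(taps, taps[::-1])
    shape = (1,) * (x.ndim - 1) + (len(kernel),)
    y = fftconvolve(xp, kernel.reshape(shape), mode="same", axes=-1)
    return y[..., padlen:padlen + n]


def bandpass(epochs: EpochSet, band: BandSpec | str) -> EpochSet:
    """Zero-phase FIR band-pass of every epoch."""
    band = BAND_MAP[band] if isinstance(band, str) else band
    taps = _design_bandpass(band, epochs.rate, epochs.epochs.shape[2])
    filt = _filtfilt_fir(taps, epochs.epochs)
    return EpochSet(epochs=filt, rate=epochs.rate,
                    epoch_length=epochs.epoch_length,
                    labels=list(epochs.labels), band=band.name)


def bandpass_recording(rec: Recording, band: BandSpec | str) -> Recording:
    """Band-pass the continuous recording (full filter order available)."""
    band = BAND_MAP[band] if isinstance(band, str) else band
    taps = _design_bandpass(band, rec.rate, rec.n_samples)
    return Recording(data=_filtfilt_fir(taps, rec.data), rate=rec.rate,
                     labels=list(rec.labels))


def instantaneous_phase(epochs: EpochSet,
                        trim: float = EDGE_TRIM) -> np.ndarray:
    """Hilbert instantaneous phase per epoch and channel, edge-trimmed.

    Returns an array (n_epochs, n_channels, n_kept_samples) of phases
    wrapped to (-pi, pi].
    """
    x = epochs.epochs
    if np.any(np.all(x == 0, axis=2)):
        raise ValueError("all-zero channel: instantaneous phase undefined")
    phases = np.angle(hilbert(x, axis=2))
    k = int(trim * x.shape[2])
    if k:
        phases = phases[:, :, k:-k]
    return phases


def pli_pair(a: np.ndarray, b: np.ndarray) -> float:
    """PLI of two phase series: |mean sign(sin(a - b))|.

    sign(0) contributes 0, so identical series give exactly 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.abs(np.mean(np.sign(np.sin(a - b)))))


def _pli_from_phases(ph: np.ndarray) -> np.ndarray:
    """Full PLI matrix from one epoch's (channels x samples) phase array.

    Uses sin(a - b) = sin(a)cos(b) - cos(a)sin(b) so the transcendentals
    are evaluated once per channel, not per pair.
    """
    n = ph.shape[0]
    s, c = np.sin(ph), np.cos(ph)
    mat = np.zeros((n, n))
    for i in range(n - 1):
        cross = np.sign(s[i] * c[i + 1:] - c[i] * s[i + 1:])
        mat[i, i + 1:] = np.abs(cross.mean(axis=1))
    return mat + mat.T


def pli_matrix(epochs: EpochSet, band: BandSpec | str | None = None,
               trim: float = EDGE_TRIM) -> list[ConnectivityMatrix]:
    """PLI between all channel pairs, one symmetric matrix per epoch.

    If ``band`` is given the epochs are band-pass filtered first; pass
    ``None`` for data that is already band-limited.
    """
    if epochs.n_channels < 2:
        raise ValueError("PLI needs at least 2 channels")
    band_name = epochs.band
    if band is not None:
        epochs = bandpass(epochs, band)
        band_name = epochs.band
    phases = instantaneous_phase(epochs, trim=trim)
    return [ConnectivityMatrix(values=_pli_from_phases(phases[e]),
                               band=band_name, epoch_index=e,
                               labels=list(epochs.labels))
            for e in range(phases.shape[0])]


def _pair_mean(values: np.ndarray, idx: np.ndarray) -> float:
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def summarize_pli(mats: list[ConnectivityMatrix], montage: Montage,
                  mode: str = "within") -> pd.Series:
    """Global and regional mean PLI, averaged across epochs.

    Global = mean over all upper-triangle entries. Regional = mean over
    within-region channel pairs (``mode="within"``) or over pairs linking
    the region to every other channel (``mode="to_rest"``). Regions with
    fewer than 2 channels in the matrix yield NaN.
    """
    if not mats:
        raise ValueError("need at least one connectivity matrix")
    labels = mats[0].labels
    stack = np.mean([m.values for m in mats], axis=0)
    n = stack.shape[0]
    iu = np.triu_indices(n, k=1)
    out = {"all": float(stack[iu].mean())}
    pos = {lab: i for i, lab in enumerate(labels)}
    for region in REGIONS:
        chans = [c for c in region_channels(montage, region) if c in pos]
        idx = np.array([pos[c] for c in chans], dtype=int)
        if len(idx) < 2:
            out[region] = np.nan
        elif mode == "within":
            out[region] = _pair_mean(stack, idx)
        elif mode == "to_rest":
            rest = np.setdiff1d(np.arange(n), idx)
            out[region] = float(stack[np.ix_(idx, rest)].mean())
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.Series(out)


class PLIConnectivity(BaseEstimator, TransformerMixin):
    """Epochs -> stack of per-epoch PLI matrices, as a transformer.

    Parameters
    ----------
    band : str or BandSpec or None
        Band-pass applied before phase extraction; None = input already
        band-limited.
    trim : float
        Fraction of samples trimmed at each epoch edge before the sign
        average (Hilbert boundary guard).
    """

    def __init__(self, band="alpha", trim=EDGE_TRIM):
        self.band = band
        self.trim = trim

    def fit(self, X: EpochSet, y=None):
        self.n_channels_ = X.n_channels
        self.labels_ = list(X.labels)
        return self

    def transform(self, X: EpochSet) -> np.ndarray:
        mats = pli_matrix(X, band=self.band, trim=self.trim)
        return np.stack([m.values for m in mats])
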