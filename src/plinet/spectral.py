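"""FFT band power, relative power, alpha peak frequency, regional averages.

Power spectra are plain (untapered) periodograms averaged across epochs, so
a 4-s epoch yields the canonical 0.25 Hz bin spacing. Relative power is the
band integral divided by the integral over the analyzed range, 0.5-30 Hz by
default: the union of the four classical bands, which makes the four
fractions a partition summing to one. Band edges are half-open [lo, hi) so
shared boundaries (4, 8, 13 Hz) are never double counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from sklearn.base import BaseEstimator, TransformerMixin

from .io_montage import EpochSet, Montage, REGIONS, region_channels

TOTAL_RANGE = (0.5, 30.0)


@dataclass(frozen=True)
class BandSpec:
    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 < self.lo < self.hi:
            raise ValueError("band requires 0 < lo < hi")


#: The four analyzed frequency bands; gamma is excluded (muscle-artifact
#: contamination and poor graph-metric reliability at scalp level).
BANDS = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)
BAND_MAP = {b.name: b for b in BANDS}


@dataclass
class PowerSpectrum:
    """Per-channel power spectral density on an evenly spaced Hz grid."""

    freqs: np.ndarray
    power: np.ndarray          # channels x freqs, density (uV^2/Hz)
    resolution: float
    labels: list[str]

    def __post_init__(self):
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def fft_power(epochs: EpochSet, window: str = "boxcar") -> PowerSpectrum:
    """Periodogram per epoch, averaged across epochs.

    Frequency spacing is 1/epoch_length (0.25 Hz for 4-s epochs). The
    default boxcar window is the plain FFT periodogram; pass e.g.
    ``"hann"`` to taper.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    freqs, pxx = periodogram(epochs.epochs, fs=epochs.rate, window=window,
                             detrend=False, axis=2)
    return PowerSpectrum(freqs=freqs, power=pxx.mean(axis=0),
                         resolution=1.0 / epochs.epoch_length,
                         labels=list(epochs.labels))


def _band_integral(spec: PowerSpectrum, lo: float, hi: float) -> np.ndarray:
    mask = (spec.freqs >= lo) & (spec.freqs < hi)   # half-open [lo, hi)
    return spec.power[:, mask].sum(axis=1) * spec.resolution


def relative_power(spec: PowerSpectrum, band: BandSpec,
                   total_range: tuple[float, float] = TOTAL_RANGE
                   ) -> np.ndarray:
    """Band power as a fraction of total power over ``total_range``."""
    lo, hi = total_range
    if band.lo < lo or band.hi > hi:
        raise ValueError(f"band {band.name} outside total range {total_range}")
    total = _band_integral(spec, lo, hi)
    if np.any(total <= 0):
        raise ValueError("zero total power in the analyzed range")
    return _band_integral(spec, band.lo, band.hi) / total


def alpha_peak(spec: PowerSpectrum,
               search_range: tuple[float, float] = (6.5, 12.0)
               ) -> np.ndarray:
    """Individual alpha peak frequency per channel, NaN when absent.

    The maximum inside the search range only counts as a peak if it is a
    local maximum of the spectrum (strictly above both neighboring bins);
    monotone 1/f-like spectra therefore report no peak rather than the
    range edge.
    """
    lo, hi = search_range
    idx = np.flatnonzero((spec.freqs >= lo) & (spec.freqs <= hi))
    if idx.size == 0:
        raise ValueError("search range outside the spectrum")
    out = np.full(spec.power.shape[0], np.nan)
    for ch in range(spec.power.shape[0]):
        p = spec.power[ch]
        k = idx[np.argmax(p[idx])]
        if 0 < k < len(p) - 1 and p[k] > p[k - 1] and p[k] > p[k + 1]:
            out[ch] = spec.freqs[k]
    return out


def regional_average(values: pd.Series, montage: Montage,
                     split_hemisphere: bool = False) -> pd.Series:
    """Mean of a per-channel quantity over each scalp region.

    ``values`` is indexed by channel label. Returns region means plus a
    global all-channel mean under the key ``"all"``; with
    ``split_hemisphere`` each region contributes separate left/right means
    (midline sites are excluded from the hemisphere split).
    """
    missing = [c for c in montage.labels if c not in values.index]
    if missing:
        raise KeyError(f"channels missing from table: {missing}")
    out = {"all": float(values.loc[list(montage.labels)].mean())}
    for region in REGIONS:
        if split_hemisphere:
            for hemi in ("left", "right"):
                chans = region_channels(montage, region, hemi)
                out[f"{region}_{hemi}"] = float(values.loc[chans].mean())
        else:
            chans = region_channels(montage, region)
            out[region] = float(values.loc[chans].mean())
    return pd.Series(out)


class BandPowerExtractor(BaseEstimator, TransformerMixin):
    """Relative band power features from epoched recordings.

    Transforms an EpochSet (or an array of shape
    ``(n_epochs, n_channels, n_samples)`` with ``rate``) into a vector of
    per-channel relative power values for each analyzed band, suitable for
    sklearn pipelines operating on one subject at a time.

    Parameters
    ----------
    bands : sequence of BandSpec
        Bands to extract; defaults to delta/theta/alpha/beta.
    total_range : (float, float)
        Normalization range in Hz for relative power.
    window : str
        Periodogram taper; boxcar = plain FFT.
    """

    def __init__(self, bands=BANDS, total_range=TOTAL_RANGE,
                 window="boxcar"):
        self.bands = bands
        self.total_range = total_range
        self.window = window

    def fit(self, X, y=None):
        self.n_bands_ = len(self.bands)
        return self

    def transform(self, X: EpochSet) -> pd.DataFrame:
        spec = fft_power(X, window=self.window)
        cols = {b.name: relative_power(spec, b, self.total_range)
                for b in self.bands}
        return pd.DataFrame(cols, index=spec.labels)
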