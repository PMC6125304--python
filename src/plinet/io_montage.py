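"""Recording and montage handling.

Reads and writes multichannel EEG as plain ASCII matrices or EDF/BDF files,
applies the common average reference, cuts contiguous fixed-length epochs,
and resolves the scalp-region channel groups (frontal, central, temporal,
parieto-occipital) of the extended 10-20 montage used for the regional
power and connectivity sub-averages.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from . import _edf

REGIONS = ("frontal", "central", "temporal", "parieto-occipital")


@dataclass
class Recording:
    """A continuous multichannel EEG recording.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling frequency in Hz.
    labels : list of str
        Channel names, one per row of ``data``.
    """

    data: np.ndarray
    rate: float
    labels: list[str]

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EpochSet:
    """Fixed-length epochs cut from one recording.

    ``epochs`` has shape (n_epochs, n_channels, samples_per_epoch) and
    ``epoch_length * rate`` equals the samples per epoch exactly.
    """

    epochs: np.ndarray
    rate: float
    epoch_length: float
    labels: list[str] = field(default_factory=list)
    band: str | None = None

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n_epochs, channels, samples)")
        if abs(self.epoch_length * self.rate - self.epochs.shape[2]) > 1e-9:
            raise ValueError("epoch_length x rate must equal samples per epoch")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class Montage:
    """Channel layout with scalp-region and hemisphere assignments."""

    labels: list[str]
    region_map: dict[str, str]
    hemisphere_map: dict[str, str]

    @classmethod
    def biosemi64(cls) -> "Montage":
        """The 64-channel extended 10-20 layout with its four region groups."""
        res = importlib.resources.files("plinet.data") / "montage_biosemi64.tsv"
        labels, regions, hemis = [], {}, {}
        lines = res.read_text().strip().splitlines()[1:]
        for line in lines:
            lab, region, hemi = line.split("\t")
            labels.append(lab)
            if region != "none":
                regions[lab] = region
            hemis[lab] = hemi
        return cls(labels=labels, region_map=regions, hemisphere_map=hemis)


def load_ascii_recording(path, rate: float, labels: list[str], *,
                         channels_as_rows: bool = True,
                         delimiter: str | None = None) -> Recording:
    """Load a whitespace/comma-delimited numeric matrix as a Recording.

    Delimiter is auto-detected among tab, comma and whitespace unless given.
    Set ``channels_as_rows=False`` for samples-as-rows files (transposed).
    """
    with open(path) as f:
        first = f.readline()
    if delimiter is None:
        delimiter = "," if "," in first else None  # None = any whitespace
    try:
        mat = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"malformed ASCII matrix in {path}: {exc}") from exc
    if not channels_as_rows:
        mat = mat.T
    return Recording(data=mat, rate=rate, labels=list(labels))


def save_ascii_recording(rec: Recording, path, *, delimiter: str = "\t") -> None:
    np.savetxt(path, rec.data, delimiter=delimiter, fmt="%.10g")


def load_edf_recording(path) -> Recording:
    """Load an EDF (16-bit) or Biosemi BDF (24-bit) file."""
    data, rate, labels = _edf.read(path)
    return Recording(data=data, rate=rate, labels=labels)


def save_edf_recording(rec: Recording, path, *, bdf: bool = False) -> None:
    _edf.write(path, rec.data, rec.rate, rec.labels, bdf=bdf)


def apply_average_reference(rec: Recording) -> Recording:
    """Re-reference to the average of all channels.

    After referencing, the mean across channels is zero at every sample.
    Idempotent.
    """
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return Recording(data=data, rate=rec.rate, labels=list(rec.labels))


def segment_epochs(rec: Recording, epoch_length: float,
                   n_epochs: int) -> EpochSet:
    """Cut ``n_epochs`` contiguous, non-overlapping epochs from the start."""
    spe = int(round(epoch_length * rec.rate))
    needed = spe * n_epochs
    if needed > rec.n_samples:
        raise ValueError(
            f"need {needed} samples for {n_epochs} epochs of {epoch_length} s, "
            f"recording has {rec.n_samples}")
    cut = rec.data[:, :needed].reshape(rec.n_channels, n_epochs, spe)
    return EpochSet(epochs=np.transpose(cut, (1, 0, 2)), rate=rec.rate,
                    epoch_length=epoch_length, labels=list(rec.labels))


def region_channels(montage: Montage, region: str,
                    hemisphere: str | None = None) -> list[str]:
    """Channels of one scalp region, optionally one hemisphere.

    Left/right follows the 10-20 convention: odd-numbered sites are left,
    even-numbered right; midline (z) sites never belong to a region group.
    """
    if region not in REGIONS:
        raise KeyError(f"unknown region {region!r}; expected one of {REGIONS}")
    chans = [c for c in montage.labels if montage.region_map.get(c) == region]
    if hemisphere is not None:
        if hemisphere not in ("left", "right"):
            raise KeyError(f"unknown hemisphere {hemisphere!r}")
        chans = [c for c in chans if montage.hemisphere_map[c] == hemisphere]
    return chans
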