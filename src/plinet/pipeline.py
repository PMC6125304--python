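"""End-to-end orchestration: recordings -> per-subject metric table -> stats.

Per subject and band: average reference, zero-phase band-pass of the
continuous recording, contiguous 4-s epoching, per-epoch PLI matrices,
MST and (optionally) weighted graph metrics averaged across epochs,
relative band power and alpha peak frequency. The per-subject rows joined
to the cohort metadata form the metric table consumed by the statistics
layer.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from . import connectivity, graph_metrics, spectral, stats
from .io_montage import Montage, Recording, apply_average_reference, \
    segment_epochs

#: Metrics entering the group comparison, as printed for the alpha band.
STAT_METRICS = ("degree", "leaf", "diameter", "eccentricity", "bc",
                "tree_hierarchy", "degree_correlation", "kappa", "mst_mean")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved analysis settings; serializable for reproducible reruns."""

    bands: tuple[str, ...] = ("delta", "theta", "alpha", "beta")
    epoch_length: float = 4.0
    n_epochs: int = 30
    total_range: tuple[float, float] = spectral.TOTAL_RANGE
    trim: float = connectivity.EDGE_TRIM
    weighted: bool = True
    modularity_method: str = "greedy"
    seed: int = 0

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as f:
            raw = json.load(f)
        raw["bands"] = tuple(raw["bands"])
        raw["total_range"] = tuple(raw["total_range"])
        return cls(**raw)


def analyze_recording(rec: Recording, config: PipelineConfig | None = None
                      ) -> pd.DataFrame:
    """One subject's per-band metric rows (one row per frequency band)."""
    config = config or PipelineConfig()
    rec = apply_average_reference(rec)

    # spectral features from the unfiltered (referenced) recording
    raw_epochs = segment_epochs(rec, config.epoch_length, config.n_epochs)
    spec = spectral.fft_power(raw_epochs)
    peaks = spectral.alpha_peak(spec)
    peak = float(np.nanmedian(peaks)) if np.any(np.isfinite(peaks)) else np.nan

    rows = []
    for band_name in config.bands:
        band = spectral.BAND_MAP[band_name]
        filtered = connectivity.bandpass_recording(rec, band)
        epochs = segment_epochs(filtered, config.epoch_length,
                                config.n_epochs)
        epochs.band = band_name
        mats = connectivity.pli_matrix(epochs, band=None, trim=config.trim)
        row = graph_metrics.subject_metrics(
            mats, weighted=config.weighted,
            modularity_method=config.modularity_method)
        row["band"] = band_name
        row["rel_power"] = float(
            spectral.relative_power(spec, band, config.total_range).mean())
        row["alpha_peak"] = peak
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_cohort(metadata: pd.DataFrame, recordings,
                   config: PipelineConfig | None = None) -> pd.DataFrame:
    """Metric table for a whole cohort: one row per subject per band."""
    config = config or PipelineConfig()
    frames = []
    for idx, meta_row in metadata.reset_index(drop=True).iterrows():
        frame = analyze_recording(recordings[idx], config)
        for col in metadata.columns:
            frame[col] = meta_row[col]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def band_statistics(metric_table: pd.DataFrame, band: str,
                    metrics=STAT_METRICS, covariates: bool = True,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Group-comparison table for one band of a cohort metric table."""
    sub = metric_table[metric_table["band"] == band]
    missing = sub[list(metrics)].columns[sub[list(metrics)].isna().all()]
    usable = [m for m in metrics if m not in set(missing)]
    return stats.group_compare_table(sub.reset_index(drop=True), usable,
                                     covariates=covariates, alpha=alpha)
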