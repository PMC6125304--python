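"""Synthetic resting-state EEG cohorts with planted phase coupling.

Every downstream stage (spectral power, phase lag index, minimum spanning
tree topology, group statistics) is validated against recordings whose
ground truth is known by construction: band-limited stochastic carriers,
nonzero-lag coupling planted on a chosen backbone graph, 1/f background
noise, and an optional zero-lag common source mimicking volume conduction.

Carriers are narrow-band filtered white noise, not sinusoids, so the
instantaneous phase wanders and phase-locking estimation is nontrivial.
Coupling is delayed-copy mixing: the receiving channel gets a copy of the
sender's carrier rotated by a fixed phase lag, which controls the planted
phase difference exactly — the quantity PLI measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_montage import Montage, Recording

#: Behavioral score models (mean, SD) per group: reading fluency (words/min),
#: rapid-naming times (s) and a nonverbal-IQ estimate, as published for the
#: adult cohort of 36 typical readers and 28 dyslexics.
BEHAVIORAL_DEFAULTS = {
    "typical": {
        "one_minute_test": (106.67, 8.96),
        "ran_letters": (17.04, 3.48),
        "ran_numbers": (18.71, 3.95),
        "ran_colors": (25.97, 4.67),
        "ran_objects": (29.09, 6.00),
        "ran_total": (22.70, 3.41),
        "raven_iq": (52.19, 4.64),
    },
    "dyslexic": {
        "one_minute_test": (82.32, 14.41),
        "ran_letters": (21.08, 4.56),
        "ran_numbers": (21.14, 3.79),
        "ran_colors": (30.90, 4.59),
        "ran_objects": (35.10, 5.84),
        "ran_total": (27.05, 3.77),
        "raven_iq": (51.96, 5.33),
    },
}

AGE_DEFAULTS = {"typical": (22.22, 2.52), "dyslexic": (23.14, 2.18)}
SEX_MALE_FRACTION = {"typical": 10 / 36, "dyslexic": 13 / 28}


@dataclass
class CouplingSpec:
    """Planted phase-coupling structure for one recording."""

    n_channels: int
    backbone: list[tuple[int, int]]
    lag: float = np.pi / 4
    coupling_strength: float = 0.5
    band: tuple[float, float] = (8.0, 13.0)

    def __post_init__(self):
        for i, j in self.backbone:
            if not (0 <= i < self.n_channels and 0 <= j < self.n_channels):
                raise ValueError(f"backbone edge ({i},{j}) outside channels")
        if not 0 < self.lag % np.pi < np.pi:
            raise ValueError(
                "lag must differ from 0 mod pi: zero/pi-lag coupling is "
                "invisible to the phase lag index by design")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Two-group cohort: recording parameters plus metadata models."""

    n_per_group: tuple[int, int] = (36, 28)   # (typical, dyslexic)
    group_effect: float = 0.1                 # strength shift for dyslexics
    base_strength: float = 0.5
    strength_jitter: float = 0.05             # between-subject SD
    age_range: tuple[float, float] = (18.0, 30.0)
    behavioral_model: dict = field(
        default_factory=lambda: BEHAVIORAL_DEFAULTS)
    n_channels: int = 64
    duration: float = 120.0                   # 30 x 4-s epochs
    rate: float = 1024.0
    band: tuple[float, float] = (8.0, 13.0)
    lag: float = np.pi / 4
    snr: float = 5.0
    topology: str = "random_tree"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValueError("need at least 2 subjects per group")
        for grp in self.behavioral_model.values():
            for _, sd in grp.values():
                if sd <= 0:
                    raise ValueError("behavioral SDs must be positive")


def make_backbone(n_channels: int, topology: str = "random_tree",
                  seed: int | None = None) -> list[tuple[int, int]]:
    """A spanning tree over the channels: the planted coupling graph.

    ``path`` chains 0-1-...-n; ``star`` attaches every node to node 0;
    ``random_tree`` draws a uniformly random labeled tree.
    """
    if n_channels < 2:
        raise ValueError("a backbone needs at least 2 channels")
    if topology == "path":
        return [(i, i + 1) for i in range(n_channels - 1)]
    if topology == "star":
        return [(0, i) for i in range(1, n_channels)]
    if topology == "random_tree":
        tree = nx.random_labeled_tree(n_channels, seed=seed)
        return [tuple(sorted(e)) for e in tree.edges()]
    raise ValueError(f"unknown topology {topology!r}")


def _bandlimited_noise(rng, n_channels, n_samples, rate, band):
    """Unit-variance white noise restricted to [lo, hi) Hz in the spectrum."""
    lo, hi = band
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1 / rate)
    spec[:, (freqs < lo) | (freqs >= hi)] = 0
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_noise(rng, n_channels, n_samples, rate):
    """1/f-power background noise, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1 / rate)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1 / np.sqrt(freqs[1:])   # amplitude 1/sqrt(f) => power 1/f
    x = np.fft.irfft(spec * shaping, n=n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


def _phase_rotate(x: np.ndarray, lag: float) -> np.ndarray:
    """Rotate the instantaneous phase of a band-limited signal by ``lag``."""
    from scipy.signal import hilbert
    return np.real(hilbert(x) * np.exp(-1j * lag))


def simulate_recording(spec: CouplingSpec, duration: float, rate: float,
                       snr: float = 5.0, seed: int | None = None,
                       labels: list[str] | None = None) -> Recording:
    """One multichannel recording with the planted coupling of ``spec``.

    Each channel is a narrow-band carrier plus 1/f noise at the given linear
    signal-to-noise variance ratio. For every backbone edge (i, j), channel
    j's carrier is mixed with a phase-rotated copy of channel i's carrier at
    the coupling strength, so the instantaneous phase difference across the
    edge concentrates at the (nonzero) planted lag. Edges are oriented by
    breadth-first traversal from the lowest-index node so coupling
    propagates along chains.
    """
    n_samples = int(round(duration * rate))
    if n_samples < 2 * rate:
        raise ValueError("duration must cover at least 2 s")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    rng = np.random.default_rng(seed)
    carriers = _bandlimited_noise(rng, spec.n_channels, n_samples, rate,
                                  spec.band)

    g = nx.Graph()
    g.add_nodes_from(range(spec.n_channels))
    g.add_edges_from(spec.backbone)
    s = spec.coupling_strength
    # Mix from the pre-coupling carriers: each child receives its parent's
    # *original* carrier, phase-rotated by the lag. Siblings then share only
    # a zero-lag component (invisible to PLI by construction) and indirect
    # pairs share nothing, so the planted edges are exactly the pairs with
    # a nonzero-lag phase relationship.
    orig = carriers.copy()
    for comp in sorted(nx.connected_components(g), key=min):
        for parent, child in nx.bfs_edges(g, source=min(comp)):
            mixed = (np.sqrt(1 - s ** 2) * orig[child]
                     + s * _phase_rotate(orig[parent], spec.lag))
            sd = mixed.std()
            carriers[child] = mixed / sd if sd > 0 else mixed

    if snr == 0:
        data = _pink_noise(rng, spec.n_channels, n_samples, rate)
    else:
        data = carriers.copy()
        if np.isfinite(snr):
            data += _pink_noise(rng, spec.n_channels, n_samples,
                                rate) / np.sqrt(snr)
    if labels is None:
        labels = [f"ch{i:02d}" for i in range(spec.n_channels)]
    return Recording(data=data, rate=rate, labels=labels)


def inject_common_source(rec: Recording, gain: float,
                         seed: int | None = 0,
                         band: tuple[float, float] = (8.0, 13.0)) -> Recording:
    """Add one shared zero-lag signal to every channel.

    Mimics volume conduction: a single source appearing instantaneously at
    all electrodes. It drives inter-channel amplitude correlation up with
    gain while leaving the phase lag index essentially unchanged, because
    zero-lag (0 mod pi) phase differences carry no sign asymmetry.
    """
    if gain < 0:
        raise ValueError("gain must be nonnegative")
    rng = np.random.default_rng(seed)
    source = _bandlimited_noise(rng, 1, rec.n_samples, rec.rate, band)[0]
    data = rec.data + gain * source
    return Recording(data=data, rate=rec.rate, labels=list(rec.labels))


class CohortRecordings:
    """Lazy per-subject recordings: generated on demand, seed-determined."""

    def __init__(self, spec: CohortSpec, strengths, child_seeds, labels):
        self._spec = spec
        self._strengths = strengths
        self._seeds = child_seeds
        self._labels = labels
        self.backbone = make_backbone(spec.n_channels, spec.topology,
                                      seed=int(child_seeds[-1]))

    def __len__(self):
        return len(self._strengths)

    def __getitem__(self, idx) -> Recording:
        spec = self._spec
        cspec = CouplingSpec(
            n_channels=spec.n_channels, backbone=self.backbone,
            lag=spec.lag, coupling_strength=self._strengths[idx],
            band=spec.band)
        return simulate_recording(cspec, spec.duration, spec.rate,
                                  snr=spec.snr, seed=int(self._seeds[idx]),
                                  labels=self._labels)


def simulate_cohort(spec: CohortSpec):
    """Metadata table plus lazy recordings for a two-group cohort.

    Returns ``(metadata, recordings)``: a DataFrame with one row per subject
    (subject id, group, age, sex, behavioral scores, the planted coupling
    strength) and an indexable lazy sequence of Recordings. Everything is a
    deterministic function of ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = sum(spec.n_per_group)
    child_seeds = rng.integers(0, 2 ** 31 - 1, size=n_total + 1)

    rows = []
    strengths = []
    groups = (["typical"] * spec.n_per_group[0]
              + ["dyslexic"] * spec.n_per_group[1])
    for sid, group in enumerate(groups):
        age_m, age_sd = AGE_DEFAULTS[group]
        age = float(np.clip(rng.normal(age_m, age_sd), *spec.age_range))
        sex = "m" if rng.random() < SEX_MALE_FRACTION[group] else "f"
        effect = spec.group_effect if group == "dyslexic" else 0.0
        strength = float(np.clip(
            spec.base_strength + effect
            + rng.normal(0, spec.strength_jitter), 0, 1))
        row = {"subject": f"sub-{sid:03d}", "group": group,
               "age": age, "sex": sex, "coupling_strength": strength}
        for test, (m, sd) in spec.behavioral_model[group].items():
            row[test] = float(rng.normal(m, sd))
        rows.append(row)
        strengths.append(strength)

    labels = (Montage.biosemi64().labels if spec.n_channels == 64
              else [f"ch{i:02d}" for i in range(spec.n_channels)])
    metadata = pd.DataFrame(rows)
    recordings = CohortRecordings(spec, strengths, child_seeds, labels)
    return metadata, recordings
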