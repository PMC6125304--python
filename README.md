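# plinet

Resting-state EEG functional-connectivity and network-topology analysis:
phase lag index (PLI) connectivity, minimum spanning tree (MST) graph
metrics, band-limited spectral power, and the group/regression statistics
used to compare clinical and control cohorts (e.g. adult dyslexics vs
typical readers). Because raw clinical EEG of this kind is rarely shareable,
the package ships a synthetic cohort generator that plants known
phase-coupling structure, so every stage of the pipeline can be validated
against ground truth.

## The method

For each subject, a 4-min eyes-open recording (64-channel extended 10–20
montage) is average-referenced, band-pass filtered into delta (0.5–4 Hz),
theta (4–8 Hz), alpha (8–13 Hz) and beta (13–30 Hz), and cut into 30
contiguous 4-s epochs. Per epoch and band, functional connectivity between
every electrode pair is the **phase lag index**

PLI = | ⟨ sign[ sin(Δφ(t_k)) ] ⟩ |,

with Δφ the Hilbert instantaneous phase difference. PLI ∈ [0, 1] measures
the asymmetry of the phase-difference distribution around 0 mod π: common
sources reaching two electrodes instantaneously (volume conduction)
produce 0-mod-π differences and are ignored by construction.

From each PLI matrix the **minimum spanning tree** on link weights 1 − PLI
(Kruskal) extracts the strongest-connectivity backbone — always N − 1
links, so tree topology can be compared across groups without
edge-density bias. Nine metrics summarize each tree: maximal degree, leaf
fraction L, diameter d (bounded by d ≤ m − L + 2), mean eccentricity,
maximal betweenness centrality BC, tree hierarchy T_h = L/(2·m·BC_max),
degree correlation R, degree divergence κ = ⟨k²⟩/⟨k⟩, and the mean PLI of
tree links. The full weighted graph additionally yields path length Lw
(edge length 1/PLI), weighted clustering Cw and Newman modularity Q.

Metrics are averaged across epochs per subject and compared between
groups by one-way ANOVA / ANCOVA (age and sex covariates), regressed on
age, and corrected for multiple testing with Nyholt's effective number of
independent tests M_eff derived from the metric correlation matrix
(α_corrected = α / M_eff, e.g. 0.05/4 ≈ 0.012).

## Worked example

```python
from plinet import (CohortSpec, simulate_cohort, analyze_cohort,
                    band_statistics, PipelineConfig)

spec = CohortSpec(n_per_group=(12, 12), n_channels=16, duration=64.0,
                  rate=256.0, group_effect=0.2, seed=7)
meta, recs = simulate_cohort(spec)
cfg = PipelineConfig(bands=("alpha",), n_epochs=16, weighted=False)
table = analyze_cohort(meta, recs, cfg)
print(table.groupby("group")[["mean_pli", "kappa", "mst_mean"]].mean().round(3))
st = band_statistics(table, "alpha",
                     metrics=("degree", "leaf", "kappa", "mst_mean"))
print(st.round(4).to_string(index=False))
```

prints

```
          mean_pli  kappa  mst_mean
group
dyslexic     0.207  2.399     0.510
typical      0.196  2.373     0.470
  metric       F  df1  df2      p   eta2  significant_corrected
  degree  2.6674    1   20 0.1181 0.1177                  False
    leaf  0.6757    1   20 0.4208 0.0327                  False
   kappa  2.5781    1   20 0.1240 0.1142                  False
mst_mean 43.9244    1   20 0.0000 0.6871                   True
```

The "dyslexic-like" group was simulated with a +0.2 shift in planted
coupling strength; the pipeline recovers it as higher mean PLI and a
strongly significant group effect on MST mean connectivity (the mean PLI
over backbone links), while purely topological metrics move less — the
expected signature of a strength (rather than reorganization) effect.
`significant_corrected` applies the Nyholt-corrected threshold computed
from these four metrics' own correlations.

The same pipeline is scriptable from a shell:

```sh
plinet simulate --out cohort/ --seed 1 --n-typical 36 --n-dyslexic 28
plinet analyze  --in cohort/ --out results/ --band alpha
```

## Estimator API

The transform-shaped stages are scikit-learn transformers and compose
with sklearn pipelines: `BandPowerExtractor` (epochs → relative band
power), `PLIConnectivity` (epochs → per-epoch PLI matrix stack) and
`MSTFeatureExtractor` (matrix stacks → per-subject network features).
Module-level functions (`pli_pair`, `mst_kruskal`, `tree_metrics`, …)
expose the same computations directly.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
regenerates the analytic benchmark quantities from scratch by running the
package: the PLI of a synthesized alpha-band pair locked at a constant
π/2 lag, the PLI of a channel against itself (the volume-conduction
degenerate case), and the leaf count and diameter of MSTs built from
chain- and star-structured 64-node connectivity matrices, writing the
measured values as JSON.
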