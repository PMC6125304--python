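# Methods

This note documents the models, numerical choices and limitations behind
the package, in the spirit of the methods appendices of mature scientific
Python libraries. It states no empirical result that the test suite or
the acceptance script does not itself compute.

## Signal model and preprocessing

A recording is a channels × samples matrix in microvolts with a sampling
rate and unique channel labels. The analysis montage is the 64-channel
extended 10–20 layout with the four scalp-region groups used for
regional sub-averages: frontal (14 sites), central (18), temporal (6),
parieto-occipital (16). The remaining 10 midline (z-suffix) sites carry
no region. Hemisphere assignment follows the 10–20 numbering convention
(odd = left, even = right); midline electrodes are excluded from
hemisphere splits, since the source protocol does not state whether they
entered the lateralization analysis.

Average referencing subtracts the instantaneous mean across channels; it
is idempotent and leaves every sample's cross-channel mean at zero.
Epochs are contiguous and non-overlapping from the start of the selected
segment: the default analysis uses 30 epochs of 4 s, the compromise
epoch length at which PLI-based tree metrics are reported to be stable.

**Band-pass filtering.** Zero-phase FIR (Hamming design, forward-backward
`filtfilt`), nominal order three cycles of the band's low cutoff. On a
4-s epoch at 1024 Hz the delta band (0.5 Hz) would demand 6145 taps —
longer than the epoch — so the order is capped so the forward-backward
padding fits inside the signal; the delta transition band widens
accordingly. The pipeline therefore filters the *continuous* recording
before epoching (`bandpass_recording`), where the full order fits; the
per-epoch `bandpass` exists for pre-cut data and matches the nominal
design whenever the epoch is long enough.

## Spectral power

Power spectra are plain (boxcar) periodograms per epoch, averaged across
epochs, giving exactly 1/epoch_length frequency resolution (0.25 Hz for
4-s epochs); a taper is available but off by default since the plain FFT
matches the stated resolution. Relative power divides the band integral
by the integral over 0.5–30 Hz — the union of the four analyzed bands,
chosen so the four fractions form a partition summing to one (the
originating protocol never defines "total power"; gamma is excluded
because scalp gamma is dominated by muscle artifact). Band edges are
half-open [lo, hi) so the shared boundaries 4, 8, 13 Hz are counted
once. The individual alpha peak is the spectral maximum within
6.5–12 Hz, accepted only if it is a strict local maximum; monotone
1/f-like spectra report "no peak" (NaN) rather than a range edge.

## Phase lag index

Phases come from the analytic (Hilbert) signal of each band-limited
epoch. Five percent of samples are trimmed at each epoch edge before the
sign average: the Hilbert transform's circular-convolution boundary
distortion otherwise leaks into the phase series, and with trimming a
constant π/2 phase offset yields PLI = 1 exactly. `sign(0)` is defined
as 0, so identical channels give PLI = 0 exactly — the degenerate
volume-conduction case. PLI is invariant to channel amplitude scaling
and, within sampling noise, to the addition of any common zero-lag
signal; both properties are enforced by tests. Regional connectivity
averages within-region channel pairs (region-to-rest averaging is
exposed as an option); arithmetic means across epochs and across pairs
commute, so the order of those two averages is immaterial.

The narrow-band null level deserves a note: for band-limited signals the
phase-difference series is strongly autocorrelated, so the effective
number of independent samples is roughly duration × bandwidth, not the
sample count. At 4-s alpha-band epochs the null PLI is therefore ≈ 0.15,
not 1/√4096; epoch averaging stabilizes but does not shrink this floor
(the absolute value is taken per epoch). Planted couplings must clear
this floor, which the defaults do by a factor of ~2.

## Minimum spanning tree metrics

The MST minimizes total 1 − PLI (Kruskal), hence maximizes total PLI.
Weight ties are broken deterministically by lexicographic edge order
under a stable sort. Construction and tree betweenness go through
networkx; tests verify them against exhaustive spanning-tree enumeration
(N ≤ 7) and brute-force path counting, which are independent of that
route.

Printed-scale normalizations, following the conventions of the MST/EEG
literature: degree = k_max/m, leaf = L/m, diameter = d/m, eccentricity =
mean nodal eccentricity/m, BC = max pair-normalized betweenness. Mean
MST degree is the constant 2m/N, so a *mean*-degree statistic would be
uninformative — the maximum is what varies; raw values are always
carried alongside so any alternative convention can be recovered. Tree
hierarchy is T_h = L/(2·m·BC_max); for N = 2 (BC_max = 0) it is NaN, as
is the degree correlation (zero degree variance), rather than a
fabricated value. Degree correlation is the Pearson correlation of
endpoint degrees with each undirected edge counted in both orientations
(standard assortativity). κ = ⟨k²⟩/⟨k⟩ over nodes.

Weighted-graph metrics: Lw averages shortest-path lengths with edge
length 1/PLI (zero-weight edges absent; a disconnected graph — which
cannot arise from a PLI matrix with positive entries — falls back to the
harmonic-mean convention with a warning). Cw is the triple-product
weighted clustering C_i = Σ w_ik w_il w_kl / Σ w_ik w_il (the variant
that reduces to w on a constant-weight complete graph); this is a
different statistic from the geometric-mean clustering in networkx,
hence implemented directly. Modularity Q is maximized by exhaustive
partition search for N ≤ 10 and by deterministic greedy agglomeration
(Clauset–Newman–Moore) above; the returned Q always equals the direct
evaluation of Newman's formula on the returned partition.

## Synthetic cohorts

The generator emulates the stated acquisition: 64 channels, 1024 Hz,
120 s (30 × 4-s epochs). Carriers are narrow-band filtered white noise —
not sinusoids, whose constant phase would make every estimator
degenerate — plus 1/f-power background noise at a linear SNR (default
5, a moderately clean resting recording; variance ratio carrier:noise).
Coupling is delayed-copy mixing on a backbone spanning tree: each child
channel mixes √(1−s²) of its own carrier with s times its parent's
carrier rotated by the lag (default π/4, safely away from the 0/π blind
spots; lags of 0 mod π are rejected because PLI cannot see them).
Mixing sources are the *pre-coupling* carriers, so siblings share only a
zero-lag component (invisible to PLI by design) and indirect pairs share
nothing: the planted edges are exactly the pairs with a nonzero-lag
phase relationship, which is what makes backbone recovery a meaningful
benchmark. The limiting case strength = 1 makes a child a pure rotated
copy of its parent's original carrier (PLI → 1 on a single edge); in
deep trees at strength exactly 1 the parent's own carrier vanishes from
its output, so recovery is specified for strengths ≤ 0.9.

Cohort metadata draws group sizes 36/28, ages (22.22 ± 2.52 vs
23.14 ± 2.18 years), sex ratios (10:26 vs 13:15 m:f) and seven
behavioral scores from the published sample table, as independent
normals per test — the table reports no between-test correlations, so
none are modeled. The "dyslexic-like" group adds a coupling-strength
shift (default +0.1) on top of a base strength 0.5 with ±0.05
between-subject jitter; these defaults put the simulated global alpha
PLI in the ~0.15–0.2 range of the published group means and give the
group statistics something detectable without being trivial. Everything
is a deterministic function of the cohort seed; recordings are generated
lazily per subject to keep 64-subject cohorts within memory.

What the generator does **not** emulate: volume conduction through a
head model (only the single common zero-lag source), artifacts (blinks,
muscle), nonstationarity, realistic cross-frequency structure, or
correlated behavioral scores. A green pipeline test therefore
establishes correctness of the estimators on their own model, not
clinical validity on real EEG.

## Statistics

One-way ANOVA uses the classical between/within decomposition with
η² = SSB/SST; an algebraically identical reconstruction from per-group
means, SDs and sizes supports worked examples from published summary
tables (agreement with published F values is limited by the rounding of
the printed summaries, at the few-tenths-of-a-percent level). The
covariate-adjusted comparison is a general linear model F test of the
group factor given age and sex (binary indicator), i.e. a partial
(type-III style) test, with partial η². Age regressions report R = |r|
with the sign carried by β and t, matching the reporting convention of
the source literature; p-values are two-sided throughout. A natural-log
transform of metrics is available as a control-analysis toggle.

Multiple testing across the nine correlated tree metrics uses Nyholt's
spectral M_eff = 1 + (M−1)(1 − Var(λ)/M) with the sample (M−1) variance
denominator, which gives exactly 1 for perfectly correlated metrics and
M for independent ones; the corrected threshold is α/M_eff.

## Acceptance benchmarks and scale

The acceptance script recomputes only analytic, seed-robust targets
(PLI boundary cases and MST structural bounds on 64-node matrices). The
headline group differences of the originating study are functions of its
undeposited raw EEG and are deliberately not "reproduced"; the published
summary statistics serve as generator calibration and worked examples
instead. Property suites in the test suite run the simulator at 256 Hz
rather than 1024 Hz: PLI's effective sample count scales with duration ×
bandwidth, not sampling rate, so this preserves the statistical regime
while keeping the suite inside a desktop time budget.
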