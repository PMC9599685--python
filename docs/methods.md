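# Methods

This note documents the models, conventions, parameter choices, and
known limitations behind `aimnet`. It describes what the code computes;
every empirical figure mentioned here is produced by the test suite or
by `scripts/acceptance.py`, not asserted from elsewhere.

## Study design emulated

The package targets a repeated-measures marksmanship design: 30
right-handed skilled shooters fire two sets of 30 shots under each of
three conditions — control, 70 dB noise disturbance, and 25 lx weak
light — while 30-channel 10–20 EEG (A1/A2 mastoid references excluded
from analysis) is recorded at 1000 Hz with a trigger marking each shot,
preceded by 2.5 min eyes-closed and 2.5 min eyes-open resting runs.
Performance is the ring score per shot, 5–10 for hits and 0 for a miss.
The montage deliberately contains 30 analysis channels; the acquisition
list of 32 includes the two reference electrodes.

The analysis asks whether preparation-stage (aiming-window) functional
connectivity and network topology differ between conditions, and
whether they correlate with mean performance.

## Synthetic cohort generator

Real recordings for such designs are rarely shareable, so the generator
is a first-class module: it produces cohorts whose every downstream
quantity is planted and recorded in a ground-truth manifest.

**Background.** Each channel is independent 1/f^α noise (α = 1 by
default), scaled to 12 µV standard deviation — typical scalp EEG
magnitude, and comfortably below the 150 µV rejection threshold even at
the extremes of a 3 s, 30-channel window.

**Coupling.** A coupled pair shares a unit-variance narrowband
oscillator (white noise masked to the band in the frequency domain).
Channel A receives the oscillator, channel B a copy delayed by
`lag / (2π f_center)` seconds, applied as an exact fractional delay in
the frequency domain, so the pair carries a genuine, sign-consistent
phase lag across the band. Mixing is `x → √(1−s²)·x + s·σ·osc` with
strength `s ∈ [0, 1]`: WPLI is monotone in `s` (measured ≈ 0.33 / 0.91 /
1.00 at s = 0.2 / 0.5 / 0.9 with 20 trials), saturating as the in-band
oscillator dominates the in-band share of the 1/f background. A
condition effect is planted by adding `condition_effect_delta` to `s`
in the flagged condition only. Per-subject strength jitter (SD 0.12)
provides the between-subject variance that condition contrasts and
performance correlations operate on.

**Volume-conduction surrogate.** One broadband 1/f source is added with
zero lag and channel-specific gains (uniform 0.5–1.5 × a global gain).
Because its imaginary cross-spectrum is identically zero, it must not
create WPLI; it can only dilute existing lagged coupling by inflating
⟨|Im S|⟩, which the tests document (no inflation, small attenuation at
moderate gain).

**Alpha peak.** Eyes-closed resting segments add an amplitude-modulated
sinusoid at the subject's IAF on O1/O2/Oz (15 µV, 0.1 Hz modulation).
IAFs are drawn from N(10, 1) Hz, snapped to the 0.5 Hz estimation grid
and clipped to [8.5, 11.5] so the peak lies strictly inside the 8–12 Hz
search band.

**Artifacts.** Contaminated trials receive a 100 ms raised-cosine pulse
of 500 µV on six random channels, centered 1.5 s before the shot —
unambiguous against the ~12 µV background and squarely inside the
aiming window, so threshold rejection can be verified against the list
of planted trials.

**Scores.** Ring scores are drawn through a discretized Gaussian
copula. The latent score is `µ* + sd·g + shot_noise`, where `g` mixes
the subject's coupling-strength perturbation with independent noise at
the configured Spearman ρ, and the latent mean µ* is solved by
root-finding so that the *discretized* {0, 5..10} expectation equals the
configured observed group mean (control 8.02 ± 0.76, noise 8.00 ± 0.81,
weak light 5.38 ± 1.56). Rounding maps latent values below 4.5 to 0
(miss) and clips at 10.

**Determinism.** All randomness flows from `SeedSequence(seed,
spawn_key=(subject, stream))`, so a subject's data is bit-identical
regardless of cohort size or generation order, and identical configs
yield identical output bytes.

What the generator does **not** emulate: volume conduction with a
realistic lead field, non-stationary rhythms, eye-blink/EMG waveform
morphology, channel-specific spectra, or learning/fatigue effects on
scores. Passing tests therefore demonstrate correctness of the
estimators under a known signal model, not robustness to every artifact
of real EEG.

## Preprocessing

- **Filtering.** Order-1000 FIR band-pass (0.1–50 Hz analysis band;
  per-band filters for theta/alpha/beta), applied zero-phase as one
  frequency-domain convolution with the filter's autocorrelation (the
  exact forward–backward |H|² response), with odd-symmetric edge
  padding. Zero phase matters because phase distortion would bias WPLI.
  The per-channel mean is subtracted first: DC lies inside the
  transition band of any realizable FIR with a 0.1 Hz edge, so offsets
  are removed exactly rather than left to the stopband. Inputs shorter
  than 3×order+1 samples are rejected with the minimum named.
- **Pipeline precision.** The orchestrated pipeline filters in float32;
  the induced error (~10⁻⁶ relative) is orders of magnitude below the
  Monte-Carlo uncertainty of any trial-averaged estimate. Direct calls
  preserve the input dtype, and all oracle tests run in float64.
- **Segmentation.** Trials are cut −5..+2 s around each shot (the
  generator guarantees the margins), rejected once on the broadband
  data, and the aiming (−3..0 s, 3000 samples) and baseline (−4..−3 s)
  sub-windows are sliced from the retained trials, so both share
  identical rejection. Epoching is index-exact: trial t, sample 0 is
  event_t − 3 s.
- **Artifact rejection** is a per-trial max-channel peak-to-peak
  threshold (150 µV default). The emulated workflow used a toolbox
  whose criterion is unspecified; a deterministic amplitude rule is the
  testable surrogate, and every report names it.
- **IAF.** Welch spectra of the eyes-closed segment (2 s Hann segments,
  50 % overlap → 0.5 Hz grid) averaged over O1/O2/Oz; IAF is the grid
  argmax in [8, 12] Hz, ties broken toward the lower frequency. If the
  chosen bin is not a local maximum of the spectrum the estimate is
  still returned but flagged and a warning emitted.
- **Bands.** theta [IAF−6, IAF−3], alpha [IAF−2, IAF+2], beta
  [IAF+3, 30] Hz. The 30 Hz beta ceiling is the conventional upper
  edge, consistent with a 40 Hz acquisition low-pass and the 50 Hz
  analysis filter.

## Connectivity

WPLI for a pair (x, y) uses the Hilbert analytic signals of the
band-filtered trials with 10 % of samples discarded at *each* end
(edge-effect trimming; the retained length is
⌊n(1 − 2·trim)⌋, so 3000 → 2400):

    WPLI = |⟨ |Im S| · sign(Im S) ⟩| / ⟨ |Im S| ⟩ ,  S(t) = a_x(t)·conj(a_y(t))

The numerator simplifies algebraically to |⟨Im S⟩|; the implementation
uses the simplified form and the test suite checks the literal
transcription against it to 10⁻¹². ⟨·⟩ is the time average within a
trial, and trial-level WPLI values are averaged across trials
(`wpli_average="within_trial"`, the default, matching a data layout
with an explicit trial dimension); pooling all trials' samples into one
expectation is available as `"pooled"`. Pairs whose |Im S| average is
numerically zero relative to the cross-spectral power (identical
signals, pure zero-lag coupling) are set to 0 by convention, with a
relative tolerance of 10⁻⁹.

ERWPLI is `(W − R) / max(R, 10⁻⁶)` elementwise, where R is the WPLI
matrix of the −4..−3 s baseline computed with identical trimming,
averaging, and rejection. The floor guards division by a zero baseline;
floored entries are counted and surfaced in the run manifest. Values
are ≥ −1 by construction and unbounded above.

## Network topology

The WPLI matrix is used directly as a weighted adjacency — no
threshold, every connection retained. Conventions follow the common
weighted brain-connectivity definitions:

- **Clustering** (Onnela): C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} /
  (k_i(k_i−1)) with ŵ = w / max(w); the average is over nodes with
  degree ≥ 2.
- **Paths**: edge length 1/w (zero weight = no edge), all-pairs
  Dijkstra; characteristic path length is the mean finite distance over
  ordered pairs (infinite pairs excluded and counted); global
  efficiency is the mean inverse distance with 1/∞ = 0.
- **Local efficiency** of node i: global efficiency of the subgraph
  induced on i's neighbors; 0 with fewer than two neighbors.
- **Eigenvector centrality**: leading eigenvector of the raw weight
  matrix by power iteration on A + max(w)·I (the shift leaves
  eigenvectors unchanged but makes the Perron root strictly dominant,
  so bipartite spectra cannot stall the iteration), relative tolerance
  10⁻¹⁰, cap 10⁴ iterations; entries non-negative, unit Euclidean
  norm. Disconnected graphs use the largest component, flagged.

Because the emulated workflow names only its toolbox, not formulas,
absolute metric values depend on these conventions; rank-based
contrasts and correlations do not. Correctness rests on independent
oracles: exhaustive path enumeration, dense eigendecomposition, and
networkx cross-checks, at 10⁻⁸.

## Group statistics

- **K–S screening**: one-sample Kolmogorov–Smirnov against a normal
  with the sample's mean and SD, asymptotic p. It is reported only —
  the pipeline always proceeds nonparametrically.
- **Wilcoxon rank-sum**, two-sided: exact p by full enumeration of rank
  assignments when n_a + n_b ≤ 12 with no ties; otherwise the normal
  approximation with midranks, tie correction, and continuity
  correction. The contrasts are unpaired, replicating the emulated
  workflow even though the design is within-subject; a paired
  signed-rank alternative is available (`paired=True`, off by default).
- **Spearman** rank correlation with the t-approximation (n−2 d.f.).
- **FDR**: Benjamini–Hochberg step-up. The family is all features of
  one type within one band and one contrast (435 edges; 30 nodes; one
  feature set per correlation call) — the most common reading of a
  per-band reporting structure; family boundaries are visible in the
  outputs, and both raw and adjusted p-values are carried everywhere.
  Significance tiers 0.05 and 0.01 are flagged.

## Pipeline, regions, provenance

`run_all` chains simulate → preprocess → connectivity → metrics → stats
and writes plain CSV/TSV/JSON. The region map groups the montage into
frontal, fronto-central, central, left/right temporal, centro-parietal,
parietal, and occipital sets (standard 10–20 laterality; narrative
attributions that swap sides in the source material are not followed).
The manifest records the config hash, seed, per-file SHA-256 checksums,
and one entry per warning-producing event (trials rejected, IAF
fallback, ERWPLI floor). Identical (config, seed) reproduces identical
bytes.

## Problem sizes used by tests and the acceptance script

Full-scale cohorts (30 subjects × 3 conditions × 60 shots) are
supported through the CLI; the shipped checks run the same code at
reduced, documented scales chosen to exercise every pathway with
adequate statistical power: null calibration uses 20 seeds × (10 + 10)
subjects × 20 trials in the beta band; planted-effect recovery uses 30
subjects per arm × 20 trials (coupling 0.3 + 0.2 under noise, planted
ρ = 0.6); IAF recovery uses 20 subjects with 20 s eyes-closed rests.
Resting-run durations in tests are shortened from the 150 s default;
the estimator needs only a few 2 s Welch windows.

## Known limitations

- The amplitude-threshold rejection cannot represent ICA-style artifact
  subtraction; rejection rates on real data would differ.
- WPLI's zero-lag insensitivity protects against common sources but a
  strong common source still attenuates true lagged coupling by
  inflating the denominator; ERWPLI inherits baseline estimation noise
  (1 s baseline → 800 retained samples per trial).
- The unpaired rank-sum contrast ignores the within-subject structure
  (kept for fidelity); the paired option is provided but off.
- The planted performance correlation is defined at the latent level;
  discretization to {0, 5..10} attenuates realized Spearman ρ slightly.
- Eigenvector centrality on near-disconnected graphs is
  component-dominated; with dense WPLI matrices this does not arise.
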