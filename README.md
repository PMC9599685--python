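# aimnet

Event-locked brain-network analysis of marksmanship EEG, built for the
question of how audiovisual sensory restriction (noise disturbance, weak
light) reshapes a shooter's preparation-stage functional connectivity —
and packaged with a synthetic cohort generator so every stage is
testable against known ground truth.

The pipeline reproduces a complete analysis workflow for a design of 30
subjects × 3 conditions (control / noise / weak light) × 2 sets of 30
shots, with 30-channel 10–20 EEG at 1000 Hz and per-shot ring scores:

1. **Synthetic cohorts** (`aimnet.simulate`) — 1/f^α background EEG with a
   controllable occipital alpha peak, band-limited phase-lagged coupling
   between chosen channel pairs, a zero-lag common source as a
   volume-conduction surrogate, injectable artifacts, and ring scores
   drawn through a Gaussian copula so a target rank correlation with a
   network feature is planted exactly.
2. **Preprocessing** (`aimnet.preprocess`) — zero-phase order-1000 FIR
   band-pass (0.1–50 Hz), −5..+2 s segmentation around each shot,
   peak-to-peak artifact rejection, and individualized band division
   anchored to the individual alpha frequency (IAF): the 8–12 Hz
   eyes-closed occipital power peak at 0.5 Hz resolution, giving
   theta = [IAF−6, IAF−3], alpha = [IAF−2, IAF+2], beta = [IAF+3, 30] Hz.
3. **Connectivity** (`aimnet.connectivity`) — the weighted phase lag index
   per channel pair, from Hilbert analytic signals with 10 % trimmed at
   each end:

   `WPLI_xy = |⟨|Im S_xy| · sign(Im S_xy)⟩| / ⟨|Im S_xy|⟩`,
   `S_xy(t) = a_x(t) · conj(a_y(t))`

   and its event-related change rate against the −4..−3 s baseline R:
   `ERWPLI = (WPLI − R) / R`. WPLI discounts zero-lag (volume-conducted)
   coupling by construction.
4. **Network topology** (`aimnet.graph`) — the WPLI matrix is used
   unthresholded as a weighted adjacency: Onnela weighted clustering,
   characteristic path length and global efficiency with edge length
   1/weight, local efficiency (neighbor-subgraph efficiency), and
   eigenvector centrality by power iteration.
5. **Group statistics** (`aimnet.stats`) — K–S normality screening
   (reported, never trusted), two-sided Wilcoxon rank-sum contrasts
   edgewise (435 pairs), nodewise (30 channels) and on global metrics,
   Spearman correlations with mean ring scores, all corrected by
   Benjamini–Hochberg FDR within each feature family.

`aimnet.pipeline.run_all` chains everything from one config with full
provenance (config hash, per-file checksums, warning ledger), and the
`aimnet` CLI exposes `simulate / preprocess / connect / network / stats /
run-all`.

## Worked example

```python
import numpy as np
from aimnet import (SimulationConfig, CouplingSpec, simulate_subject,
                    estimate_iaf, bands_from_iaf, bandpass_fir, epoch,
                    reject_artifacts, analytic_signal, wpli, mean_wpli,
                    network_metrics)

cfg = SimulationConfig(
    n_subjects=1, conditions=("control",), shots_per_condition=20,
    coupling_specs=(CouplingSpec(pair=("C3", "C4"), band="beta",
                                 phase_lag=np.pi/4, strength=0.9),),
    rest_eyes_closed_s=20, rest_eyes_open_s=5, seed=7)
sub = simulate_subject(cfg, 0)

iaf = estimate_iaf(sub.resting)
theta, alpha, beta = bands_from_iaf(iaf)
rec = bandpass_fir(sub.recordings["control"], 0.1, 50.0)
trials = epoch(rec, (-5.0, 2.0))
clean, report = reject_artifacts(trials, 150.0)
beta_rec = bandpass_fir(rec, beta.low, beta.high)
aiming = epoch(beta_rec, (-5.0, 2.0), event_ids=clean.retained_trial_ids,
               band_label="beta").subwindow(-3.0, 0.0)
m = wpli(analytic_signal(aiming))
i, j = m.channel_labels.index("C3"), m.channel_labels.index("C4")
print(f"IAF {iaf.iaf:.1f} Hz, beta [{beta.low:.1f}, {beta.high:.1f}] Hz")
print(f"WPLI(C3-C4) = {m.values[i, j]:.3f}, grand mean = {mean_wpli(m):.3f}")
print(f"global efficiency = {network_metrics(m.values).global_efficiency:.3f}")
```

Output:

```
IAF 10.0 Hz, beta [13.0, 30.0] Hz
WPLI(C3-C4) = 0.996, grand mean = 0.186
global efficiency = 0.186
```

The planted C3–C4 beta coupling (strength 0.9, lag π/4) is recovered as
a near-unit WPLI; uncoupled pairs sit at the ~0.19 noise floor of a
20-trial estimate, and the unthresholded network's global efficiency
sits at that same floor (in a dense near-uniform weighted graph the
direct edge dominates every route, so mean inverse distance ≈ mean
weight).

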