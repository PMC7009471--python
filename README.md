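# burstdecode

Decoding intended movement from subthalamic local field potentials (LFPs),
conditioned on alpha/beta bursts.

Deep-brain-stimulation electrodes record LFPs from six directional contacts
in the subthalamic nucleus while a subject makes cued upper- or lower-limb
movements.  Spectral power in 100 ms windows carries information about the
limb *about to be moved* — already before the imperative cue when the limb
is known in advance — and transient bursts of 8–30 Hz activity degrade that
information.  `burstdecode` implements the full analysis chain needed to
measure this, plus a synthetic-session generator with known ground truth so
that every stage is testable without patient data:

1. **synthdata** — multi-contact LFP sessions: 1/f background, stochastic
   alpha/beta bursts (Poisson onsets, Gamma durations), a class-dependent
   multi-band power contrast tied to the trial structure, and a gating
   factor gamma in [0, 1] controlling how much of that contrast survives
   during a burst.
2. **preprocess** — 2 Hz high-pass, detrend, z-score (whole record, before
   segmentation); cue-aligned epochs; complex Morlet power on a 1 Hz grid
   (8–500 Hz); per-trial baseline normalization (500 ms at [−2, −1.5] s).
3. **bursts** — 75th-percentile threshold on smoothed band envelopes,
   minimum duration 100 ms; removal of overlapping alpha/beta bursts;
   non-burst periods; 100 ms windows centred on burst and non-burst
   midpoints; rate/duration/occupancy/overlap statistics.
4. **features** — mean normalized power per contact in nine bands
   (8–12 … 350–500 Hz); training-fold standardization; ReliefF ranking with
   top-6 selection inside 4-fold cross-validation; importance =
   selection count / 4.
5. **gnb** — Gaussian naive Bayes from first principles (log-space
   posteriors, frequency priors, variance flooring).
6. **evaluate** — out-of-fold ROC-AUC per window position, task period and
   burst state; same/different best-three-contact summaries; the
   Lilliefors → Box-Cox → rmANOVA (Greenhouse-Geisser) → paired t-test →
   FDR statistics chain.
7. **report** — deterministic figures and a Markdown summary from the tidy
   result CSVs.

The core classifier is the Gaussian naive Bayes rule
`P(Y=k | x) ∝ π_k · Π_j N(x_j; μ_kj, σ²_kj)` on the ReliefF-selected
features, scored by the area under the ROC curve (0.5 = chance).

## Worked example

```python
import numpy as np
from burstdecode import synthdata as sd, pipeline as pl

cfg = sd.GeneratorConfig(seed=1)            # forewarned (fixed-limb) design
rec, events, truth = sd.generate_session(cfg)

res = pl.decode_periods(rec, events, pl.PipelineConfig(seed=1),
                        periods=("rest", "pre_cue"))
print(res.period_summary.round(3))

burst = pl.decode_burst_states(rec, events, pl.PipelineConfig(seed=1))
print(burst.state_auc.groupby("state")["auc"].mean().round(3))
print(burst.burst_stats.groupby("band")[["rate", "mean_duration",
                                         "occupancy"]].mean().round(3))
```

prints

```
period
pre_cue    0.777
rest       0.503
Name: auc, dtype: float64
state
alpha_burst    0.772
beta_burst     0.693
non_burst      0.830
Name: auc, dtype: float64
        rate  mean_duration  occupancy
band
alpha  0.781          0.315      0.246
beta   0.711          0.344      0.244
```

Rest decoding sits at chance (0.50) while pre-cue decoding is far above it
(0.78): before the cue, the signal already tells the limbs apart.  With the
default gating factor 0.5, burst windows decode slightly worse than
non-burst windows; regenerate with `burst_gating_factor=0` and the burst
states collapse toward chance while non-burst windows do not.  Detected
burst rates and occupancies describe what the percentile detector finds in
the synthetic pre-cue periods.

The same pipeline is scriptable from the shell:

```
burstdecode simulate --seed 1 --out session/
burstdecode run session/ --out results/
burstdecode report results/
```

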