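# phasealign

Analysis pipeline for stimulus-locked **phase alignment** in epoched
intracranial EEG, built around the question of whether theta-band phase
resetting in anterior thalamic recordings differs between successfully and
unsuccessfully encoded stimuli, and whether that alignment covaries with
theta–gamma cross-frequency coupling across participants.

The package bundles:

* a **synthetic-cohort generator** producing epoched multi-channel
  recordings (frontal, left/right anterior thalamus, left/right dorsomedial
  thalamus) with known injected effects — von Mises phase resets, an early
  broadband evoked reset, multiplicative theta–gamma coupling, an ERP-like
  transient, and 1/f background noise — so every downstream stage is
  testable without patient data;
* Morlet **time–frequency decomposition** with bipolar re-referencing;
* the **phase alignment index** (phase-locking factor / inter-trial
  coherence) with condition-balanced trial counts;
* Canolty-style **theta–gamma modulation index** with circular-shift
  surrogate normalisation, and inter-channel **phase-locking value**;
* **ERPs** (1–8 Hz zero-phase filter, 200 ms baseline) and ERP–alignment
  correlations;
* **group statistics**: paired t-maps, cluster-size permutation testing,
  Pearson correlations, Benjamini–Hochberg FDR, and Fisher z comparison of
  correlations;
* a CLI (`phasealign simulate | analyze | report`) and an HDF5 epoch
  container for moving cohorts between stages.

## The statistics at the core

For epochs k = 1..K with phase φₖ(f, t) at a time–frequency point, the
phase alignment index is the mean resultant length

    PAI(f, t) = | Σₖ exp(i φₖ(f, t)) | / K        ∈ [0, 1]

(0 = no alignment, 1 = identical phase in every trial). Condition
contrasts on PAI maps use paired two-sided t-tests across participants and
control multiplicity with a cluster-size permutation test: clusters of
4-adjacent points with p < 0.05 are compared against the permutation
distribution of the largest cluster obtained by randomly swapping each
participant's condition labels 1000 times.

Theta–gamma coupling is the composite-signal modulation index

    MI = | ⟨ A₄₀₋₅₀(t) · exp(i φ₇₋₈(t)) ⟩ₜ |

normalised to a z-score against surrogates in which the amplitude series
is circularly time-shifted. Across-participant relations between
alignment, coupling, and synchrony are Pearson correlations with BH-FDR,
and condition differences in correlation use the Fisher z-transform,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)).

## Worked example

```python
import phasealign as pa

cfg = pa.RunConfig(synth=pa.SynthConfig(seed=5))   # 7 participants, 40+40 trials
report = pa.run_full_analysis(cfg)

ct = report["cluster_tests"]["R-ATN"]
print(f"late theta T max = {ct['t_max_late_theta']:.2f}, "
      f"min cluster p = {ct['min_cluster_p']:.3f}")
late = [c for c in report["correlations"]
        if c["label"] == "late_ratn_theta_pai_vs_cfc_SE"][0]
print(f"late RATN PAI vs CFC (SE): r = {late['r']:.2f}, p = {late['p']:.3f}")
```

prints, for this seed:

```
late theta T max = 7.10, min cluster p = 0.042
late RATN PAI vs CFC (SE): r = 0.89, p = 0.007
```

i.e. the right-ATN channel shows a significant SE-vs-UE cluster in the
late (0.9–1.1 s) theta window — the injected condition difference in reset
concentration — and participants with stronger late theta alignment show
stronger surrogate-normalised theta–gamma coupling, reflecting the latent
correlation the generator imposes between the two effect sizes.

The same run from the shell:

```bash
phasealign analyze --seed 5 --out results/
phasealign report results/summary.json
```

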