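# lgnsnr

Signal-to-noise analysis of luminance and chromatic temporal contrast
sensitivity across three stages of the primate early visual system:
simulated cone photocurrents, LGN spike trains, and behavior.

## The problem

Contrast sensitivity for luminance flicker (L and M cones modulated in
phase, *L+M*) peaks near 10 Hz, whereas sensitivity for chromatic
flicker (cones in counterphase, *L−M*) is low-pass. Because the same
cones mediate both, the difference must arise where L and M signals are
combined. Quantifying *where* the information is lost requires putting
every stage on a common scale. This package does that with the signal
detection theory discriminability index d′:

* **Behavior** — performance in a 2AFC detection task maps to d′ via
  the ideal-observer relation `pc = Φ(d′/√2)`; the conventional 82%
  correct at threshold corresponds to d′ ≈ 1.27. A temporal contrast
  sensitivity function (TCSF) per color direction, modeled as a
  difference of cascaded low-pass filters, places every stimulus at
  detection threshold (clipped, and flagged, at the display gamut caps
  of 0.19 cone contrast for L−M and 0.86 for L+M).
* **LGN spikes** — each trial is summarized by the magnitude of the
  complex projection of its spike train onto the stimulus fundamental
  frequency (F1); d′ compares stimulus trials to blanks,
  `d′ = (μ_stim − μ_blank) / √((σ²_stim + σ²_blank)/2)`,
  with bootstrap standard errors and an independently offset spike
  counting window. Single-neuron d′ is inflated to a population d′ by
  pooling N effective neurons with equicorrelated noise:
  `k = √(N / (1 + (N−1)ρ))`.
* **Cone currents** — a linear photocurrent kernel plus stationary
  Gaussian noise with a Lorentzian-sum spectrum yields the
  matched-filter bound `d′² = 4∫₀^∞ |S(f)|²/PSD(f) df` per cone,
  summed in d′² over the cones under the stimulus aperture. This upper
  bounds what any downstream stage can achieve.

A synthetic LGN of linear–nonlinear–Poisson neurons ties the stages
together: magnocellular cells have non-opponent centers and delayed,
nearly balancing surrounds (bandpass for L+M), parvocellular cells have
single-cone centers and mixed surrounds (low-pass for L−M), so the
whole pipeline is testable end to end without recorded data.

## Worked example

```python
from lgnsnr.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig()          # defaults: 1-20 Hz, L+M and L-M,
stage = run_experiment(config, seed=1)  # 12 neurons/class, 100 trials/cond
cols = ["condition_id", "contrast", "behavior_dprime", "cone_dprime",
        "magno_dprime_population", "parvo_dprime_population"]
print(stage[cols].to_string(index=False, float_format=lambda x: f"{x:.2f}"))
```

```
condition_id  contrast  behavior_dprime  cone_dprime  magno_dprime_population  parvo_dprime_population
     L+M_1Hz      0.13             1.29        48.79                     0.54                     1.56
     L+M_2Hz      0.08             1.29        31.05                     0.86                     1.64
     L+M_5Hz      0.04             1.29        20.27                     1.22                     1.05
    L+M_10Hz      0.04             1.29        16.93                     2.56                     1.19
    L+M_20Hz      0.08             1.29        15.40                     6.47                     1.65
     L-M_1Hz      0.01             1.29         4.29                    -0.08                     1.38
     L-M_2Hz      0.01             1.29         4.68                     0.10                     1.86
     L-M_5Hz      0.02             1.29         8.41                     0.07                     1.73
    L-M_10Hz      0.05             1.29        18.55                     0.09                     3.81
    L-M_20Hz      0.19             1.29        36.65                     0.13                     5.98
```

Every stimulus sits at behavioral threshold (the `behavior_dprime`
column is the constant criterion 1.29, from 82% correct), yet LGN
population d′ rises steeply with temporal frequency: near the criterion
at 1 Hz, ~5× above it at 20 Hz — the high-frequency information present
in the LGN is discarded downstream. The cone-array column shows the
opposite pattern of loss upstream: at 1 Hz only ~1–2% of the cone SNR
for L+M reaches the LGN (0.54/48.79), versus ~32% for L−M
(1.38/4.29), reflecting the delayed-surround cancellation of slow
luminance modulations in the retina; above 5 Hz the ordering reverses.
Slightly negative entries (magno at L−M 1 Hz) are ordinary estimator
noise around zero signal — the magno cell's balanced center makes it
blind to counterphase modulation. The cone bound dominates the LGN
everywhere (any violation would be flagged `unphysical`, not clamped).

The same analysis is available from the shell:

```bash
lgnsnr simulate --seed 1 --out exp/          # write conditions + rasters
lgnsnr dprime --rasters exp/rasters_magno_00.tsv \
    --conditions exp/conditions.tsv --out dprime.tsv
lgnsnr sweep --rasters exp/rasters_parvo_00.tsv \
    --conditions exp/conditions.tsv --condition-id L-M_1Hz --out sweep.tsv
lgnsnr compare --seed 1 --out results/       # full cross-stage table
```

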