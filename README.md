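# fdflim

Frequency-domain FLIM analysis of NADH and protoporphyrin IX (PPIX)
autofluorescence in brain-tumor tissue samples.

Macroscopic frequency-domain fluorescence-lifetime imaging is a candidate
tool for fluorescence-guided neurosurgery: after 5-ALA administration, tumor
tissue accumulates PPIX (~16 ns native lifetime), while NADH autofluorescence
(free ~0.4 ns, protein-bound 1–4 ns) reports cellular energy metabolism.
`fdflim` implements the complete analysis chain for such acquisitions, for
researchers building or evaluating FLIM pipelines of this kind:

- **Homodyne reconstruction** — a modulated laser (f = 10 MHz) excites the
  tissue; the camera records K = 16 phase-stepped frames
  I_k = I₀(1 + m·cos(θ_k − φ)). A DFT estimator recovers phase φ,
  modulation m and DC per pixel; a reference target removes the instrument
  phase/gain; the phase lifetime is τ_φ = tan(φ)/(2πf).
- **Post-processing** — manual-segmentation masks, lifetime ceilings
  (NADH < 5 ns, PPIX < 17 ns), an intensity noise floor, and 100 random
  colocalized pixels per sample so every sample contributes equally.
- **Statistics** — per-sample means, group medians with 25/75 % quantiles,
  and two-tailed Mann–Whitney U tests (α = 5 %).
- **Phasor analysis** — calibrated clouds (g, s) = (m cos φ, m sin φ) against
  the universal semicircle (g−½)² + s² = ¼; a total-least-squares chord fit
  extracts the two components of a bi-exponential decay from the chord's
  semicircle intersections (τ = s/(g·ω)).
- **Classification** — RUS-boosted decision trees (AdaBoost.M2 pseudo-loss
  with per-iteration random undersampling, a scikit-learn-style estimator)
  predicting tumor grade {LGG, HGG, MET} and tissue type
  {REA, INF, NEC, TUM} from PPIX-only or combined NADH+PPIX lifetimes under
  fivefold cross-validation.
- **Synthetic cohort generator** — a 42-sample / 21-patient cohort with
  realistic group lifetime distributions, shot noise, sub-field sample
  shapes, vessel streaks and necrotic cores, so the whole chain is testable
  without patient data. See `docs/methods.md` for the model details.

## Worked example

```python
from fdflim.cohort import CohortConfig
from fdflim.pipeline import run_pipeline

result = run_pipeline(CohortConfig(mode="tissue", seed=7), run_classification=True)
print(result.group_summaries["tissue"].to_string(index=False,
      float_format=lambda v: f"{v:.2f}"))
```

```
   key label  n_samples  nadh_median_ns  nadh_q25_ns  nadh_q75_ns  ppix_median_ns  ppix_q25_ns  ppix_q75_ns
tissue   INF         12            1.93         1.51         2.06            3.08         2.11         4.25
tissue   NEC          7            2.26         2.21         2.59            4.78         3.99         5.27
tissue   NPL          2            1.18         1.16         1.20            2.00         1.97         2.02
tissue   REA          5            1.93         1.91         3.78            8.30         7.94         8.46
tissue   TUM         16            1.74         1.59         1.97           10.47         6.09        14.44
```

Each row summarizes one tissue class over its samples' mean lifetimes (ns):
compact tumor (TUM) carries a long apparent PPIX lifetime (~10.5 ns here,
i.e. a high native-PPIX fraction), non-pathological tissue (NPL) sits at the
~2 ns autofluorescence level, and NADH varies much less across classes.
Continuing with the same result object:

```python
chord = result.ppix_chord
print(chord.tau_long_ns, chord.tau_short_ns)   # 15.97, 1.89
for (task, fs), cv in result.cv_results.items():
    print(task, fs, f"{cv.overall_accuracy:.1%}")
```

```
grade  ppix_only 58.1%
tissue ppix_only 63.7%
grade  nadh_ppix 73.4%
tissue nadh_ppix 82.7%
```

The pooled-phasor chord recovers the generator's PPIX decay components
(16 ns native PPIX, 1.9 ns tissue autofluorescence), and adding the
colocalized NADH lifetime improves both classifiers, because NADH separates
necrotic and reactive tissue that PPIX alone confuses.

The same pipeline is scriptable from a shell:

```bash
fdflim simulate --seed 1 --out cohort/          # 42 synthetic samples
fdflim run --cohort cohort/ --out results/      # full analysis + run report
fdflim phasor --cohort cohort/ --plot --out results/
```

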