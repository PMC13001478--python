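# omiflim

Label-free **optical metabolic imaging (OMI)** analysis of immune cells.
Fluorescence-lifetime imaging (FLIM) of the endogenous metabolic cofactors
NAD(P)H and FAD reports single-cell metabolic state without stains or
genetic reporters, which makes it attractive for profiling peripheral
blood mononuclear cells (PBMCs — T cells, B cells, NK cells, monocytes)
and for detecting immune activation.  `omiflim` provides the full desk
side of that workflow for FLIM practitioners and image-analysis
developers:

* **Synthetic data with ground truth** — multi-cell fields of view as
  per-pixel TCSPC photon-arrival histograms for NAD(P)H-like and FAD-like
  channels, Poisson-sampled from biexponential emitters convolved with a
  Gaussian instrument response; plus a fast statistical path that draws
  per-cell feature tables directly from cell-type profiles.
* **Decay fitting** — sliding-kernel spatial binning (5×5 for NAD(P)H,
  7×7 for FAD, to reach 2,500 photons per decay), background
  thresholding, and per-pixel fits of
  `I(t) = α₁e^(−t/τ₁) + α₂e^(−t/τ₂) + C` by Poisson maximum likelihood
  with circular IRF reconvolution over the 12.5 ns repetition period.
* **Per-cell features and QC** — the 10 OMI variables (NAD(P)H and FAD
  τ_m, τ₁, τ₂, α₁, the optical redox ratio
  ORR = I_NAD(P)H/(I_NAD(P)H+I_FAD), and cell area), with the standard
  exclusion rules (intensity < 10 a.u., area < 70 px, reduced χ² > 1.3,
  NAD(P)H τ₁ < 350 ps) and CD69/CD56 stain gating.
* **Statistics and classification** — Cohen's d with the conventional
  effect-size categories, coefficient-of-variation heterogeneity,
  z-scored Ward/Euclidean hierarchical clustering, and balanced (minority
  undersampled) 70/30 one-vs-rest random-forest classification with full
  ROC/AUC/confusion reporting.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

Simulate quiescent and chemically activated PBMCs (the activated profiles
shift lymphocyte NAD(P)H τ_m down and α₁ up, monocytes the opposite way,
and raise the redox ratio for all types), then quantify and classify the
activation signature:

```python
import pandas as pd
from omiflim import sample_feature_table, run_classification, cohens_d
from omiflim.simulate import default_profiles, activated_profiles

q = sample_feature_table(default_profiles(), 300, rng_seed=0, condition="quiescent")
a = sample_feature_table(activated_profiles(strength=1.5), 300, rng_seed=1,
                         condition="activated")
cells = pd.concat([q, a], ignore_index=True)

es = cohens_d(
    cells.loc[cells.condition == "activated", "nadph_tau_m"],
    cells.loc[cells.condition == "quiescent", "nadph_tau_m"],
)
print(f"activation effect on NAD(P)H tau_m: d = {es.d:+.2f} ({es.category}, {es.direction})")

report = run_classification(cells, "condition", rng_seed=0)
print(f"quiescent vs activated: accuracy = {100 * report.accuracy:.1f}%, "
      f"AUC = {report.auc['activated']:.3f}")
for name, w in sorted(report.feature_importances.items(), key=lambda kv: -kv[1])[:3]:
    print(f"  feature importance {name}: {100 * w:.1f}%")
```

Output:

```
activation effect on NAD(P)H tau_m: d = -1.32 (large, decrease)
quiescent vs activated: accuracy = 94.0%, AUC = 0.989
  feature importance nadph_tau1: 38.6%
  feature importance nadph_tau_m: 16.0%
  feature importance orr: 14.3%
```

The effect size says activation lowered the mean NAD(P)H lifetime by 1.3
pooled standard deviations (a large, decrease-direction change, consistent
with a shift toward free NAD(P)H / glycolysis); the balanced random forest
separates the two conditions with 94% test accuracy, leaning mostly on the
NAD(P)H short-lifetime component and the redox ratio.

The imaging path works the same way from raw histograms — see
`build_scene`, `fit_image`, `build_feature_table` — or from the shell:

```sh
omiflim simulate config.yaml scene/
omiflim fit scene/nadph.tif fits/ --irf scene/irf_nadph.csv --channel nadph
omiflim fit scene/fad.tif  fits/ --irf scene/irf_fad.csv  --channel fad
omiflim extract --masks scene/labels.tif --fit-dir fits/ \
    --nadph-cube scene/nadph.tif --fad-cube scene/fad.tif --out cells.csv
omiflim stats cells.csv --out stats/
omiflim classify cells.csv --out clf/ --label-col cell_type
```

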