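# mimicspec

Visual modelling and statistics for quantifying **adult plumage aggressive
mimicry** in a brood-parasite–host system, and for the host behavioural
experiments that test it.

The motivating biology: female cuckoo finches (*Anomalospiza imberbis*)
resemble harmless female *Euplectes* weavers (bishops) far more closely than
they resemble their own closest relatives, the *Vidua* finches — an
aggressive-mimicry strategy that may blunt the defences of their
tawny-flanked prinia hosts. Demonstrating this requires (i) modelling
plumage colour and pattern through a *bird's* eye rather than ours,
(ii) measuring how hosts respond to intruder models at the nest, and
(iii) measuring whether seeing a particular intruder changes the host's
subsequent rejection of a foreign egg. `mimicspec` implements all three
stages as a tested, reusable pipeline, together with synthetic-data
generators that emulate the full study design (museum skins, polymorphic
egg clutches, behavioural trials) with seeded reproducibility.

## What it computes

**Receptor-noise-limited discrimination.** Reflectance spectra (or
calibrated camera pixels mapped through a polynomial transform) become von
Kries-normalized cone catches *q*ᵢ. Two stimuli are compared through the
log catch ratios Δfᵢ = ln(qᵢᵃ/qᵢᵇ); for *n* receptor classes with Weber
fractions *e*ᵢ the chromatic distance in "just-noticeable differences" is

```
ΔS² =  Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δf_i − Δf_j)²
       ───────────────────────────────────────────
       Σ_{|T|=n−1} (Π_{k∈T} e_k)²
```

which reduces to the familiar dichromat (|Δf₁−Δf₂|/√(e₁²+e₂²)),
trichromat and tetrachromat forms. Achromatic (double-cone) contrast is
|ln(qₐ/q_b)|/e_D. Values ≳ 1–3 JND are discriminable under good light.

**Plumage difference statistics**, per body region (nine regions per
specimen: back, beak, belly, breast, cheek, eyebrow, head, throat, wing):

- *colour JND* between the two patches' **abundant colours** — the pixel
  colour with more other pixels within 2 JNDs of it than any other,
  found by exhaustive O(n²) search over the ≤ 2000-pixel patch;
- *L_diff* — the total-variation distance Σ|pᵢᵃ − pᵢᵇ| between 32-bin
  luminance-proportion histograms (range 0–2);
- *S_diff* — the granularity difference: each patch passes through 33
  half-octave Fourier band-pass filters on a geometric scale grid, the
  "energy" at a scale is the SD of the filtered pixels, and S_diff sums
  absolute energy differences across scales.

**Egg metrics**: replicate reflectance spectra → tetrachromatic (UVS, or
violet-sensitive alternative) colour and luminance JNDs against the clutch
mean; eggshell pattern through the same granularity machinery; volume and
shape (elongation, asymmetry) from the egg outline as a solid of
revolution; and the field rules for classifying nest outcomes (one missing
egg = rejected, whole clutch gone = depredated, intact and incubated 3
days = accepted).

**Inference**: random-intercept Gaussian mixed models estimated by profile
REML (exactly reproducing the paired *t*-test on balanced within-pair
designs), IRLS logistic regression with Wald tests, backward elimination
at p > 0.05 with the focal treatment protected, and all pairwise treatment
contrasts via reference-category rotation.

## Worked example

```python
import numpy as np
from mimicspec import (builtin_receptor_set, generate_specimens,
                       build_comparison_table, generate_egg_experiment,
                       ExperimentSpec, fit_logistic)

# 1. simulate museum skins with the calibrated mimicry structure and
#    recover the group-level colour/luminance differences
receptors = builtin_receptor_set("trichrom_skins")
focal, others, truth = generate_specimens(seed=1, receptors=receptors)
result = build_comparison_table(focal, others, receptors.weber_fractions())
print(result.records.groupby("taxon_group")[["colour_jnd", "luminance_jnd"]]
      .mean().round(2))

# 2. simulate the coupled model-presentation / egg-rejection experiment
#    and fit the rejection model
tabs = generate_egg_experiment(ExperimentSpec(), seed=1,
                               covariates=("colour",), keep_raw=False)
fit = fit_logistic(tabs.rejection, "rejected",
                   ["C(model_type)", "colour_jnd"])
print(fit.summary())
```

prints

```
                  colour_jnd  luminance_jnd
taxon_group
Euplectes               2.80           0.76
Vidua                   3.85           0.79
conspecific_male        8.18           0.72
Logistic regression (IRLS)    rejected ~ C(model_type) + colour_jnd
n = 51, converged = True
------------------------------------------------------------------------
                                      estimate     se       z      p
Intercept                              -0.4411 0.6836 -0.6452 0.5188
C(model_type)[T.female_cuckoo_finch]   -1.2223 0.8236 -1.4841 0.1378
C(model_type)[T.male_bishop]           -2.2471 0.9209 -2.4402 0.0147
colour_jnd                              0.4152 0.1462  2.8392 0.0045
------------------------------------------------------------------------
loglik = -28.246
```

Reading the output: the focal female's plumage colour sits ~2.8 JND from
the model group (*Euplectes*), ~3.9 from the relatives (*Vidua*) and ~8.2
from conspecific males — the mimicry ordering — while luminance barely
differs across groups (~0.8 JND, below threshold). In the rejection model,
hosts that saw a male bishop were much less likely to reject the foreign
egg than those that saw a female bishop (the reference level), and
rejection probability rises with the colour distance between the foreign
egg and the clutch (positive `colour_jnd` slope); this single 51-nest
replicate drew a slope of 0.42 around the generating value of 0.29.

A shell interface drives the same stages end to end:

```sh
mimicspec simulate --config config.yaml        # write a synthetic bundle
mimicspec plumage-compare --config config.yaml
mimicspec egg-analysis --config config.yaml
mimicspec behaviour-stats --config config.yaml
mimicspec report --config config.yaml
```

## Layout

- `src/mimicspec/vision.py` — spectra, cone catches, camera→cone
  polynomial mapping, JND formulas
- `src/mimicspec/calibration.py` — grey-standard normalization, patch
  extraction, pixel-budget subsampling
- `src/mimicspec/plumage.py` — abundant colour, L_diff, S_diff,
  comparison tables
- `src/mimicspec/eggs.py` — egg spectra, volume/shape, outcome rules
- `src/mimicspec/stats.py` — mixed models, logistic regression,
  elimination, contrasts
- `src/mimicspec/simulate.py` — seeded generators for every input
- `src/mimicspec/pipeline.py`, `cli.py` — end-to-end orchestration

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
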