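# Methods notes

This note records the models implemented in `mimicspec`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices a careful user should know about.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Visual model

**Cone catches.** A stimulus reflectance R(λ) under illuminant I(λ) gives
receptor *i* the raw catch qᵢ = ∫ R I Sᵢ dλ, evaluated by trapezoid
quadrature on a common 1-nm grid (spectra are linearly interpolated onto
the grid; extrapolation is refused). von Kries normalization divides by
the catch of a perfect white (R ≡ 1) reflector, modelling chromatic
adaptation: a spectrally flat grey surface then yields equal catches in
every class, and a pure intensity change leaves chromatic coordinates
untouched. The default illuminant is equal-energy; a measured daylight
table can be supplied as a spectrum CSV.

**Receptor sets.** Three built-in sets cover the analyses: a visible-band
trichromat (SWS/MWS/LWS + double cone) for museum-skin work, where camera
images carry no UV channel; an ultraviolet-sensitive tetrachromat for egg
spectra; and a violet-sensitive tetrachromat as the robustness
alternative. Their spectral sensitivities are *synthetic idealized
Gaussian pigment templates* built in code — adequate for simulation and
for exercising the discrimination model, and replaceable by measured
tables via `Spectrum.from_csv`. Relative cone abundances default to the
widely used blue-tit proportions (UVS 0.37 : SWS 0.70 : MWS 0.99 :
LWS 1.00); Weber fractions scale from the reference receptor (LWS at
0.05; double cone 0.05) as eᵢ = e_ref √(η_ref/ηᵢ), the standard
receptor-noise pooling argument. All of this is configuration, not
hard-coded truth.

**Discrimination.** The chromatic JND uses the general n-receptor
receptor-noise form (see README). Numerically, the log-ratio vector Δf is
centred before the quadratic form is applied: the form annihilates the
uniform (intensity) component analytically, and centring prevents
floating-point leakage of large intensity components into the chromatic
distance (without it, JND(a, c·a) evaluates to ~10⁻⁷ instead of ~10⁻¹⁴).
Catches are floored at 10⁻⁶ before logarithms so dark pixels cannot
produce −∞; the floor perturbs any realistic JND negligibly.

**Camera → cone mapping.** Calibrated camera catches map to receptor
catches through per-receptor least-squares polynomials with all
interaction terms, default degree 2 — the convention of calibrated
digital photography. The fit demands ≥ 3× more training spectra than
terms and a full-rank design (collinear monomials are named in the
error); per-receptor R² is reported so a poor mapping is visible.

## Plumage statistics

**Pixel budget.** Patches are reduced to at most 2000 pixels before the
exhaustive colour analysis. This is implemented as *seeded uniform
subsampling without replacement*, not geometric resizing, because the
downstream statistics (abundant colour, luminance histograms) consume the
pixel colour multiset and resizing would blur it; resizing remains
available upstream of the package. Subsampling is unbiased for
per-channel means (property-tested).

**Abundant colour.** For every pixel, count the other pixels strictly
within 2.0 JND of it; return the pixel with the maximal count, ties
broken by lowest pixel index. At 2000 pixels this is ≤ 4·10⁶ JND
evaluations, done as one vectorized quadratic-form Gram computation, so no
approximate neighbour search is needed. The Gram identity loses ~√ε
precision near zero distance (~10⁻⁷ JND), irrelevant at a 2.0 threshold;
the scalar path is exact and the two are cross-checked in tests.

**Luminance histograms and L_diff.** Double-cone catches are read as
fractions of the reflectance-normalized maximum, clipped to [0, 1] (the
clip count is logged), and binned into 32 equal half-open bins (last bin
closed). Counts are normalized to proportions so patches of unequal size
compare; L_diff is the L1 distance between the proportion vectors, hence
a pseudometric bounded by 2. A raw-count mode is deliberately absent —
unequal patch sizes would make it incoherent.

**Granularity (pattern energy) and S_diff.** The patch luminance image
(mean-filled outside its mask, cropped to the mask bounding box) is
Fourier transformed; for each of 33 scales on a geometric grid from 2 px
to the shorter image dimension, the annulus of wavelengths within half an
octave of the scale ([s/√2, s·√2)) is retained, inverse-transformed, and
the SD of in-mask pixels recorded. The half-octave annulus is the
standard band-pass convention of granularity analysis and keeps every
band populated with DFT lattice frequencies even at the longest
wavelengths, where a disjoint tiling would leave some bands empty.
Consequences, all tested: DC exclusion makes the spectrum invariant to
constant offsets; energy is absolutely homogeneous (E(k·img) = |k|E);
a pure sinusoid peaks in the band containing its wavelength. S_diff sums
absolute energy differences across scales and is a pseudometric in
luminance units. Peak-frequency/peak-energy summaries of older
granularity work are deliberately not provided; collapsing the spectrum
to its mode discards multimodal pattern structure.

**Comparison tables.** Every focal specimen is compared with every
specimen of every other set in every shared region (specimens missing a
region are excluded with a logged warning). The modelling table averages
specimen pairs within species × region; the pattern measure enters
modelling as ln(S_diff + 10⁻⁸) — the offset only guards exact zeros from
degenerate (constant) patches.

## Egg metrics

Replicate background spectra (five per egg by default) are averaged
pointwise; the between-replicate coefficient of variation is available as
a data-quality check. The clutch reference is the *mean of the host
eggs' von Kries catches*; using per-egg minima instead would make the
covariate depend on clutch size. Requesting a UVS computation on spectra
that do not cover the UV band is an explicit error rather than a silent
extrapolation. Egg volume treats the outline as a solid of revolution
about its principal axis, V = π∫(w(x)/2)² dx by trapezoid quadrature on
the polygon width profile; shape is summarized by elongation
(length / max width) and asymmetry (offset of the widest section from
mid-length, as a fraction of length) — the minimal descriptor pair for
"egg shape" — and the single shape-difference covariate is the Euclidean
distance on standardized descriptors. Probe geometry (45°, 5 mm) is
metadata only; no BRDF correction is attempted.

## Inference

The Gaussian mixed model has one random intercept. The variance ratio
λ = σ²_group/σ²_resid is profiled out of the REML criterion by bounded
scalar optimization (log-λ in ±14); fixed effects are GLS at the optimum,
computed group-wise via the Woodbury identity. A boundary fit (λ → 0)
reduces to OLS and warns. Fixed-effect tests use t statistics on
*containment* degrees of freedom, n − rank(X) − (n_groups − 1): on a
balanced two-condition within-group design this reproduces the paired
t-test exactly (same t, same df, same p), which anchors the df convention
to a known-correct special case; for other designs it is an
approximation, documented as such. The logistic model is Newton–Raphson
IRLS with Wald Z tests; complete separation and constant responses are
detected and warned. Both engines are cross-checked in the test suite
against statsmodels (MixedLM, Logit) as independent implementations.

Backward elimination refits after dropping the highest-p removable term
(factors tested jointly by Wald) while p > α (default 0.05); the focal
treatment is protected and never dropped, and both the full and final
fits plus the elimination trace are reported. Pairwise treatment
contrasts come from refitting with each factor level as the reference —
a pure reparameterization, so fitted values and deviance are unchanged
(tested to 10⁻⁹) and contrast antisymmetry holds by construction.
Alarm-call counts are analysed as Gaussian LMM responses; egg-difference
covariates enter the rejection model in their natural units (JND for
colour/luminance) so the colour slope is interpretable per JND, with
shape and volume standardized inside their own descriptors. AIC-based
selection and Poisson count models are out of scope.

## Synthetic-data generators

A single top-level seed fans out to per-component child streams through
`SeedSequence` spawn keys, so adding a generator never perturbs existing
outputs, and every generator is byte-reproducible for a fixed seed.

**Specimens.** 8 specimens × 9 body regions per species. Species colour
loci sit at controlled chromatic separations from the focal female in
log-catch space — by default ~2.86 JND to the model group, ~3.92 to the
relatives and ~8.17 to conspecific males, the magnitudes the skin
analysis is meant to recover, with small per-species jitter. Specimens
scatter lognormally around their species locus (log-sd 0.02) and pixels
around the specimen (log-sd 0.04); with these scatters the pipeline's
recovered group means land close to the generating separations (the
noise inflation of a 2.86-JND separation is ≈ +0.1 JND). Region
luminance levels are *identical across species*, with specimen log-sd
0.0341 chosen so the expected pairwise luminance JND between independent
specimens is ≈ 0.77 (E|ΔlnL| = 2σ/√π at e_D = 0.05) — luminance is a
designed null. Textures are band-limited noise with a log-Gaussian
energy bump at a species-specific dominant scale: mimic and model group
similar (6 vs 6.5 px), relatives coarser (12 px), males finer (3 px).

**Egg experiment.** Arms of 17/16/18 pairs (the study's design). Clutch
ground colours come from a one-parameter polymorphic reflectance family
(a pigment absorption bump of varying centre/depth over a varying base),
sweeping blue-white to olive; the experimental egg is an independent
population draw, so host-vs-foreign colour JNDs range from mimetic to
conspicuous. The rejection outcome is Bernoulli with log-odds
α_arm + β·colourJND (β = 0.29 by default); α_arm is calibrated by root
finding so the arm's expected rejection rate equals the requested arm
rate (58.2 % / 62.5 % / 38.9 % by default). Nest-check tables (day 0–3)
are generated consistently with the outcome-classification rules and
round-trip through `classify_outcome` exactly.

**Aggression trials.** 15 pairs × 4 intruder models, randomized
presentation order, replicate models alternating. Alarm calls are
negative-binomial (dispersion 8) around model-type means with a
multiplicative pair intercept (log-sd 0.4, ICC ≈ 0.3); mobbing seconds
are Gaussian (pair sd 15 s, residual sd 25 s) censored to the 300-s
trial. The two female models share identical generating means — the
hosts-cannot-tell-them-apart premise — and males elicit far weaker
responses; order, replicate and nest-stage effects are zero, so backward
elimination should remove them.

**What the generators do not emulate.** Real plumage is spatially
organized (barring, streaking, patch boundaries), not stationary shaped
noise; real museum skins fade and vary with preparation; specimen colour
variation is phylogenetically structured; real egg spectra have
maculation that the "background colour" measurements only partially
avoid; behavioural counts are serially dependent within a trial. Passing
tests therefore demonstrate that the *pipeline* recovers known structure
from data of realistic dimension and noise — not that these biological
complications are handled.

## Problem sizes used in the automated checks

The test suite runs the ordering check at the full study design (8
specimens × 9 regions × 9 species) over 100 seeded replicates with
20×20-pixel patches, the engine-calibration null at 2000 replicates of
the 15-pair design, and slope recovery on one 10,000-pair arm; the
acceptance script simulates 10,000 replicate experiments per arm. Patch
size is the one dimension scaled below the field setting (2000-pixel
budget): the abundant-colour statistic is budget-independent by
construction, and 400 pixels keeps the full factorial design cheap.

## Known limitations

- LMM p-values rely on the containment-df t approximation; for strongly
  unbalanced designs a Satterthwaite or Kenward–Roger correction (not
  implemented) would be preferable.
- The receptor templates are idealized; absolute JND values depend on the
  sensitivity tables and Weber fractions supplied, and only *relative*
  structure should be compared across configurations.
- `abundant_colour` is exact but O(n²); budgets far above 2000 pixels
  will need an approximate neighbour count.
- Egg shape is two descriptors; curvature-based shape indices would
  discriminate more finely between similar ovoids.
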