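"""Synthetic study generators: specimens, egg experiments, aggression trials.

Everything the pipeline consumes can be simulated here with seeded
reproducibility, at the study's own dimensions (8 skins per species across
9 body regions; 15 breeding pairs × 4 intruder models; 17/16/18 pairs in
the three egg-rejection arms).

The plumage generator encodes the mimicry structure as ground truth:
species colour loci are placed at controlled chromatic JND separations from
the focal female mimic — by default ~2.86 JND to the model group
(*Euplectes*), ~3.92 to the relatives (*Vidua*) and ~8.17 to conspecific
males, matching the magnitudes the museum-skin analysis is meant to
recover.  Egg-rejection outcomes are Bernoulli draws from a logistic model
in the host-vs-foreign colour JND, with each arm's intercept calibrated so
the marginal rejection rate equals the requested arm rate.

A single top-level seed fans out to per-component child streams via
``numpy.random.SeedSequence`` spawn keys, so adding a generator never
perturbs existing outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .calibration import BODY_REGIONS
from .eggs import EggRecord, egg_volume_shape, egg_pattern_diff, shape_distance
from .plumage import ConeCatchPatch, SpecimenSet
from .vision import (Spectrum, ReceptorSet, builtin_receptor_set,
                     flat_illuminant, jnd_quadratic_form, interpolate_spectrum)

__all__ = [
    "TaxonSpec",
    "ExperimentSpec",
    "EggExperimentTables",
    "default_taxa",
    "generate_specimens",
    "generate_egg_experiment",
    "generate_aggression_trials",
    "MODEL_SEPARATION_JND",
    "RELATIVE_SEPARATION_JND",
    "MALE_SEPARATION_JND",
]

#: Default mimic-to-group chromatic separations (JND) used to calibrate the
#: synthetic taxa; anchored to the magnitudes of the skin analysis.
MODEL_SEPARATION_JND = 2.86
RELATIVE_SEPARATION_JND = 3.92
MALE_SEPARATION_JND = 8.17

#: Specimen-level luminance log-sd chosen so that the expected pairwise
#: luminance JND between independent specimens is ~0.77 at e_D = 0.05
#: (E|Δln L| = 2σ/√π).
LUMINANCE_LOG_SD = 0.77 * 0.05 * math.sqrt(math.pi) / 2.0


def _child_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# museum-skin specimens


@dataclass
class TaxonSpec:
    """Generator parameters for one species' plumage."""

    name: str
    group: str  # focal_mimic | conspecific_male | Euplectes | Vidua
    region_colour_centres: dict[str, np.ndarray]  # chromatic catch loci
    region_luminance: dict[str, float]
    pattern_scale_px: float = 6.0      # dominant marking scale
    pattern_amplitude: float = 0.06    # texture contrast (luminance units)
    n_specimens: int = 8
    specimen_log_sd: float = 0.02
    pixel_log_sd: float = 0.04
    luminance_log_sd: float = LUMINANCE_LOG_SD
    patch_shape: tuple[int, int] = (20, 20)

    def __post_init__(self):
        if self.n_specimens < 2:
            raise ValueError("need at least 2 specimens per taxon")
        for r, c in self.region_colour_centres.items():
            if np.any(np.asarray(c) <= 0):
                raise ValueError(f"non-positive colour locus in region {r!r}")


def _jnd_direction(direction: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Normalize a log-catch direction to unit chromatic JND length."""
    d = np.asarray(direction, dtype=float)
    return d / math.sqrt(d @ Q @ d)


def default_taxa(receptors: ReceptorSet | None = None,
                 n_model_species: int = 4, n_relative_species: int = 3,
                 n_specimens: int = 8,
                 regions: tuple[str, ...] = BODY_REGIONS,
                 model_sep: float = MODEL_SEPARATION_JND,
                 relative_sep: float = RELATIVE_SEPARATION_JND,
                 male_sep: float = MALE_SEPARATION_JND) -> list[TaxonSpec]:
    """The study-shaped taxon list: focal mimic, conspecific male, model and
    relative species, with colour loci at calibrated JND separations."""
    if receptors is None:
        receptors = builtin_receptor_set("trichrom_skins")
    w = receptors.weber_fractions()
    Q = jnd_quadratic_form(w)
    k = len(receptors.chromatic_names)

    rng = np.random.default_rng(12345)  # fixed: taxon definitions are data
    base = {}
    lum = {}
    for i, region in enumerate(regions):
        level = 0.25 + 0.35 * (i / max(len(regions) - 1, 1))
        tilt = 0.15 * np.sin(np.linspace(0, np.pi, k) + i)
        base[region] = level * np.exp(tilt)
        lum[region] = 0.25 + 0.3 * (i / max(len(regions) - 1, 1))

    d_model = _jnd_direction(np.array([1.0, 0.0, -1.0]), Q)
    d_rel = _jnd_direction(np.array([0.0, 1.0, -1.0]), Q)
    d_male = _jnd_direction(np.array([1.0, -1.0, 0.0]), Q)

    def shifted(direction, jnd):
        return {r: base[r] * np.exp(jnd * direction) for r in regions}

    taxa = [
        TaxonSpec("female_cuckoo_finch", "focal_mimic",
                  {r: base[r].copy() for r in regions}, dict(lum),
                  pattern_scale_px=6.0, pattern_amplitude=0.060,
                  n_specimens=n_specimens),
        TaxonSpec("male_cuckoo_finch", "conspecific_male",
                  shifted(d_male, male_sep), dict(lum),
                  pattern_scale_px=3.0, pattern_amplitude=0.035,
                  n_specimens=n_specimens),
    ]
    for i in range(n_model_species):
        jitter = rng.normal(0, 0.1)
        taxa.append(TaxonSpec(
            f"euplectes_sp{i + 1}", "Euplectes",
            shifted(d_model, model_sep + jitter), dict(lum),
            pattern_scale_px=6.5, pattern_amplitude=0.065,
            n_specimens=n_specimens))
    for i in range(n_relative_species):
        jitter = rng.normal(0, 0.1)
        taxa.append(TaxonSpec(
            f"vidua_sp{i + 1}", "Vidua",
            shifted(d_rel, relative_sep + jitter), dict(lum),
            pattern_scale_px=12.0, pattern_amplitude=0.10,
            n_specimens=n_specimens))
    return taxa


def _shaped_texture(rng: np.random.Generator, shape: tuple[int, int],
                    scale_px: float, amplitude: float) -> np.ndarray:
    """Band-limited noise with a log-Gaussian energy bump at one scale."""
    h, w = shape
    noise = rng.standard_normal(shape)
    F = np.fft.fft2(noise)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    rho = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        lam = np.where(rho > 0, 1.0 / rho, np.inf)
    amp = np.exp(-0.5 * ((np.log(lam) - np.log(scale_px)) / 0.35) ** 2)
    amp[rho == 0] = 0.0
    tex = np.fft.ifft2(F * amp).real
    sd = tex.std()
    if sd > 0:
        tex *= amplitude / sd
    return tex


def generate_specimens(taxa: list[TaxonSpec] | None = None, seed: int = 0,
                       receptors: ReceptorSet | None = None
                       ) -> tuple[SpecimenSet, list[SpecimenSet],
                                  pd.DataFrame]:
    """Simulate patch images for every specimen of every taxon.

    Per specimen × region, pixel chromatic catches scatter lognormally
    around the specimen's colour locus (itself a lognormal draw around the
    taxon-region centre), and the double-cone (luminance) image is the
    region's base level plus band-limited texture shaped to the taxon's
    dominant marking scale.  Returns the focal set, the other sets, and a
    ground-truth table of the true locus separations.
    """
    if receptors is None:
        receptors = builtin_receptor_set("trichrom_skins")
    if taxa is None:
        taxa = default_taxa(receptors)
    w = receptors.weber_fractions()
    Q = jnd_quadratic_form(w)
    chrom_names = receptors.chromatic_names

    focal = next(t for t in taxa if t.group == "focal_mimic")
    sets: list[SpecimenSet] = []
    truth_rows = []
    for ti, taxon in enumerate(taxa):
        rng = _child_rng(seed, 0, ti)
        patches: dict[str, dict[str, ConeCatchPatch]] = {}
        for si in range(taxon.n_specimens):
            sid = f"{taxon.name}_{si:02d}"
            patches[sid] = {}
            for region, centre in taxon.region_colour_centres.items():
                h, wd = taxon.patch_shape
                n_px = h * wd
                locus = centre * np.exp(
                    rng.normal(0, taxon.specimen_log_sd, centre.size))
                catches = locus * np.exp(
                    rng.normal(0, taxon.pixel_log_sd, (n_px, centre.size)))
                lum_mean = (taxon.region_luminance[region]
                            * np.exp(rng.normal(0, taxon.luminance_log_sd)))
                grid = lum_mean + _shaped_texture(
                    rng, taxon.patch_shape, taxon.pattern_scale_px,
                    taxon.pattern_amplitude)
                grid = np.clip(grid, 1e-4, None)
                patches[sid][region] = ConeCatchPatch(
                    region=region, catches=catches, luminance=grid.ravel(),
                    receptor_names=chrom_names, luminance_grid=grid,
                    grid_mask=None)
        sset = SpecimenSet(taxon.name, taxon.group, patches)
        if taxon.group == "focal_mimic":
            focal_set = sset
        else:
            sets.append(sset)
        for region in taxon.region_colour_centres:
            df_log = (np.log(taxon.region_colour_centres[region])
                      - np.log(focal.region_colour_centres[region]))
            truth_rows.append({
                "taxon": taxon.name, "group": taxon.group, "region": region,
                "true_colour_jnd_to_focal":
                    float(math.sqrt(max(df_log @ Q @ df_log, 0.0))),
                "pattern_scale_px": taxon.pattern_scale_px,
                "pattern_amplitude": taxon.pattern_amplitude,
            })
    return focal_set, sets, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# egg-rejection experiment


@dataclass
class ExperimentSpec:
    """Dimensions and effect sizes of the behavioural experiments.

    Defaults mirror the study: rejection arms of 17/16/18 pairs with arm
    rejection rates 58.2% / 62.5% / 38.9%, a colour-JND log-odds slope of
    0.29 per JND, and 15 pairs × 4 intruder models for the aggression
    trials.
    """

    arms: dict[str, int] = field(default_factory=lambda: {
        "female_cuckoo_finch": 17, "female_bishop": 16, "male_bishop": 18})
    arm_rejection_probs: dict[str, float] = field(default_factory=lambda: {
        "female_cuckoo_finch": 0.582, "female_bishop": 0.625,
        "male_bishop": 0.389})
    colour_jnd_effect: float = 0.29
    clutch_size: int = 3
    n_replicate_spectra: int = 5
    spectrum_noise_sd: float = 0.01
    mistaken_rejection_prob: float = 0.1
    # aggression-trial block
    n_pairs: int = 15
    # hosts cannot tell the two female models apart, so their generating
    # means are equal; males elicit far weaker responses
    alarm_means: dict[str, float] = field(default_factory=lambda: {
        "female_cuckoo_finch": 35.0, "male_cuckoo_finch": 10.0,
        "female_bishop": 35.0, "male_bishop": 10.0})
    mobbing_means: dict[str, float] = field(default_factory=lambda: {
        "female_cuckoo_finch": 70.0, "male_cuckoo_finch": 17.0,
        "female_bishop": 70.0, "male_bishop": 17.0})
    alarm_pair_log_sd: float = 0.4
    alarm_dispersion: float = 8.0   # negative-binomial shape
    mobbing_pair_sd: float = 15.0
    mobbing_resid_sd: float = 25.0
    trial_seconds: float = 300.0

    def __post_init__(self):
        for a, p in self.arm_rejection_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"arm {a}: probability {p} outside [0, 1]")
        if any(n < 1 for n in self.arms.values()):
            raise ValueError("arm sizes must be >= 1")


@dataclass
class EggExperimentTables:
    """Output bundle of :func:`generate_egg_experiment`."""

    rejection: pd.DataFrame
    nest_checks: pd.DataFrame
    spectra: pd.DataFrame | None
    outlines: pd.DataFrame | None
    ground_truth: dict


_EGG_GRID = np.arange(300.0, 701.0)


def _egg_reflectance(rng, centre_nm: float, depth: float,
                     base: float) -> np.ndarray:
    """Polymorphic ground-colour family: broad pigment absorption bump.

    ``centre_nm`` near 550-650 with shallow depth reads blue-white; deeper
    absorption centred lower reads olive/brown — a one-parameter sweep
    through the natural polymorphism.
    """
    bump = depth * np.exp(-0.5 * ((_EGG_GRID - centre_nm) / 60.0) ** 2)
    r = base - bump
    return np.clip(r, 0.02, 1.0)


def _sens_matrix(receptors: ReceptorSet, names) -> np.ndarray:
    return np.column_stack([
        interpolate_spectrum(receptors.sensitivities[n], _EGG_GRID).value
        for n in names])


def _egg_outline(rng, length_mm: float, width_mm: float,
                 asym: float, n_pts: int = 60) -> np.ndarray:
    """Ovoid boundary: ellipse tapered toward one pole."""
    t = np.linspace(0, 2 * np.pi, n_pts, endpoint=False)
    a, b = length_mm / 2.0, width_mm / 2.0
    x = a * np.cos(t)
    y = b * np.sin(t) * (1.0 - asym * np.cos(t))
    return np.column_stack([x, y])


def _calibrate_alpha(jnds: np.ndarray, beta: float, p: float) -> float:
    """Arm intercept so the mean rejection probability over pairs equals p."""
    if p <= 0.0 or p >= 1.0:
        if beta != 0.0 and np.ptp(jnds) > 0:
            raise ValueError(
                f"cannot calibrate an arm rate of {p} with a non-zero "
                "colour effect (probabilities saturate)")
        return 40.0 if p >= 1.0 else -40.0
    if beta == 0.0 or np.ptp(jnds) == 0:
        return math.log(p / (1 - p)) - beta * float(np.mean(jnds))

    def gap(alpha):
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + beta * jnds))))) - p

    return float(optimize.brentq(gap, -60.0, 60.0))


def generate_egg_experiment(spec: ExperimentSpec | None = None, seed: int = 0,
                            receptors: ReceptorSet | None = None,
                            covariates: tuple[str, ...] = (
                                "colour", "luminance", "pattern", "shape",
                                "volume"),
                            keep_raw: bool | None = None
                            ) -> EggExperimentTables:
    """Simulate one coupled model-presentation / egg-rejection experiment.

    Each breeding pair gets a clutch whose ground colour is a draw from a
    polymorphic reflectance family, plus an experimental egg drawn
    independently from the population, each egg carrying replicate
    measurement spectra.  The rejection outcome is Bernoulli with log-odds
    ``α_arm + β · colour JND``, the arm intercept calibrated so the arm's
    expected rejection rate equals ``spec.arm_rejection_probs``.  Nest-check
    records consistent with the outcome-classification rules accompany each
    clutch.  ``covariates`` selects which measured egg-difference covariates
    to compute (shape/volume need the outline geometry and are the slow
    ones); ``keep_raw`` controls whether long-format spectra/outline tables
    are materialized (defaults to True for small experiments).
    """
    if spec is None:
        spec = ExperimentSpec()
    if receptors is None:
        receptors = builtin_receptor_set("tetra_uvs")
    beta = spec.colour_jnd_effect
    n_total = sum(spec.arms.values())
    if keep_raw is None:
        keep_raw = n_total <= 200

    chrom = receptors.chromatic_names
    all_names = receptors.names
    S = _sens_matrix(receptors, all_names)
    ill = flat_illuminant(_EGG_GRID[0], _EGG_GRID[-1])
    ill_v = interpolate_spectrum(ill, _EGG_GRID).value
    # trapezoid quadrature weights on the 1-nm grid (matches the spectrum
    # integration used everywhere else in the package)
    tw = np.ones_like(_EGG_GRID)
    tw[0] = tw[-1] = 0.5
    ill_v = ill_v * tw
    denom = ill_v @ S
    w = receptors.weber_fractions()
    Q = jnd_quadratic_form(w)
    chrom_idx = [all_names.index(n) for n in chrom]
    dbl_idx = (all_names.index(receptors.double_cone)
               if receptors.double_cone else None)

    vs_receptors = builtin_receptor_set("tetra_vs")
    want_vs = "colour_vs" in covariates
    if want_vs:
        S_vs = _sens_matrix(vs_receptors, vs_receptors.chromatic_names)
        denom_vs = ill_v @ S_vs
        Q_vs = jnd_quadratic_form(vs_receptors.weber_fractions())

    rows: list[dict] = []
    check_rows: list[dict] = []
    spectra_rows: list[dict] = []
    outline_rows: list[dict] = []
    truth_alphas: dict[str, float] = {}

    pair_counter = 0
    for ai, (arm, n_arm) in enumerate(spec.arms.items()):
        rng = _child_rng(seed, 1, ai)
        arm_jnds = np.empty(n_arm)
        arm_rows = []
        for pi in range(n_arm):
            pair_counter += 1
            pid = f"pair_{pair_counter:04d}"
            clutch_id = f"clutch_{pair_counter:04d}"
            n_eggs = spec.clutch_size + 1  # own clutch + experimental egg
            # clutch-level ground colour; experimental egg independent
            c_centre = rng.uniform(480.0, 640.0)
            c_depth = rng.uniform(0.05, 0.45)
            c_base = rng.uniform(0.45, 0.85)
            e_centre = rng.uniform(480.0, 640.0)
            e_depth = rng.uniform(0.05, 0.45)
            e_base = rng.uniform(0.45, 0.85)

            egg_means = []
            egg_ids = []
            roles = []
            for ei in range(n_eggs):
                if ei < spec.clutch_size:
                    mu = _egg_reflectance(rng, c_centre + rng.normal(0, 4.0),
                                          c_depth * np.exp(rng.normal(0, .05)),
                                          c_base * np.exp(rng.normal(0, .03)))
                    roles.append("host")
                else:
                    mu = _egg_reflectance(rng, e_centre, e_depth, e_base)
                    roles.append("experimental")
                reps = mu[None, :] + rng.normal(
                    0, spec.spectrum_noise_sd,
                    (spec.n_replicate_spectra, mu.size))
                reps = np.clip(reps, 0.0, 1.5)
                mean_r = reps.mean(axis=0)
                egg_means.append(mean_r)
                egg_ids.append(f"{clutch_id}_egg{ei + 1}")
                if keep_raw:
                    for ri, rep in enumerate(reps):
                        for wl, rv in zip(_EGG_GRID[::20], rep[::20]):
                            spectra_rows.append({
                                "egg_id": egg_ids[-1], "replicate": ri + 1,
                                "wavelength_nm": wl, "reflectance": rv})
            R = np.vstack(egg_means)
            catches = np.maximum((R * ill_v) @ S / denom, 1e-9)
            host_q = catches[:spec.clutch_size]
            exp_q = catches[spec.clutch_size]
            ref = host_q.mean(axis=0)
            df_log = np.log(ref[chrom_idx]) - np.log(exp_q[chrom_idx])
            colour = float(math.sqrt(max(df_log @ Q @ df_log, 0.0)))
            arm_jnds[pi] = colour
            row = {"pair_id": pid, "clutch_id": clutch_id,
                   "model_type": arm, "colour_jnd": colour}
            if "luminance" in covariates and dbl_idx is not None:
                row["luminance_jnd"] = float(
                    abs(math.log(ref[dbl_idx] / exp_q[dbl_idx]))
                    / receptors.double_cone_weber)
            if want_vs:
                catches_vs = np.maximum((R * ill_v) @ S_vs / denom_vs, 1e-9)
                dfv = (np.log(catches_vs[:spec.clutch_size].mean(axis=0))
                       - np.log(catches_vs[spec.clutch_size]))
                row["colour_jnd_vs"] = float(
                    math.sqrt(max(dfv @ Q_vs @ dfv, 0.0)))
            if "pattern" in covariates:
                host_tex = 0.5 + _shaped_texture(rng, (24, 24),
                                                 rng.uniform(2.5, 5.0),
                                                 rng.uniform(0.02, 0.10))
                exp_tex = 0.5 + _shaped_texture(rng, (24, 24),
                                                rng.uniform(2.5, 5.0),
                                                rng.uniform(0.02, 0.10))
                row["pattern_diff"] = egg_pattern_diff(host_tex, exp_tex)
            if "shape" in covariates or "volume" in covariates:
                shapes = []
                for role_tag in ("host", "experimental"):
                    ln = rng.normal(15.5, 0.6)
                    wd = rng.normal(11.2, 0.45)
                    asym = abs(rng.normal(0.12, 0.03))
                    out = _egg_outline(rng, ln, wd, asym)
                    shapes.append(egg_volume_shape(out))
                    if keep_raw:
                        eid = (egg_ids[0] if role_tag == "host"
                               else egg_ids[-1])
                        for (x, y) in out:
                            outline_rows.append({"egg_id": eid,
                                                 "x_mm": x, "y_mm": y})
                if "shape" in covariates:
                    row["shape_diff"] = shape_distance(
                        shapes[0], shapes[1], scales=(0.08, 0.03))
                if "volume" in covariates:
                    row["volume_diff"] = abs(shapes[0].volume_mm3
                                             - shapes[1].volume_mm3)
            arm_rows.append(row)
        p_arm = spec.arm_rejection_probs[arm]
        alpha = _calibrate_alpha(arm_jnds, beta, p_arm)
        truth_alphas[arm] = alpha
        logits = alpha + beta * arm_jnds
        probs = 1.0 / (1.0 + np.exp(-logits))
        outcomes = rng.random(n_arm) < probs
        for row, rej in zip(arm_rows, outcomes):
            row["rejected"] = int(rej)
            row["outcome"] = "rejected" if rej else "accepted"
            row["mistaken_own_rejection"] = bool(
                rej and rng.random() < spec.mistaken_rejection_prob)
            n0 = spec.clutch_size + 1
            d_rej = int(rng.integers(1, 4)) if rej else None
            for d in (0, 1, 2, 3):  # day 0 = insertion check
                n_now = n0 - (1 if rej and d >= d_rej else 0)
                check_rows.append({"clutch_id": row["clutch_id"],
                                   "day": d, "n_eggs": n_now,
                                   "incubating": True})
        rows.extend(arm_rows)

    return EggExperimentTables(
        rejection=pd.DataFrame(rows),
        nest_checks=pd.DataFrame(check_rows),
        spectra=pd.DataFrame(spectra_rows) if keep_raw else None,
        outlines=pd.DataFrame(outline_rows) if keep_raw else None,
        ground_truth={"alphas": truth_alphas, "beta": beta,
                      "arm_rejection_probs": dict(spec.arm_rejection_probs)})


# ---------------------------------------------------------------------------
# aggression trials


def generate_aggression_trials(spec: ExperimentSpec | None = None,
                               seed: int = 0) -> pd.DataFrame:
    """Simulate the 15-pair × 4-model aggression experiment.

    Each pair sees all four intruder models in a randomized order (model
    replicate alternating between the two physical models); alarm-call
    counts are negative-binomial around model-type means with a
    multiplicative pair intercept, and mobbing seconds are Gaussian around
    model-type means with an additive pair intercept, censored to the
    300-second trial.  Order, replicate and nest-stage effects are zero by
    construction, so backward elimination should remove them.
    """
    if spec is None:
        spec = ExperimentSpec()
    rng = _child_rng(seed, 2)
    model_types = list(spec.alarm_means)
    rows = []
    for pi in range(spec.n_pairs):
        pid = f"pair_{pi + 1:03d}"
        order = rng.permutation(len(model_types))
        pair_alarm = math.exp(rng.normal(0, spec.alarm_pair_log_sd))
        pair_mob = rng.normal(0, spec.mobbing_pair_sd)
        stage = "laying" if rng.random() < 0.5 else "early_incubation"
        for slot, mi in enumerate(order):
            mt = model_types[mi]
            mu_alarm = spec.alarm_means[mt] * pair_alarm
            alarm = rng.negative_binomial(
                spec.alarm_dispersion,
                spec.alarm_dispersion / (spec.alarm_dispersion + mu_alarm))
            mob = rng.normal(spec.mobbing_means[mt] + pair_mob,
                             spec.mobbing_resid_sd)
            rows.append({
                "pair_id": pid, "model_type": mt,
                "presentation_order": slot + 1,
                "model_replicate": int(rng.integers(1, 3)),
                "nest_stage": stage,
                "alarm_calls": int(alarm),
                "mobbing_seconds": float(np.clip(mob, 0.0,
                                                 spec.trial_seconds)),
            })
    return pd.DataFrame(rows)
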