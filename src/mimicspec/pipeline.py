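"""End-to-end pipeline stages behind the command-line interface.

Each stage reads/writes plain files under a bundle directory so a full run
is reproducible from its manifest alone: ``simulate`` writes a complete
synthetic input bundle (cone-catch patch images as float TIFFs, behavioural
CSV tables, ground truth), ``plumage-compare`` builds the specimen-pair
comparison tables, ``egg-analysis`` classifies nest outcomes,
``behaviour-stats`` runs the inference stages, and ``report`` assembles the
summary tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import BODY_REGIONS
from .eggs import classify_outcome
from .plumage import ConeCatchPatch, SpecimenSet, build_comparison_table
from .simulate import (ExperimentSpec, default_taxa, generate_specimens,
                       generate_egg_experiment, generate_aggression_trials)
from .stats import run_paper_models
from .vision import builtin_receptor_set

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_simulate", "run_plumage_compare",
           "run_egg_analysis", "run_behaviour_stats", "run_report"]


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run."""

    bundle_dir: str = "bundle"
    out_dir: str = "out"
    receptor_set: str = "trichrom_skins"
    egg_receptor_set: str = "tetra_uvs"
    jnd_radius: float = 2.0
    n_luminance_bins: int = 32
    n_pattern_scales: int = 33
    pixel_budget: int = 2000
    double_cone_weber: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    n_specimens: int = 8
    n_model_species: int = 4
    n_relative_species: int = 3

    def __post_init__(self):
        for name in ("jnd_radius", "n_luminance_bins", "n_pattern_scales",
                     "pixel_budget", "double_cone_weber", "n_specimens"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"config parameter {name!r} must be positive "
                    f"(got {getattr(self, name)}); a zero JND radius, for "
                    "instance, makes every abundant-colour count zero")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(cfg: PipelineConfig, out: Path, stage: str):
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"stage": stage, "config": asdict(cfg),
                "config_hash": cfg.digest(), "seed": cfg.seed,
                "version": __version__}
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2))


def run_simulate(cfg: PipelineConfig) -> Path:
    """Write a complete synthetic input bundle under ``cfg.bundle_dir``."""
    import tifffile

    bundle = Path(cfg.bundle_dir)
    (bundle / "specimens").mkdir(parents=True, exist_ok=True)
    receptors = builtin_receptor_set(cfg.receptor_set)
    taxa = default_taxa(receptors, n_model_species=cfg.n_model_species,
                        n_relative_species=cfg.n_relative_species,
                        n_specimens=cfg.n_specimens)
    focal, others, truth = generate_specimens(taxa, seed=cfg.seed,
                                              receptors=receptors)
    channel_names = list(receptors.chromatic_names) + ["DBL"]
    rows = []
    for sset in [focal, *others]:
        for sid, regions in sset.patches.items():
            for region, patch in regions.items():
                h, w = patch.luminance_grid.shape
                img = np.concatenate(
                    [patch.catches.reshape(h, w, -1),
                     patch.luminance_grid[:, :, None]], axis=2)
                rel = f"specimens/{sid}_{region}.tif"
                tifffile.imwrite(bundle / rel, img.astype(np.float32))
                rows.append({"specimen_id": sid, "species": sset.name,
                             "taxon_group": sset.group, "region": region,
                             "image_path": rel,
                             "channels": ",".join(channel_names)})
    pd.DataFrame(rows).to_csv(bundle / "manifest.csv", index=False)
    truth.to_csv(bundle / "ground_truth_specimens.csv", index=False)

    trials = generate_aggression_trials(ExperimentSpec(), seed=cfg.seed)
    trials.to_csv(bundle / "trials.csv", index=False)
    eggs = generate_egg_experiment(ExperimentSpec(), seed=cfg.seed)
    eggs.rejection.to_csv(bundle / "rejection.csv", index=False)
    eggs.nest_checks.to_csv(bundle / "nest_checks.csv", index=False)
    if eggs.spectra is not None:
        eggs.spectra.to_csv(bundle / "egg_spectra.csv", index=False)
    if eggs.outlines is not None:
        eggs.outlines.to_csv(bundle / "egg_outlines.csv", index=False)
    (bundle / "ground_truth_eggs.json").write_text(
        json.dumps(eggs.ground_truth, indent=2))
    _write_manifest(cfg, bundle, "simulate")
    logger.info("bundle written to %s", bundle)
    return bundle


def _load_specimen_sets(cfg: PipelineConfig):
    import tifffile

    bundle = Path(cfg.bundle_dir)
    manifest = pd.read_csv(bundle / "manifest.csv")
    receptors = builtin_receptor_set(cfg.receptor_set)
    chrom = receptors.chromatic_names
    rng = np.random.default_rng(cfg.seed)
    sets: dict[str, SpecimenSet] = {}
    for (species, group), sub in manifest.groupby(["species", "taxon_group"]):
        patches: dict[str, dict[str, ConeCatchPatch]] = {}
        for _, row in sub.iterrows():
            img = tifffile.imread(bundle / row["image_path"]).astype(float)
            catches = img[:, :, :len(chrom)].reshape(-1, len(chrom))
            lum_grid = img[:, :, len(chrom)]
            if catches.shape[0] > cfg.pixel_budget:
                keep = np.sort(rng.choice(catches.shape[0], cfg.pixel_budget,
                                          replace=False))
                catches = catches[keep]
                lum = lum_grid.ravel()[keep]
            else:
                lum = lum_grid.ravel()
            patches.setdefault(row["specimen_id"], {})[row["region"]] = \
                ConeCatchPatch(region=row["region"],
                               catches=np.maximum(catches, 1e-9),
                               luminance=np.maximum(lum, 1e-9),
                               receptor_names=chrom,
                               luminance_grid=np.maximum(lum_grid, 1e-9))
        sets[species] = SpecimenSet(species, group, patches)
    focal = next(s for s in sets.values() if s.group == "focal_mimic")
    others = [s for s in sets.values() if s.group != "focal_mimic"]
    return focal, others, receptors


def run_plumage_compare(cfg: PipelineConfig) -> Path:
    """Build the specimen-pair comparison tables from the image bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    focal, others, receptors = _load_specimen_sets(cfg)
    result = build_comparison_table(focal, others,
                                    receptors.weber_fractions(),
                                    e_d=cfg.double_cone_weber)
    result.records.to_csv(out / "plumage_records.csv", index=False)
    result.species_region_means.to_csv(out / "plumage_species_means.csv",
                                       index=False)
    result.group_region_means.to_csv(out / "plumage_group_means.csv",
                                     index=False)
    _write_manifest(cfg, out, "plumage_compare")
    return out


def run_egg_analysis(cfg: PipelineConfig) -> Path:
    """Classify nest outcomes from check records and assemble covariates."""
    bundle, out = Path(cfg.bundle_dir), Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rejection = pd.read_csv(bundle / "rejection.csv")
    checks = pd.read_csv(bundle / "nest_checks.csv")
    classified = {cid: classify_outcome(sub)
                  for cid, sub in checks.groupby("clutch_id")}
    rejection["outcome_from_checks"] = rejection["clutch_id"].map(classified)
    keep = rejection["outcome_from_checks"].isin(["rejected", "accepted"])
    n_excl = int((~keep).sum())
    if n_excl:
        logger.warning("excluding %d unresolved/depredated clutches", n_excl)
    analysed = rejection[keep].copy()
    analysed["rejected"] = (analysed["outcome_from_checks"]
                            == "rejected").astype(int)
    analysed.to_csv(out / "egg_analysis.csv", index=False)
    _write_manifest(cfg, out, "egg_analysis")
    return out


def run_behaviour_stats(cfg: PipelineConfig) -> Path:
    """Run the three inference stages and write coefficient tables."""
    bundle, out = Path(cfg.bundle_dir), Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plumage = None
    species_means = out / "plumage_species_means.csv"
    if species_means.exists():
        plumage = pd.read_csv(species_means)
    trials = pd.read_csv(bundle / "trials.csv")
    egg_path = out / "egg_analysis.csv"
    rejection = (pd.read_csv(egg_path) if egg_path.exists()
                 else pd.read_csv(bundle / "rejection.csv"))
    reports = run_paper_models(plumage, trials, rejection, alpha=cfg.alpha)
    trace_lines = []
    for name, rep in reports.items():
        rep.full.to_frame().to_csv(out / f"model_{name}_full.csv")
        rep.final.to_frame().to_csv(out / f"model_{name}_final.csv")
        rep.contrasts.to_csv(out / f"model_{name}_contrasts.csv", index=False)
        trace_lines.append(f"== {name} ==")
        if rep.trace:
            for step in rep.trace:
                trace_lines.append(
                    f"dropped {step['dropped']} (p = {step['p']:.4f})")
        else:
            trace_lines.append("no terms dropped")
    (out / "elimination_trace.txt").write_text("\n".join(trace_lines) + "\n")
    _write_manifest(cfg, out, "behaviour_stats")
    return out


def run_report(cfg: PipelineConfig) -> Path:
    """Assemble the group-mean and model-coefficient summary report."""
    out = Path(cfg.out_dir)
    lines = [f"# mimicspec run report (seed {cfg.seed}, "
             f"config {cfg.digest()})", ""]
    gm = out / "plumage_group_means.csv"
    if gm.exists():
        df = pd.read_csv(gm)
        lines += ["## Plumage difference group means (focal vs group, "
                  "by region)", "", df.to_string(index=False), ""]
        overall = df.groupby("taxon_group").mean(numeric_only=True)
        lines += ["### Overall (across regions)", "",
                  overall.to_string(), ""]
    for f in sorted(out.glob("model_*_contrasts.csv")):
        lines += [f"## {f.stem}", "", pd.read_csv(f).to_string(index=False),
                  ""]
    report = out / "report.md"
    report.write_text("\n".join(lines))
    _write_manifest(cfg, out, "report")
    return report
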