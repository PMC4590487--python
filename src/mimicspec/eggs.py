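"""Host-vs-experimental egg difference quantification.

Egg background colour is measured as replicate reflectance spectra (five per
egg by default, taken between pattern markings), mapped to tetrachromatic
cone catches and compared as chromatic / achromatic JNDs against the clutch
mean.  Eggshell pattern reuses the plumage granularity machinery.  Volume
and shape come from the egg's photographed outline treated as a solid of
revolution about its long axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vision import (ReceptorSet, Spectrum, cone_catch_from_spectrum,
                     chromatic_jnd, luminance_jnd, interpolate_spectrum,
                     flat_illuminant, ConeCatch)
from .plumage import pattern_energy, s_diff

__all__ = [
    "EggRecord",
    "EggDifference",
    "EggShape",
    "mean_spectrum",
    "replicate_cv",
    "egg_colour_luminance_jnd",
    "egg_pattern_diff",
    "egg_volume_shape",
    "shape_distance",
    "classify_outcome",
]


@dataclass
class EggRecord:
    """One egg: replicate background spectra plus optional outline/pattern."""

    clutch_id: str
    egg_id: str
    role: str  # "host" | "experimental"
    spectra: list[Spectrum]
    outline: np.ndarray | None = None       # ordered boundary points, mm
    pattern_patch: np.ndarray | None = None  # luminance grid of the shell

    def __post_init__(self):
        if self.role not in ("host", "experimental"):
            raise ValueError("role must be 'host' or 'experimental'")
        if len(self.spectra) < 2:
            raise ValueError("need at least 2 replicate spectra per egg")
        if self.outline is not None:
            pts = np.asarray(self.outline, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 20:
                raise ValueError("outline must be >= 20 ordered 2-D points")
            self.outline = pts


@dataclass
class EggDifference:
    """Host-clutch vs experimental-egg covariates for the rejection model."""

    colour_jnd: float
    luminance_jnd: float
    colour_jnd_vs: float | None = None
    pattern_diff: float | None = None
    shape_diff: float | None = None
    volume_diff: float | None = None


@dataclass(frozen=True)
class EggShape:
    """Solid-of-revolution descriptors of an egg outline."""

    volume_mm3: float
    length_mm: float
    max_width_mm: float
    elongation: float
    asymmetry: float


def mean_spectrum(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise mean of replicate spectra on their shared 1-nm grid."""
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates to average")
    lo = max(s.wavelength_nm[0] for s in replicates)
    hi = min(s.wavelength_nm[-1] for s in replicates)
    if hi <= lo:
        raise ValueError("replicates share no wavelength overlap")
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    vals = np.vstack([interpolate_spectrum(s, grid).value for s in replicates])
    return Spectrum(grid, vals.mean(axis=0), kind=replicates[0].kind)


def replicate_cv(replicates: list[Spectrum]) -> float:
    """Mean across wavelengths of the between-replicate CV (noise check)."""
    lo = max(s.wavelength_nm[0] for s in replicates)
    hi = min(s.wavelength_nm[-1] for s in replicates)
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    vals = np.vstack([interpolate_spectrum(s, grid).value for s in replicates])
    mu = vals.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, vals.std(axis=0, ddof=1) / mu, 0.0)
    return float(cv.mean())


def _egg_catch(egg: EggRecord, receptors: ReceptorSet,
               illuminant: Spectrum) -> ConeCatch:
    return cone_catch_from_spectrum(mean_spectrum(egg.spectra), illuminant,
                                    receptors)


def egg_colour_luminance_jnd(host_eggs: list[EggRecord], foreign: EggRecord,
                             receptors: ReceptorSet,
                             illuminant: Spectrum | None = None,
                             ) -> tuple[float, float]:
    """Chromatic and luminance JND of a foreign egg against the clutch.

    The clutch reference is the mean of the host eggs' von Kries catches;
    the chromatic distance uses the receptor set's chromatic cones
    (tetrachromatic by default), the achromatic one its double cone.
    A UVS receptor requires spectra that actually cover the UV band.
    """
    if not host_eggs:
        raise ValueError("clutch must contain at least one host egg")
    if illuminant is None:
        illuminant = flat_illuminant()
    uv_names = [n for n in receptors.chromatic_names if n.startswith("UV")]
    if uv_names:
        for egg in [*host_eggs, foreign]:
            for s in egg.spectra:
                if s.wavelength_nm[0] > 400:
                    raise ValueError(
                        f"egg {egg.egg_id}: spectra start at "
                        f"{s.wavelength_nm[0]} nm but receptor "
                        f"{uv_names[0]} needs the UV band")
    host_catches = [_egg_catch(e, receptors, illuminant) for e in host_eggs]
    ref_q = np.mean([c.q for c in host_catches], axis=0)
    ref = ConeCatch(ref_q, host_catches[0].receptor_names)
    fq = _egg_catch(foreign, receptors, illuminant)

    names = ref.receptor_names
    chrom = [i for i, n in enumerate(names) if n != receptors.double_cone]
    a = ConeCatch(ref.q[chrom], tuple(names[i] for i in chrom))
    b = ConeCatch(fq.q[chrom], tuple(names[i] for i in chrom))
    colour = chromatic_jnd(a, b, receptors.weber_fractions())
    if receptors.double_cone is not None:
        lum = luminance_jnd(ref[receptors.double_cone],
                            fq[receptors.double_cone],
                            receptors.double_cone_weber)
    else:
        lum = float("nan")
    return colour, lum


def egg_pattern_diff(host_patch: np.ndarray,
                     foreign_patch: np.ndarray) -> float:
    """Eggshell pattern difference via the shared granularity pipeline."""
    a = pattern_energy(host_patch)
    b = pattern_energy(foreign_patch)
    return s_diff(a, b)


def egg_volume_shape(outline: np.ndarray, n_samples: int = 200) -> EggShape:
    """Volume and shape of an egg from its 2-D outline.

    The outline is aligned to its principal (long) axis; the width profile
    ``w(x)`` is read off the polygon and the volume computed as a solid of
    revolution, ``V = π ∫ (w(x)/2)² dx``.  Elongation is length over maximum
    width; asymmetry is the offset of the widest section from mid-length,
    as a fraction of length (0 for a symmetric ovoid).
    """
    from shapely.geometry import Polygon, LineString

    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 20:
        raise ValueError("outline must be >= 20 ordered 2-D points")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("outline is self-intersecting or degenerate")

    centred = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    aligned = centred @ vt.T  # first axis = long axis
    poly = Polygon(aligned)
    x_lo, _, x_hi, _ = poly.bounds
    length = x_hi - x_lo
    if length <= 0:
        raise ValueError("outline has no extent along its long axis")

    xs = np.linspace(x_lo, x_hi, n_samples)
    widths = np.empty(n_samples)
    pad = 1e-9 * length
    for i, x in enumerate(xs):
        xq = min(max(x, x_lo + pad), x_hi - pad)
        cut = poly.intersection(
            LineString([(xq, poly.bounds[1] - 1), (xq, poly.bounds[3] + 1)]))
        widths[i] = cut.length
    volume = float(np.pi * np.trapezoid((widths / 2.0) ** 2, xs))
    max_w = float(widths.max())
    x_at_max = float(xs[int(np.argmax(widths))] - x_lo)
    return EggShape(volume_mm3=volume, length_mm=float(length),
                    max_width_mm=max_w, elongation=float(length / max_w),
                    asymmetry=float(abs(x_at_max - length / 2.0) / length))


def shape_distance(a: EggShape, b: EggShape,
                   scales: tuple[float, float] = (1.0, 1.0)) -> float:
    """Euclidean distance on (elongation, asymmetry) standardized by
    population scales — the single "shape difference" covariate."""
    de = (a.elongation - b.elongation) / scales[0]
    da = (a.asymmetry - b.asymmetry) / scales[1]
    return float(np.hypot(de, da))


def classify_outcome(observations: pd.DataFrame,
                     accept_days: int = 3) -> str:
    """Classify a clutch's fate from daily nest-check records.

    ``observations`` needs columns ``day`` (days since the experimental egg
    was inserted), ``n_eggs`` and ``incubating``.  A single missing egg at
    any check means rejection (predators typically take the whole clutch);
    an entirely missing clutch is depredation and is excluded; a clutch
    intact and under active incubation through ``accept_days`` days is
    accepted; anything else is unresolved and excluded.
    """
    if len(observations) < 1:
        raise ValueError("need at least one post-manipulation observation")
    obs = observations.sort_values("day").reset_index(drop=True)
    n0 = int(obs.loc[0, "n_eggs"])
    if n0 < 1:
        return "depredated/excluded"
    prev = n0
    for _, row in obs.iterrows():
        n = int(row["n_eggs"])
        if n > prev:
            raise ValueError(
                f"egg count increased from {prev} to {n} on day "
                f"{row['day']}: contradictory records")
        if n == 0:
            return "depredated/excluded"
        if n == n0 - 1:
            return "rejected"
        if n < n0 - 1:
            return "unresolved/excluded"
        prev = n
    last = obs.iloc[-1]
    if (int(last["n_eggs"]) == n0 and bool(last["incubating"])
            and float(last["day"]) >= accept_days):
        return "accepted"
    return "unresolved/excluded"
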