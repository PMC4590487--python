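"""Receptor-noise-limited avian visual modelling.

Maps reflectance spectra (or calibrated camera pixel values) to photoreceptor
quantum catches and computes chromatic and achromatic just-noticeable
differences (JNDs) under the receptor-noise-limited model of colour
discrimination.  A JND of ~1-3 is conventionally taken as the threshold of
discriminability under good light.

The chromatic distance between two stimuli ``a`` and ``b`` seen by ``n``
receptor classes with Weber fractions ``e_i`` is computed from the log catch
ratios ``Δf_i = ln(q_i^a / q_i^b)`` as::

    ΔS² = Σ_{i<j} (Π_{k∉{i,j}} e_k)² (Δf_i − Δf_j)²
          ─────────────────────────────────────────
          Σ_{|T|=n−1} (Π_{k∈T} e_k)²

which reduces to the familiar dichromat, trichromat and tetrachromat closed
forms.  Achromatic (luminance) contrast uses the double cone:
``|ln(qa/qb)| / e_D``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "ReceptorSet",
    "ConeCatch",
    "WeberFractions",
    "PolynomialMapping",
    "interpolate_spectrum",
    "cone_catch_from_spectrum",
    "fit_camera_to_cone",
    "apply_camera_to_cone",
    "chromatic_jnd",
    "luminance_jnd",
    "weber_from_abundances",
    "jnd_quadratic_form",
    "pairwise_chromatic_jnd",
    "gaussian_receptor",
    "builtin_receptor_set",
    "flat_illuminant",
    "CATCH_FLOOR",
]

#: Catches are floored here before any logarithm; avoids -inf from dark
#: pixels while perturbing JNDs negligibly.
CATCH_FLOOR = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A function of wavelength: reflectance, radiance or sensitivity.

    Parameters
    ----------
    wavelength_nm : array
        Strictly ascending wavelength grid, restricted to [300, 700] nm.
    value : array
        Non-negative values, one per wavelength.  Reflectance spectra may
        exceed 1 slightly (measurement noise) but not 1.5.
    """

    wavelength_nm: np.ndarray
    value: np.ndarray
    kind: str = "reflectance"

    def __post_init__(self):
        wl = np.asarray(self.wavelength_nm, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or v.shape != wl.shape:
            raise ValueError("wavelength and value must be matching 1-D arrays")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if wl[0] < 300 - 1e-9 or wl[-1] > 700 + 1e-9:
            raise ValueError("wavelengths must lie within [300, 700] nm")
        if np.any(v < 0):
            raise ValueError("spectral values must be non-negative")
        if self.kind == "reflectance" and np.any(v > 1.5):
            raise ValueError("reflectance above 1.5 is not physical")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", v)

    @classmethod
    def flat(cls, level: float, lo: float = 300, hi: float = 700,
             kind: str = "reflectance") -> "Spectrum":
        grid = np.arange(lo, hi + 1.0)
        return cls(grid, np.full(grid.size, float(level)), kind=kind)

    @classmethod
    def from_csv(cls, path, kind: str = "reflectance") -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(),
                   kind=kind)


def interpolate_spectrum(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum onto a new (typically 1-nm) grid.

    Extrapolation outside the measured range is refused.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavelength_nm[0] - 1e-9 or grid[-1] > s.wavelength_nm[-1] + 1e-9:
        raise ValueError(
            f"requested grid [{grid[0]}, {grid[-1]}] extends beyond the "
            f"measured range [{s.wavelength_nm[0]}, {s.wavelength_nm[-1]}]"
        )
    v = np.interp(grid, s.wavelength_nm, s.value)
    return Spectrum(grid, v, kind=s.kind)


def flat_illuminant(lo: float = 300, hi: float = 700) -> Spectrum:
    """Equal-energy illuminant (the default for synthetic work)."""
    return Spectrum.flat(1.0, lo, hi, kind="radiance")


@dataclass(frozen=True)
class WeberFractions:
    """Per-receptor Weber fractions (noise-to-signal ratios)."""

    e: np.ndarray
    receptor_names: tuple[str, ...]

    def __post_init__(self):
        e = np.asarray(self.e, dtype=float)
        if np.any(e <= 0) or np.any(e >= 1):
            raise ValueError("Weber fractions must lie in (0, 1)")
        object.__setattr__(self, "e", e)
        object.__setattr__(self, "receptor_names", tuple(self.receptor_names))


def weber_from_abundances(abundances: dict[str, float],
                          reference: tuple[str, float]) -> WeberFractions:
    """Scale Weber fractions from relative cone abundances.

    ``e_i = e_ref * sqrt(eta_ref / eta_i)`` — channels with more receptors
    pool more signal and are proportionally less noisy.
    """
    ref_name, e_ref = reference
    if ref_name not in abundances:
        raise ValueError(f"reference receptor {ref_name!r} not in abundances")
    eta = np.array([abundances[n] for n in abundances], dtype=float)
    if np.any(eta <= 0):
        raise ValueError("abundances must be positive")
    eta_ref = abundances[ref_name]
    e = e_ref * np.sqrt(eta_ref / eta)
    return WeberFractions(e, tuple(abundances))


@dataclass(frozen=True)
class ReceptorSet:
    """An ordered set of receptor spectral sensitivities.

    Chromatic receptors come first (in ``names``); an optional double cone
    (achromatic channel) is named in ``double_cone``.  Abundances drive the
    Weber-fraction scaling via :func:`weber_from_abundances`.
    """

    names: tuple[str, ...]
    sensitivities: dict[str, Spectrum]
    abundances: dict[str, float]
    weber_reference: tuple[str, float] = ("LWS", 0.05)
    double_cone: str | None = None
    double_cone_weber: float = 0.05

    def __post_init__(self):
        chromatic = [n for n in self.names if n != self.double_cone]
        if len(chromatic) < 2:
            raise ValueError("need at least two chromatic receptors")
        for n in self.names:
            if n not in self.sensitivities:
                raise ValueError(f"missing sensitivity for receptor {n!r}")
        if self.weber_reference[0] not in self.names:
            raise ValueError("Weber reference receptor not present")
        object.__setattr__(self, "names", tuple(self.names))

    @property
    def chromatic_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != self.double_cone)

    def weber_fractions(self) -> WeberFractions:
        ab = {n: self.abundances[n] for n in self.chromatic_names}
        return weber_from_abundances(ab, self.weber_reference)


@dataclass(frozen=True)
class ConeCatch:
    """von Kries-normalized quantum catches, one per receptor."""

    q: np.ndarray
    receptor_names: tuple[str, ...]

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if np.any(q <= 0):
            raise ValueError("cone catches must be positive")
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "receptor_names", tuple(self.receptor_names))

    def __getitem__(self, name: str) -> float:
        return float(self.q[self.receptor_names.index(name)])


def gaussian_receptor(peak_nm: float, sd_nm: float = 40.0,
                      lo: float = 300, hi: float = 700) -> Spectrum:
    """Synthetic idealized pigment template: a Gaussian sensitivity curve.

    A stand-in for measured receptor tables (which can be loaded from CSV);
    adequate for simulation and for exercising the discrimination model.
    """
    grid = np.arange(lo, hi + 1.0)
    v = np.exp(-0.5 * ((grid - peak_nm) / sd_nm) ** 2)
    return Spectrum(grid, v, kind="sensitivity")


def builtin_receptor_set(name: str) -> ReceptorSet:
    """Built-in synthetic receptor sets.

    ``trichrom_skins``
        Visible-band trichromat (SWS/MWS/LWS) used for museum-skin work where
        camera images carry no UV channel.
    ``tetra_uvs``
        Ultraviolet-sensitive tetrachromat (blue-tit-like SWS1 at ~370 nm)
        with a double cone; the default for egg spectra.
    ``tetra_vs``
        Violet-sensitive tetrachromat (peafowl-like SWS1 at ~432 nm),
        the robustness alternative for egg spectra.

    Abundance ratios follow the widely used blue-tit cone proportions
    (UVS 0.37 : SWS 0.70 : MWS 0.99 : LWS 1.00); sensitivities are idealized
    Gaussian templates, replaceable by measured tables via CSV.
    """
    if name == "trichrom_skins":
        return ReceptorSet(
            names=("SWS", "MWS", "LWS", "DBL"),
            sensitivities={
                "SWS": gaussian_receptor(450, 35),
                "MWS": gaussian_receptor(505, 40),
                "LWS": gaussian_receptor(563, 45),
                "DBL": gaussian_receptor(560, 80),
            },
            abundances={"SWS": 0.70, "MWS": 0.99, "LWS": 1.00, "DBL": 1.0},
            weber_reference=("LWS", 0.05),
            double_cone="DBL",
        )
    if name == "tetra_uvs":
        return ReceptorSet(
            names=("UVS", "SWS", "MWS", "LWS", "DBL"),
            sensitivities={
                "UVS": gaussian_receptor(372, 25),
                "SWS": gaussian_receptor(450, 35),
                "MWS": gaussian_receptor(505, 40),
                "LWS": gaussian_receptor(563, 45),
                "DBL": gaussian_receptor(560, 80),
            },
            abundances={"UVS": 0.37, "SWS": 0.70, "MWS": 0.99, "LWS": 1.00,
                        "DBL": 1.0},
            weber_reference=("LWS", 0.05),
            double_cone="DBL",
        )
    if name == "tetra_vs":
        return ReceptorSet(
            names=("VS", "SWS", "MWS", "LWS", "DBL"),
            sensitivities={
                "VS": gaussian_receptor(432, 30),
                "SWS": gaussian_receptor(477, 35),
                "MWS": gaussian_receptor(537, 40),
                "LWS": gaussian_receptor(605, 45),
                "DBL": gaussian_receptor(560, 80),
            },
            abundances={"VS": 0.45, "SWS": 0.70, "MWS": 0.99, "LWS": 1.00,
                        "DBL": 1.0},
            weber_reference=("LWS", 0.05),
            double_cone="DBL",
        )
    raise ValueError(f"unknown receptor set {name!r}")


def cone_catch_from_spectrum(reflectance: Spectrum, illuminant: Spectrum,
                             receptors: ReceptorSet,
                             include_double_cone: bool = True) -> ConeCatch:
    """Integrate a reflectance spectrum into von Kries-normalized catches.

    Raw catch of receptor *i*: ``q_i = ∫ R(λ) I(λ) S_i(λ) dλ`` evaluated by
    trapezoid quadrature on a common 1-nm grid.  von Kries normalization
    divides by the catch of a perfect (R ≡ 1) reflector under the same
    illuminant, modelling chromatic adaptation; a grey reflector therefore
    yields equal catches.
    """
    names = receptors.names if include_double_cone else receptors.chromatic_names
    lo = max(reflectance.wavelength_nm[0], illuminant.wavelength_nm[0],
             *(receptors.sensitivities[n].wavelength_nm[0] for n in names))
    hi = min(reflectance.wavelength_nm[-1], illuminant.wavelength_nm[-1],
             *(receptors.sensitivities[n].wavelength_nm[-1] for n in names))
    if hi <= lo:
        raise ValueError("spectra share no wavelength overlap")
    grid = np.arange(np.ceil(lo), np.floor(hi) + 1.0)
    r = interpolate_spectrum(reflectance, grid).value
    ill = interpolate_spectrum(illuminant, grid).value
    q = np.empty(len(names))
    for i, n in enumerate(names):
        s = interpolate_spectrum(receptors.sensitivities[n], grid).value
        denom = float(np.trapezoid(ill * s, grid))
        if denom <= 0:
            raise ValueError(
                f"receptor {n!r} has no overlap with the illuminant "
                "(degenerate catch)")
        q[i] = float(np.trapezoid(r * ill * s, grid)) / denom
    q = np.maximum(q, CATCH_FLOOR)
    return ConeCatch(q, names)


# ---------------------------------------------------------------------------
# receptor-noise-limited discrimination


def _check_catches(a: ConeCatch, b: ConeCatch):
    if a.receptor_names != b.receptor_names:
        raise ValueError(
            f"receptor mismatch: {a.receptor_names} vs {b.receptor_names}")


def jnd_quadratic_form(w: WeberFractions) -> np.ndarray:
    """Matrix ``Q`` such that ``ΔS² = Δf' Q Δf`` for log-ratio vector Δf.

    Encodes the general n-receptor receptor-noise distance; used to
    vectorize large pairwise JND computations.
    """
    e = w.e
    n = e.size
    idx = list(range(n))
    denom = sum(np.prod(e[list(t)]) ** 2
                for t in itertools.combinations(idx, n - 1))
    Q = np.zeros((n, n))
    for i, j in itertools.combinations(idx, 2):
        others = [k for k in idx if k not in (i, j)]
        wgt = (np.prod(e[others]) ** 2) if others else 1.0
        # (Δf_i − Δf_j)² expands into the quadratic form
        Q[i, i] += wgt
        Q[j, j] += wgt
        Q[i, j] -= wgt
        Q[j, i] -= wgt
    return Q / denom


def chromatic_jnd(a: ConeCatch, b: ConeCatch, w: WeberFractions) -> float:
    """Receptor-noise-limited chromatic distance in JND units.

    Symmetric, non-negative, zero iff all catch ratios agree, and invariant
    to scaling either stimulus by a positive constant (an intensity change
    is not a chromatic difference).
    """
    _check_catches(a, b)
    if len(a.receptor_names) != w.e.size:
        raise ValueError("Weber fractions do not match receptor count")
    df = np.log(a.q) - np.log(b.q)
    # Q annihilates the uniform (pure-intensity) component analytically;
    # centering Δf removes it before rounding error can leak through
    df = df - df.mean()
    Q = jnd_quadratic_form(w)
    return float(np.sqrt(max(df @ Q @ df, 0.0)))


def pairwise_chromatic_jnd(f: np.ndarray, w: WeberFractions) -> np.ndarray:
    """All-pairs JND matrix from log-catch rows ``f`` (n_pixels × n_receptors).

    Uses the Gram-matrix identity ``ΔS²_ij = d_i + d_j − 2 f_i' Q f_j`` so the
    exhaustive O(n²) comparison stays feasible at the 2000-pixel budget.
    """
    Q = jnd_quadratic_form(w)
    fc = f - f.mean(axis=1, keepdims=True)  # drop the intensity component
    fq = fc @ Q
    d = np.einsum("ij,ij->i", fq, fc)
    sq = d[:, None] + d[None, :] - 2.0 * (fq @ fc.T)
    np.maximum(sq, 0.0, out=sq)
    return np.sqrt(sq)


def luminance_jnd(qa: float, qb: float, e_d: float = 0.05) -> float:
    """Achromatic (double-cone) contrast: ``|ln(qa/qb)| / e_D``."""
    if qa <= 0 or qb <= 0:
        raise ValueError("luminance catches must be positive")
    if not 0 < e_d < 1:
        raise ValueError("double-cone Weber fraction must lie in (0, 1)")
    return abs(np.log(qa / qb)) / e_d


# ---------------------------------------------------------------------------
# camera -> cone polynomial mapping


def _poly_terms(n_channels: int, degree: int) -> list[tuple[int, ...]]:
    """Monomial exponent tuples (total degree 0..degree), incl. interactions."""
    terms = []
    for total in range(degree + 1):
        for combo in itertools.combinations_with_replacement(
                range(n_channels), total):
            expo = [0] * n_channels
            for c in combo:
                expo[c] += 1
            terms.append(tuple(expo))
    return terms


def _design(x: np.ndarray, terms: list[tuple[int, ...]]) -> np.ndarray:
    cols = [np.prod([x[:, c] ** p for c, p in enumerate(t)], axis=0)
            if any(t) else np.ones(x.shape[0]) for t in terms]
    return np.column_stack(cols)


@dataclass
class PolynomialMapping:
    """Least-squares polynomial map from camera-channel to cone catches."""

    degree: int
    channel_names: tuple[str, ...]
    receptor_names: tuple[str, ...]
    terms: list[tuple[int, ...]] = field(repr=False)
    coefficients: np.ndarray = field(repr=False)  # n_terms × n_receptors
    fit_r2: np.ndarray = field(default=None, repr=False)


def fit_camera_to_cone(training_camera: np.ndarray,
                       training_cones: np.ndarray,
                       degree: int = 2,
                       channel_names: tuple[str, ...] = ("vR", "vG", "vB"),
                       receptor_names: tuple[str, ...] = ("SWS", "MWS", "LWS"),
                       ) -> PolynomialMapping:
    """Fit per-receptor polynomials (with interactions) in camera catches.

    The standard calibrated-photography route from camera colour space to
    receptor space.  Requires at least 3x more training spectra than
    polynomial terms and a full-rank design.
    """
    X = np.asarray(training_camera, dtype=float)
    Y = np.asarray(training_cones, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("training arrays must be 2-D with matching rows")
    terms = _poly_terms(X.shape[1], degree)
    if X.shape[0] < 3 * len(terms):
        raise ValueError(
            f"need >= {3 * len(terms)} training spectra for {len(terms)} "
            f"terms; got {X.shape[0]}")
    D = _design(X, terms)
    rank = np.linalg.matrix_rank(D)
    if rank < D.shape[1]:
        # name the collinear monomials for the error message
        _, r = np.linalg.qr(D)
        bad = [terms[i] for i in range(D.shape[1])
               if abs(r[i, i]) < 1e-10 * abs(r[0, 0])]
        raise ValueError(f"rank-deficient polynomial design; collinear "
                         f"terms {bad}")
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    resid = Y - D @ coef
    ss_res = np.sum(resid ** 2, axis=0)
    ss_tot = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return PolynomialMapping(degree=degree, channel_names=tuple(channel_names),
                             receptor_names=tuple(receptor_names),
                             terms=terms, coefficients=coef,
                             fit_r2=np.clip(r2, 0.0, 1.0))


def apply_camera_to_cone(mapping: PolynomialMapping,
                         pixels: np.ndarray) -> np.ndarray:
    """Predict per-pixel cone catches from camera-channel pixel values.

    Predictions are floored at :data:`CATCH_FLOOR` so downstream logarithms
    are always defined.
    """
    x = np.atleast_2d(np.asarray(pixels, dtype=float))
    if x.shape[1] != len(mapping.channel_names):
        raise ValueError(
            f"expected {len(mapping.channel_names)} channels, got {x.shape[1]}")
    pred = _design(x, mapping.terms) @ mapping.coefficients
    return np.maximum(pred, CATCH_FLOOR)
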