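"""Image calibration and body-region patch extraction.

Specimen photographs arrive as linear-valued images (RAW decoding and camera
linearization are upstream concerns).  This module normalizes them against an
in-frame grey standard of known reflectance, cuts out labelled body-region
patches, and subsamples each patch down to the pixel budget the exhaustive
colour analysis can afford.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BODY_REGIONS",
    "LinearImage",
    "GreyStandardRegion",
    "PatchImage",
    "normalize_to_standard",
    "extract_patch",
    "downsample_patch",
    "read_linear_image",
    "read_mask",
]

#: The nine plumage regions scored on each specimen.
BODY_REGIONS = ("back", "beak", "belly", "breast", "cheek", "eyebrow",
                "head", "throat", "wing")

#: Default pixel budget for the exhaustive abundant-colour calculation.
PIXEL_BUDGET = 2000


@dataclass(frozen=True)
class LinearImage:
    """A linear-valued multi-channel image (H × W × C)."""

    pixels: np.ndarray
    channel_names: tuple[str, ...] = ("vR", "vG", "vB")
    scale: str = "raw-linear"  # or "reflectance-normalized"

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 2:
            px = px[:, :, None]
        if px.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if px.shape[2] != len(self.channel_names):
            raise ValueError("channel_names must match channel count")
        if np.any(px < 0):
            raise ValueError("linear pixel values must be non-negative")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class GreyStandardRegion:
    """Mask of the in-frame grey standard and its known reflectance."""

    mask: np.ndarray
    reflectance: float = 0.40

    def __post_init__(self):
        mask = np.asarray(self.mask, dtype=bool)
        if not mask.any():
            raise ValueError("grey-standard mask is empty")
        if not 0 < self.reflectance <= 1:
            raise ValueError("standard reflectance must lie in (0, 1]")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class PatchImage:
    """Masked pixels of one body region of one specimen.

    ``pixels`` holds only the masked pixels (n_pixels × C); ``mask`` retains
    their location in the source image so spatial (pattern) analyses can
    re-embed them in the bounding box.
    """

    region: str
    pixels: np.ndarray
    mask: np.ndarray
    channel_names: tuple[str, ...] = ("vR", "vG", "vB")

    def __post_init__(self):
        if self.region not in BODY_REGIONS:
            raise ValueError(
                f"unknown region {self.region!r}; expected one of "
                f"{BODY_REGIONS}")
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim == 1:
            px = px[:, None]
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]


def normalize_to_standard(img: LinearImage,
                          std: GreyStandardRegion) -> LinearImage:
    """Scale each channel so the grey standard reads its known reflectance.

    A pixel value ``v`` becomes ``v * std.reflectance / mean(channel over the
    standard region)``, the equalize-to-grey convention of calibrated
    photography.  Idempotent, and invariant to any global gain applied
    upstream.
    """
    if std.mask.shape != img.shape:
        raise ValueError("standard mask does not match image shape")
    means = img.pixels[std.mask].mean(axis=0)
    if np.any(means <= 0):
        bad = [n for n, m in zip(img.channel_names, means) if m <= 0]
        raise ValueError(
            f"grey standard region has non-positive mean in channels {bad}; "
            "cannot calibrate")
    out = img.pixels * (std.reflectance / means)
    return LinearImage(out, img.channel_names, scale="reflectance-normalized")


def extract_patch(img: LinearImage, mask: np.ndarray,
                  region: str) -> PatchImage:
    """Cut the masked pixels of one body region out of a calibrated image."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("patch mask does not match image shape")
    if not mask.any():
        raise ValueError(f"empty mask for region {region!r}")
    return PatchImage(region=region, pixels=img.pixels[mask], mask=mask,
                      channel_names=img.channel_names)


def downsample_patch(patch: PatchImage, budget: int = PIXEL_BUDGET,
                     seed: int | None = 0) -> PatchImage:
    """Subsample a patch to at most ``budget`` pixels.

    Seeded uniform sampling without replacement preserves the pixel colour
    multiset's distribution, which is what the abundant-colour and histogram
    statistics consume; patches already within budget pass through unchanged.
    """
    if budget < 1:
        raise ValueError("pixel budget must be >= 1")
    if patch.n_pixels <= budget:
        return patch
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(patch.n_pixels, size=budget, replace=False))
    coords = np.argwhere(patch.mask)[keep]
    new_mask = np.zeros_like(patch.mask)
    new_mask[coords[:, 0], coords[:, 1]] = True
    return replace(patch, pixels=patch.pixels[keep], mask=new_mask)


def read_linear_image(path, channel_names=("vR", "vG", "vB")) -> LinearImage:
    """Read a linear-valued TIFF or PNG into a :class:`LinearImage`.

    16-bit integer images are rescaled to [0, 1]; float images are taken
    as-is.
    """
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    return LinearImage(arr.astype(float), channel_names)


def read_mask(path) -> np.ndarray:
    """Read an 8-bit PNG mask (0/255) as a boolean grid."""
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
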