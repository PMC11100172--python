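"""sRGB → CIEXYZ → CIEL*a*b* conversion and distributional colour descriptors.

Flesh colour is non-homogeneous, so a single colour reading cannot summarise a
fruit section.  Instead every masked pixel is converted to CIEL*a*b* (D65,
2° observer) and the *distribution* is summarised by its mean and standard
deviation per channel, with hue angle and chroma derived from the mean
chromatic coordinates (a*, b*).

The conversion follows the CIE 1976 pipeline: inverse sRGB companding, the
sRGB/D65 linear transform to XYZ, then the cube-root L*a*b* functions.  The
reference white is taken as the exact image of sRGB (1, 1, 1) under the
matrix, so neutral grays map to a* = b* = 0 identically.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SRGB_TO_XYZ",
    "D65_WHITE",
    "srgb_to_lab",
    "lab_to_srgb",
    "hue_chroma",
    "ColourDescriptors",
    "compute_descriptors",
    "aggregate_genotype",
]

#: Linear-RGB → XYZ matrix for sRGB primaries under illuminant D65 (2° observer).
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: Reference white: exact image of RGB (1,1,1), keeping the neutral axis exact.
D65_WHITE = SRGB_TO_XYZ.sum(axis=1)

_EPS = (6.0 / 29.0) ** 3
_KAPPA_DEN = 3.0 * (6.0 / 29.0) ** 2


def _inverse_compand(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def _compand(c: np.ndarray) -> np.ndarray:
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * np.clip(c, 0, None) ** (1 / 2.4) - 0.055)


def srgb_to_lab(pixels: np.ndarray) -> np.ndarray:
    """Convert 8-bit sRGB values to CIEL*a*b* (D65).

    Parameters
    ----------
    pixels
        Array of shape ``(..., 3)`` with channel values in [0, 255].

    Returns
    -------
    ndarray of the same shape: L* in [0, 100] for in-gamut inputs, a*/b* signed.
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.shape[-1] != 3:
        raise ValueError("expected trailing axis of size 3 (R, G, B)")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("sRGB channel values must lie in [0, 255]")
    rgb_lin = _inverse_compand(arr / 255.0)
    xyz = rgb_lin @ SRGB_TO_XYZ.T
    r = xyz / D65_WHITE
    f = np.where(r > _EPS, np.cbrt(r), r / _KAPPA_DEN + 4.0 / 29.0)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_to_srgb(lab: np.ndarray, *, clip: bool = True) -> np.ndarray:
    """Inverse conversion, CIEL*a*b* → 8-bit sRGB floats in [0, 255].

    With ``clip=False`` out-of-gamut values are returned unclipped so callers
    can detect them; with the default they are clipped to the sRGB cube.
    """
    arr = np.asarray(lab, dtype=float)
    fy = (arr[..., 0] + 16.0) / 116.0
    fx = fy + arr[..., 1] / 500.0
    fz = fy - arr[..., 2] / 200.0
    f = np.stack([fx, fy, fz], axis=-1)
    r = np.where(f > 6.0 / 29.0, f**3, (f - 4.0 / 29.0) * _KAPPA_DEN)
    xyz = r * D65_WHITE
    rgb_lin = xyz @ np.linalg.inv(SRGB_TO_XYZ).T
    rgb = _compand(rgb_lin) * 255.0
    if clip:
        rgb = np.clip(rgb, 0.0, 255.0)
    return rgb


def hue_chroma(
    a_mean: float, b_mean: float, *, formula: str = "standard"
) -> tuple[float, float]:
    """Hue angle (degrees) and chroma from mean chromatic coordinates.

    ``formula="standard"`` is the CIELCh angle atan2(b*, a*) mapped to
    [0, 360): red ≈ 0°, yellow ≈ 90°.  ``formula="paper"`` evaluates the
    ratio form arctan(a*/b*) instead.  Chroma is √(a*² + b*²) either way.
    Hue is undefined at the neutral point and returned as NaN with chroma 0.
    """
    chroma = math.hypot(a_mean, b_mean)
    if chroma == 0.0:
        return float("nan"), 0.0
    if formula == "standard":
        hue = math.degrees(math.atan2(b_mean, a_mean)) % 360.0
        if hue >= 360.0:  # guard: tiny negative angles round up to 360 exactly
            hue = 0.0
    elif formula == "paper":
        if b_mean == 0.0:
            return float("nan"), chroma
        hue = math.degrees(math.atan(a_mean / b_mean))
    else:
        raise ValueError(f"unknown hue formula: {formula!r}")
    return hue, chroma


@dataclass
class ColourDescriptors:
    """Per-fruit (or per-genotype aggregate) distributional colour summary."""

    genotype_id: str
    fruit_id: str
    year: int
    R_mean: float
    G_mean: float
    B_mean: float
    R_sd: float
    G_sd: float
    B_sd: float
    L_mean: float
    a_mean: float
    b_mean: float
    L_sd: float
    a_sd: float
    b_sd: float
    hue_deg: float
    chroma: float
    colour_index: float | None = None

    _NUMERIC = (
        "R_mean", "G_mean", "B_mean", "R_sd", "G_sd", "B_sd",
        "L_mean", "a_mean", "b_mean", "L_sd", "a_sd", "b_sd",
    )

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class InsufficientPixelsError(ValueError):
    pass


def compute_descriptors(
    section,
    *,
    genotype_id: str = "",
    fruit_id: str = "",
    year: int = 0,
    colour_index: float | None = None,
    hue_formula: str = "standard",
    min_pixels: int = 100,
) -> ColourDescriptors:
    """Means and population SDs of R, G, B, L*, a*, b* over a section's mask.

    Only pixels under the foreground mask contribute; background never leaks
    into the descriptors.  Hue and chroma are computed from the *mean*
    (a*, b*), i.e. from the section's average chromatic position, not as a
    per-pixel average.
    """
    mask = np.asarray(section.mask, dtype=bool)
    n = int(mask.sum())
    if n < min_pixels:
        raise InsufficientPixelsError(
            f"section mask has {n} pixels; at least {min_pixels} required"
        )
    rgb = np.asarray(section.pixels, dtype=float)[mask]
    lab = srgb_to_lab(rgb)
    r_m, g_m, b_m = rgb.mean(axis=0)
    r_s, g_s, b_s = rgb.std(axis=0)  # population SD
    L_m, a_m, bb_m = lab.mean(axis=0)
    L_s, a_s, bb_s = lab.std(axis=0)
    hue, chroma = hue_chroma(a_m, bb_m, formula=hue_formula)
    return ColourDescriptors(
        genotype_id=genotype_id,
        fruit_id=fruit_id,
        year=year,
        R_mean=r_m, G_mean=g_m, B_mean=b_m,
        R_sd=r_s, G_sd=g_s, B_sd=b_s,
        L_mean=L_m, a_mean=a_m, b_mean=bb_m,
        L_sd=L_s, a_sd=a_s, b_sd=bb_s,
        hue_deg=hue, chroma=chroma,
        colour_index=colour_index,
    )


def aggregate_genotype(
    descriptors: Sequence[ColourDescriptors], *, hue_formula: str = "standard"
) -> ColourDescriptors:
    """Average per-fruit descriptors (typically four fruits) into one record.

    Every numeric field is averaged arithmetically; hue and chroma are then
    recomputed from the aggregated (a*, b*) so the angular coordinates stay
    consistent with the averaged chromatic position.
    """
    if not descriptors:
        raise ValueError("no descriptors to aggregate")
    gids = {d.genotype_id for d in descriptors}
    years = {d.year for d in descriptors}
    if len(gids) != 1 or len(years) != 1:
        raise ValueError(f"descriptors mix genotypes/years: {gids} / {years}")
    means = {
        name: float(np.mean([getattr(d, name) for d in descriptors]))
        for name in ColourDescriptors._NUMERIC
    }
    hue, chroma = hue_chroma(means["a_mean"], means["b_mean"], formula=hue_formula)
    idx = [d.colour_index for d in descriptors if d.colour_index is not None]
    return ColourDescriptors(
        genotype_id=gids.pop(),
        fruit_id="mean",
        year=years.pop(),
        **means,
        hue_deg=hue,
        chroma=chroma,
        colour_index=float(np.mean(idx)) if idx else None,
    )


def descriptors_to_frame(records: Iterable[ColourDescriptors]):
    """Stack descriptor records into a pandas DataFrame with fixed columns."""
    import pandas as pd

    return pd.DataFrame([d.as_dict() for d in records])
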