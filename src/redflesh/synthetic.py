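"""Synthetic scans and genotype panels with exact ground truth.

Two generators make the whole pipeline testable without any real data:

* :func:`generate_scan` renders a scanner-like PNG — up to four fruit-section
  disks on a white field — where a chosen fraction of each disk is replaced by
  blobs of a second colour.  Because each section is an exact two-colour
  mixture of *quantised* sRGB colours, the expected per-channel mean and
  population SD of its Lab distribution are known in closed form.

* :func:`generate_panel` draws a genotype panel with known biochemistry→colour
  structure: a latent pigmentation score g per genotype drives log-normal
  anthocyanins upward, flavanols downward (the flavonoid-pathway competition
  seen in red-flesh material) and flavonols weakly upward; pH, water content
  and the remaining classes are independent draws inside realistic ranges.
  The colour response is a linear model on analytically standardised
  predictors plus Gaussian noise, so correlations and variable-importance
  orderings are recoverable quantities, not assumptions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import hue_chroma, lab_to_srgb, srgb_to_lab
from .sections import ScanImage

__all__ = [
    "GamutError",
    "SectionTruth",
    "ScanTruth",
    "PanelTruth",
    "generate_scan",
    "generate_panel",
    "PANEL_PARAMS",
    "predictor_moments",
    "DEFAULT_BETA_A",
    "DEFAULT_BETA_B",
]


class GamutError(ValueError):
    """A requested Lab colour has no sRGB representation."""


# --------------------------------------------------------------------------
# scans


@dataclass
class SectionTruth:
    """Exact mixture ground truth for one rendered section."""

    center: tuple[int, int]
    radius: int
    base_lab: tuple[float, float, float]   # Lab of the quantised base colour
    blob_lab: tuple[float, float, float]
    blob_fraction: float                   # achieved, from the pixel counts
    expected_mean: tuple[float, float, float]
    expected_sd: tuple[float, float, float]
    area_px: int


@dataclass
class ScanTruth:
    seed: int
    sections: list[SectionTruth] = field(default_factory=list)


def _lab_to_quantised_srgb(lab) -> np.ndarray:
    rgb = lab_to_srgb(np.asarray(lab, float), clip=False)
    if rgb.min() < -0.5 or rgb.max() > 255.5:
        raise GamutError(f"Lab colour {tuple(lab)} is outside the sRGB gamut: {rgb}")
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def generate_scan(
    n_sections: int = 4,
    *,
    base_lab=(45.0, 45.0, 25.0),
    heterogeneity: float = 0.0,
    blob_lab=(60.0, 30.0, 22.0),
    radius_px: int = 150,
    seed: int = 0,
    margin: int = 40,
) -> tuple[ScanImage, ScanTruth]:
    """Render a white-background scan of 1–4 two-colour fruit-section disks.

    ``heterogeneity`` is the target fraction of each disk covered by blobs of
    ``blob_lab``; the achieved fraction (exact, from pixel counts) is
    recorded in the truth together with the closed-form mixture moments
    mean = (1−f)·base + f·blob and sd = |base−blob|·√(f(1−f)) per channel.
    """
    if not 1 <= n_sections <= 4:
        raise ValueError("n_sections must be in 1..4")
    if not 0.0 <= heterogeneity <= 1.0:
        raise ValueError("heterogeneity must be in [0, 1]")
    base_rgb = _lab_to_quantised_srgb(base_lab)
    blob_rgb = _lab_to_quantised_srgb(blob_lab)
    base_q = srgb_to_lab(base_rgb.astype(float))
    blob_q = srgb_to_lab(blob_rgb.astype(float))

    rng = np.random.default_rng(seed)
    cell = 2 * radius_px + 2 * margin
    ncols = 2 if n_sections > 1 else 1
    nrows = 1 if n_sections <= 2 else 2
    H, W = nrows * cell, ncols * cell
    img = np.full((H, W, 3), 255, dtype=np.uint8)
    truth = ScanTruth(seed=seed)

    yy, xx = np.mgrid[0:H, 0:W]
    for k in range(n_sections):
        r_cell, c_cell = divmod(k, ncols)
        cy = r_cell * cell + cell // 2
        cx = c_cell * cell + cell // 2
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
        area = int(disk.sum())
        img[disk] = base_rgb
        blob_mask = np.zeros((H, W), dtype=bool)
        target = heterogeneity * area
        guard = 0
        while blob_mask.sum() < target and guard < 10_000:
            guard += 1
            ang = rng.uniform(0, 2 * math.pi)
            rad = radius_px * math.sqrt(rng.uniform())
            by, bx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
            br = rng.uniform(0.06, 0.16) * radius_px
            blob = (yy - by) ** 2 + (xx - bx) ** 2 <= br**2
            blob_mask |= blob & disk
        img[blob_mask] = blob_rgb
        f = blob_mask.sum() / area
        mean = (1 - f) * base_q + f * blob_q
        sd = np.abs(base_q - blob_q) * math.sqrt(f * (1 - f))
        truth.sections.append(
            SectionTruth(
                center=(cy, cx),
                radius=radius_px,
                base_lab=tuple(base_q),
                blob_lab=tuple(blob_q),
                blob_fraction=float(f),
                expected_mean=tuple(mean),
                expected_sd=tuple(sd),
                area_px=area,
            )
        )
    scan = ScanImage(pixels=img, source_id=f"synth{seed}")
    return scan, truth


# --------------------------------------------------------------------------
# panels

#: Generative parameters of the biochemical panel.  Log-scale location/spread
#: of the log-normal classes (µg/g FW), the latent-score couplings, and the
#: Gaussian factors.  Ranges emulate a segregating red-flesh F1 family:
#: anthocyanins spanning ~2–300 µg/g, flavanol totals up to ~700, pH around
#: 2.9–3.8 and water content near 0.77–0.91.
PANEL_PARAMS = {
    "log_anthocyanins": {"mu": 3.3, "s_g": 1.0, "s_e": 0.3},
    "flavanols": {"mu": 5.0, "s_g": -0.6, "s_e": 0.3},
    "flavonols": {"mu": 1.3, "s_g": 0.15, "s_e": 0.35},
    "hydroxycinnamic_acids": {"mu": 5.0, "s_g": 0.0, "s_e": 0.6},
    "dihydrochalcones": {"mu": 1.8, "s_g": 0.0, "s_e": 0.7},
    "pH": {"mean": 3.18, "sd": 0.15},
    "water_content": {"mean": 0.815, "sd": 0.025},
}

#: Default colour-model coefficients (on analytically standardised
#: predictors).  a*: anthocyanins dominate positively, flavanols oppose,
#: flavonols help weakly, pH contributes — the structure reported for
#: red-flesh pigmentation.  b*: lower with anthocyanins, raised by flavanols
#: and pH.
DEFAULT_BETA_A = {
    "log_anthocyanins": 0.9,
    "flavanols": -0.35,
    "flavonols": 0.20,
    "hydroxycinnamic_acids": 0.0,
    "dihydrochalcones": 0.0,
    "pH": 0.15,
    "water_content": 0.0,
}
DEFAULT_BETA_B = {
    "log_anthocyanins": -0.5,
    "flavanols": 0.30,
    "flavonols": 0.0,
    "hydroxycinnamic_acids": 0.0,
    "dihydrochalcones": 0.0,
    "pH": 0.30,
    "water_content": 0.0,
}

#: Affine map from the standardised response to descriptor units.
A_STAR_LOC, A_STAR_SCALE = 12.0, 8.0
B_STAR_LOC, B_STAR_SCALE = 14.0, 3.0


def predictor_moments() -> tuple[dict[str, float], dict[str, float]]:
    """Closed-form mean and SD of every predictor under PANEL_PARAMS.

    Log-normal classes use exp(µ + v/2) and (e^v − 1)e^(2µ+v) with
    v = s_g² + s_e²; the Gaussian factors are their own parameters;
    log-anthocyanins stays on the log scale (it is the model predictor).
    """
    means, sds = {}, {}
    for name, par in PANEL_PARAMS.items():
        if "mu" in par:
            v = par["s_g"] ** 2 + par["s_e"] ** 2
            if name == "log_anthocyanins":
                means[name] = par["mu"]
                sds[name] = math.sqrt(v)
            else:
                means[name] = math.exp(par["mu"] + v / 2)
                sds[name] = math.sqrt((math.exp(v) - 1) * math.exp(2 * par["mu"] + v))
        else:
            means[name], sds[name] = par["mean"], par["sd"]
    return means, sds


@dataclass
class PanelTruth:
    seed: int
    beta_a: dict
    beta_b: dict
    noise_sd: float
    g: np.ndarray
    y_a_std: np.ndarray
    y_b_std: np.ndarray
    predictor_means: dict
    predictor_sds: dict
    anthocyanin_saturation: float | None = None


def generate_panel(
    n_genotypes: int = 91,
    *,
    coefficients: dict | None = None,
    coefficients_b: dict | None = None,
    noise_sd: float = 0.55,
    anthocyanin_saturation: float | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PanelTruth]:
    """Draw a genotype panel with known biochemistry→colour structure.

    Returns a biochemical-profile table, a genotype-level colour-descriptor
    table, and the generative truth (β, latent scores, noise).  The colour
    responses are a* = 12 + 8·(βᵀz + ε) and b* = 14 + 3·(β_bᵀz + ε′) with z
    the predictors standardised by their *analytic* moments, so population
    correlations follow in closed form from β and ``noise_sd``.
    """
    if n_genotypes < 10:
        raise ValueError("n_genotypes must be >= 10")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    beta_a = dict(DEFAULT_BETA_A if coefficients is None else coefficients)
    beta_b = dict(DEFAULT_BETA_B if coefficients_b is None else coefficients_b)

    rng = np.random.default_rng(seed)
    n = n_genotypes
    g = rng.standard_normal(n)
    cols = {}
    for name, par in PANEL_PARAMS.items():
        if "mu" in par:
            lin = par["mu"] + par["s_g"] * g + par["s_e"] * rng.standard_normal(n)
            cols[name] = lin if name == "log_anthocyanins" else np.exp(lin)
        else:
            cols[name] = par["mean"] + par["sd"] * rng.standard_normal(n)
    anth = np.exp(cols.pop("log_anthocyanins"))
    if anthocyanin_saturation is not None:
        sat = float(anthocyanin_saturation)
        anth = sat * (1.0 - np.exp(-anth / sat))
    means, sds = predictor_moments()
    z = {
        name: (np.log(anth) - means["log_anthocyanins"]) / sds["log_anthocyanins"]
        if name == "log_anthocyanins"
        else (cols[name] - means[name]) / sds[name]
        for name in PANEL_PARAMS
    }
    y_a = sum(beta_a[k] * z[k] for k in PANEL_PARAMS) + noise_sd * rng.standard_normal(n)
    y_b = sum(beta_b[k] * z[k] for k in PANEL_PARAMS) + noise_sd * rng.standard_normal(n)

    gids = [f"G{k:03d}" for k in range(1, n + 1)]
    index = np.clip(np.round(1.1 * y_a + 2.2), 0, 5)
    profiles = pd.DataFrame(
        {
            "genotype_id": gids,
            "anthocyanins": anth,
            "flavanols": cols["flavanols"],
            "flavonols": cols["flavonols"],
            "hydroxycinnamic_acids": cols["hydroxycinnamic_acids"],
            "dihydrochalcones": cols["dihydrochalcones"],
            "pH": cols["pH"],
            "water_content": cols["water_content"],
            "colour_index": index,
        }
    )

    a_star = A_STAR_LOC + A_STAR_SCALE * y_a
    b_star = B_STAR_LOC + B_STAR_SCALE * y_b
    L_star = np.clip(72.0 - 5.0 * y_a, 20.0, 97.0)
    hue = np.empty(n)
    chroma = np.empty(n)
    for i in range(n):
        hue[i], chroma[i] = hue_chroma(a_star[i], b_star[i])
    mean_rgb = lab_to_srgb(np.stack([L_star, a_star, b_star], axis=-1), clip=True)
    desc = pd.DataFrame(
        {
            "genotype_id": gids,
            "fruit_id": "mean",
            "year": 2022,
            "R_mean": mean_rgb[:, 0],
            "G_mean": mean_rgb[:, 1],
            "B_mean": mean_rgb[:, 2],
            "R_sd": np.abs(8.0 + 3.0 * y_a) + 1.0,
            "G_sd": np.abs(9.0 + 3.5 * y_a) + 1.0,
            "B_sd": np.abs(7.0 + 2.5 * y_a) + 1.0,
            "L_mean": L_star,
            "a_mean": a_star,
            "b_mean": b_star,
            "L_sd": np.abs(4.0 + 1.5 * y_a) + 0.5,
            "a_sd": np.abs(5.0 + 2.0 * y_a) + 0.5,
            "b_sd": np.abs(2.0 + 0.5 * y_b) + 0.5,
            "hue_deg": hue,
            "chroma": chroma,
            "colour_index": index,
        }
    )
    truth = PanelTruth(
        seed=seed,
        beta_a=beta_a,
        beta_b=beta_b,
        noise_sd=noise_sd,
        g=g,
        y_a_std=y_a,
        y_b_std=y_b,
        predictor_means=means,
        predictor_sds=sds,
        anthocyanin_saturation=anthocyanin_saturation,
    )
    return profiles, desc, truth
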