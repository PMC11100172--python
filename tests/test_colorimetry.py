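"""Colour conversion and distributional descriptors."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.color import rgb2lab

from redflesh.colorimetry import (
    ColourDescriptors,
    InsufficientPixelsError,
    aggregate_genotype,
    compute_descriptors,
    hue_chroma,
    lab_to_srgb,
    srgb_to_lab,
)

# Frozen hand evaluations of the CIE pipeline (inverse companding, sRGB/D65
# matrix, cube-root Lab), computed independently with scalar arithmetic.
HAND_ORACLE = {
    (255, 0, 0): (53.240792, 80.092470, 67.203193),
    (0, 255, 0): (87.734719, -86.182702, 83.179315),
    (0, 0, 255): (32.297009, 79.187527, -107.860165),
    (128, 64, 32): (34.724814, 25.000040, 31.372060),
    (200, 30, 60): (43.563216, 64.057345, 28.471145),
}


class TestSrgbToLab:
    def test_white_black_and_neutral_axis(self):
        assert srgb_to_lab(np.array([255.0, 255.0, 255.0])) == pytest.approx(
            (100.0, 0.0, 0.0), abs=1e-6
        )
        assert srgb_to_lab(np.array([0.0, 0.0, 0.0])) == pytest.approx(
            (0.0, 0.0, 0.0), abs=1e-6
        )
        grays = np.stack([np.arange(256.0)] * 3, axis=-1)
        lab = srgb_to_lab(grays)
        assert np.abs(lab[:, 1:]).max() < 1e-6

    @pytest.mark.parametrize("rgb,expected", sorted(HAND_ORACLE.items()))
    def test_matches_hand_evaluated_formulas(self, rgb, expected):
        assert srgb_to_lab(np.array(rgb, float)) == pytest.approx(expected, abs=1e-4)

    def test_cross_check_against_skimage(self, rng):
        """Independent library conversion agrees closely (different matrix
        precision accounts for the small slack)."""
        pix = rng.integers(0, 256, size=(50, 3)).astype(np.uint8)
        ours = srgb_to_lab(pix.astype(float))
        ref = rgb2lab(pix[None, :, :] / 255.0)[0]
        assert np.abs(ours - ref).max() < 0.05

    def test_round_trip(self, rng):
        pix = rng.integers(0, 256, size=(200, 3)).astype(float)
        lab = srgb_to_lab(pix)
        back = srgb_to_lab(lab_to_srgb(lab))
        assert np.abs(back - lab).max() < 0.01

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            srgb_to_lab(np.array([256.0, 0.0, 0.0]))
        with pytest.raises(ValueError):
            srgb_to_lab(np.array([-1.0, 0.0, 0.0]))

    def test_increasing_red_never_decreases_a_star(self):
        reds = np.stack(
            [np.arange(256.0), np.full(256, 90.0), np.full(256, 90.0)], axis=-1
        )
        a = srgb_to_lab(reds)[:, 1]
        assert np.all(np.diff(a) >= -1e-9)


class TestHueChroma:
    def test_three_four_five_triangle(self):
        hue, chroma = hue_chroma(3.0, 4.0)
        assert chroma == pytest.approx(5.0)

    def test_pure_red_direction_is_zero_degrees(self):
        hue, chroma = hue_chroma(50.0, 0.0)
        assert hue == pytest.approx(0.0)
        assert chroma == pytest.approx(50.0)

    def test_diagonal(self):
        hue, chroma = hue_chroma(30.0, 30.0)
        assert hue == pytest.approx(45.0)
        assert chroma == pytest.approx(30.0 * np.sqrt(2.0))

    def test_neutral_point_hue_undefined(self):
        hue, chroma = hue_chroma(0.0, 0.0)
        assert np.isnan(hue) and chroma == 0.0

    def test_paper_ratio_formula(self):
        hue, _ = hue_chroma(30.0, 30.0, formula="paper")
        assert hue == pytest.approx(45.0)
        hue, _ = hue_chroma(10.0, 40.0, formula="paper")
        assert hue == pytest.approx(np.degrees(np.arctan(0.25)))

    @given(
        a=st.floats(-100, 100, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_quadrant_and_radius_consistency(self, a, b):
        hue, chroma = hue_chroma(a, b)
        assert chroma == pytest.approx(np.hypot(a, b))
        if chroma > 1e-9:
            assert 0.0 <= hue < 360.0
            assert a == pytest.approx(chroma * np.cos(np.radians(hue)), abs=1e-6)
            assert b == pytest.approx(chroma * np.sin(np.radians(hue)), abs=1e-6)


class _Section:
    def __init__(self, pixels, mask):
        self.pixels, self.mask = pixels, mask


def _uniform_section(colour, n=20):
    pixels = np.tile(np.array(colour, np.uint8), (n, n, 1))
    return _Section(pixels, np.ones((n, n), bool))


class TestDescriptors:
    def test_uniform_section_has_zero_sd(self):
        colour = (180, 70, 60)
        d = compute_descriptors(_uniform_section(colour))
        assert (d.R_sd, d.G_sd, d.B_sd, d.L_sd, d.a_sd, d.b_sd) == pytest.approx(
            (0,) * 6, abs=1e-9
        )
        assert (d.R_mean, d.G_mean, d.B_mean) == pytest.approx(colour)
        lab = srgb_to_lab(np.array(colour, float))
        assert (d.L_mean, d.a_mean, d.b_mean) == pytest.approx(tuple(lab))

    def test_two_point_mixture_closed_form(self):
        ca, cb = np.array([200, 40, 40]), np.array([100, 140, 60])
        pixels = np.zeros((10, 20, 3), np.uint8)
        pixels[:, :10] = ca
        pixels[:, 10:] = cb
        d = compute_descriptors(_Section(pixels, np.ones((10, 20), bool)))
        la, lb = srgb_to_lab(ca.astype(float)), srgb_to_lab(cb.astype(float))
        assert (d.R_mean, d.G_mean, d.B_mean) == pytest.approx(tuple((ca + cb) / 2))
        assert (d.R_sd, d.G_sd, d.B_sd) == pytest.approx(tuple(np.abs(ca - cb) / 2))
        assert (d.L_mean, d.a_mean, d.b_mean) == pytest.approx(tuple((la + lb) / 2))
        assert (d.L_sd, d.a_sd, d.b_sd) == pytest.approx(tuple(np.abs(la - lb) / 2))

    def test_mask_invariance(self):
        colour = (150, 60, 50)
        sec = _uniform_section(colour, n=30)
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        d1 = compute_descriptors(_Section(sec.pixels, mask))
        noisy = sec.pixels.copy()
        noisy[~mask] = (255, 255, 0)
        d2 = compute_descriptors(_Section(noisy, mask))
        assert d1.as_dict() == d2.as_dict()

    def test_too_few_pixels_rejected(self):
        with pytest.raises(InsufficientPixelsError):
            compute_descriptors(_uniform_section((10, 10, 10), n=5))


def _desc(gid="G1", a=10.0, b=20.0, **kw):
    base = dict(
        genotype_id=gid, fruit_id="1", year=2022,
        R_mean=100, G_mean=50, B_mean=40, R_sd=5, G_sd=4, B_sd=3,
        L_mean=50, a_mean=a, b_mean=b, L_sd=2, a_sd=2, b_sd=1,
        hue_deg=hue_chroma(a, b)[0], chroma=hue_chroma(a, b)[1],
    )
    base.update(kw)
    return ColourDescriptors(**base)


class TestAggregate:
    def test_identical_records_idempotent(self):
        d = _desc()
        agg = aggregate_genotype([d] * 4)
        for name in ColourDescriptors._NUMERIC:
            assert getattr(agg, name) == pytest.approx(getattr(d, name))

    def test_fieldwise_mean(self):
        agg = aggregate_genotype([_desc(a=10.0), _desc(a=30.0)])
        assert agg.a_mean == pytest.approx(20.0)

    def test_hue_recomputed_from_aggregated_ab(self):
        agg = aggregate_genotype([_desc(a=30.0, b=0.0), _desc(a=0.0, b=30.0)])
        assert agg.hue_deg == pytest.approx(45.0)
        assert agg.chroma == pytest.approx(15.0 * np.sqrt(2.0))
        # recompute-from-mean, not the mean of per-fruit hues (0° and 90°)
        assert agg.chroma != pytest.approx(30.0)

    def test_mixed_genotypes_rejected(self):
        with pytest.raises(ValueError):
            aggregate_genotype([_desc(gid="G1"), _desc(gid="G2")])
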