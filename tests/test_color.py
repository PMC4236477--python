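"""Color-index math: exact examples, independent oracles, invariants."""

import colorsys
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import color as skcolor

from ricecanopyn.color import (
    D65,
    DEFAULT_CONFIG,
    ChannelMeans,
    ColorConfig,
    ConfigurationError,
    DegenerateColorWarning,
    GamutWarning,
    TristimulusXYZ,
    compute_index_set,
    compute_index_set_per_pixel,
    hue_degrees,
    intensity,
    lab_to_rgb,
    lab_to_xyz,
    normalize_rgb,
    rgb_to_hue,
    rgb_to_xyz,
    vi_green,
    xyz_to_lab,
)

triplets = st.tuples(
    st.integers(0, 255), st.integers(0, 255), st.integers(0, 255)
)


@pytest.mark.parametrize(
    "rgb, expected",
    [
        ((100, 150, 50), (1 / 3, 1 / 2, 1 / 6)),
        ((85, 85, 85), (1 / 3, 1 / 3, 1 / 3)),
        ((0, 255, 0), (0.0, 1.0, 0.0)),
    ],
)
def test_normalized_rgb_exact(rgb, expected):
    assert normalize_rgb(ChannelMeans(*rgb)) == pytest.approx(expected, abs=1e-12)


def test_normalized_rgb_black_is_neutral_with_warning():
    with pytest.warns(DegenerateColorWarning):
        r, g, b = normalize_rgb(ChannelMeans(0, 0, 0))
    assert (r, g, b) == pytest.approx((1 / 3,) * 3)


@pytest.mark.parametrize(
    "rgb, expected",
    [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((30, 60, 90), 60.0)],
)
def test_intensity_exact(rgb, expected):
    assert intensity(ChannelMeans(*rgb)) == expected


@pytest.mark.parametrize(
    "rgb, expected",
    [((120, 120, 33), 0.0), ((0, 200, 17), 1.0), ((100, 150, 80), 0.2)],
)
def test_vi_green_exact(rgb, expected):
    assert vi_green(ChannelMeans(*rgb)) == pytest.approx(expected, abs=1e-12)


def test_vi_green_degenerate_denominator():
    with pytest.warns(DegenerateColorWarning):
        assert vi_green(ChannelMeans(0, 0, 200)) == 0.0


@pytest.mark.parametrize(
    "rgb, expected",
    [((255, 0, 0), 0.0), ((0, 255, 0), 120.0), ((0, 0, 255), 240.0)],
)
def test_hue_primaries(rgb, expected):
    assert rgb_to_hue(ChannelMeans(*rgb)) == pytest.approx(expected)


def test_hue_zero_chroma_flagged():
    with pytest.warns(DegenerateColorWarning):
        assert rgb_to_hue(ChannelMeans(80, 80, 80)) == 0.0


def test_hue_matches_colorsys_oracle(rng):
    """Hexcone hue agrees with the standard library's HSV conversion."""
    for _ in range(300):
        R, G, B = (int(v) for v in rng.integers(0, 256, size=3))
        if R == G == B:
            continue
        expected = colorsys.rgb_to_hsv(R / 255, G / 255, B / 255)[0] * 360.0 % 360.0
        assert float(hue_degrees(R, G, B)) == pytest.approx(expected, abs=1e-9)


@given(rgb=triplets, scale=st.floats(0.05, 1.0))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_hue_invariant_under_positive_scaling(rgb, scale):
    R, G, B = rgb
    if R == G == B:
        return
    h1 = float(hue_degrees(R, G, B))
    h2 = float(hue_degrees(R * scale, G * scale, B * scale))
    assert h1 == pytest.approx(h2, abs=1e-8)


@given(rgb=triplets)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_chromatic_coordinates_sum_to_one(rgb):
    means = ChannelMeans(*rgb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateColorWarning)
        r, g, b = normalize_rgb(means)
    assert r + g + b == pytest.approx(1.0, abs=1e-9)


# -- RGB <-> XYZ <-> Lab -----------------------------------------------------

def test_white_maps_to_white_point():
    xyz = rgb_to_xyz(ChannelMeans(255, 255, 255))
    assert (xyz.X, xyz.Y, xyz.Z) == pytest.approx((D65.Xn, D65.Yn, D65.Zn), rel=1e-9)
    assert xyz_to_lab(xyz) == pytest.approx((100.0, 0.0, 0.0), abs=1e-9)


def test_black_maps_to_zero():
    xyz = rgb_to_xyz(ChannelMeans(0, 0, 0))
    assert (xyz.X, xyz.Y, xyz.Z) == (0.0, 0.0, 0.0)
    assert xyz_to_lab(xyz) == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)


def test_srgb_green_xyz_against_hand_computed_reference():
    # Frozen from a by-hand evaluation of the published sRGB D65 matrix:
    # u = 128/255 -> linear 0.2158605; X,Y,Z columns scaled by 100.
    xyz = rgb_to_xyz(ChannelMeans(0, 128, 0))
    assert xyz.X == pytest.approx(7.718656, rel=1e-5)
    assert xyz.Y == pytest.approx(15.437311, rel=1e-5)
    assert xyz.Z == pytest.approx(2.572884, rel=1e-5)


def test_midgray_lightness_closed_form():
    """Neutral color at Y = 18.4% of Yn: a* = b* = 0 and the closed-form L*."""
    y = 0.184 * D65.Yn
    xyz = TristimulusXYZ(0.184 * D65.Xn, y, 0.184 * D65.Zn)
    L, a, b = xyz_to_lab(xyz)
    assert a == pytest.approx(0.0, abs=1e-12)
    assert b == pytest.approx(0.0, abs=1e-12)
    assert L == pytest.approx(49.977714, abs=1e-5)  # 116*f(0.184) - 16


def test_lab_agrees_with_skimage_reference():
    """Cross-check the full RGB->Lab path against scikit-image's rgb2lab."""
    rng = np.random.default_rng(5)
    rgbs = rng.integers(0, 256, size=(50, 3))
    ours = np.array(
        [xyz_to_lab(rgb_to_xyz(ChannelMeans(*map(int, t)))) for t in rgbs]
    )
    ref = skcolor.rgb2lab(rgbs[None, :, :] / 255.0)[0]
    assert np.allclose(ours, ref, atol=5e-3)


def test_lab_to_xyz_inverts_xyz_to_lab(rng):
    """Inverse reproduces XYZ to 1e-6 relative error above the linear segment."""
    eps = (6 / 29) ** 3
    for _ in range(200):
        ratios = rng.uniform(eps * 1.5, 1.0, size=3)
        xyz = TristimulusXYZ(ratios[0] * D65.Xn, ratios[1] * D65.Yn, ratios[2] * D65.Zn)
        back = lab_to_xyz(xyz_to_lab(xyz))
        assert back.X == pytest.approx(xyz.X, rel=1e-6)
        assert back.Y == pytest.approx(xyz.Y, rel=1e-6)
        assert back.Z == pytest.approx(xyz.Z, rel=1e-6)


def test_lab_rgb_round_trip_within_one_digital_number(rng):
    """rgb -> lab -> rgb differs by <= 1 DN across 1000 random triplets."""
    rgbs = rng.integers(0, 256, size=(1000, 3))
    for t in rgbs:
        means = ChannelMeans(*(int(v) for v in t))
        lab = xyz_to_lab(rgb_to_xyz(means))
        back = lab_to_rgb(lab)
        assert abs(back.R - means.R) <= 1.0
        assert abs(back.G - means.G) <= 1.0
        assert abs(back.B - means.B) <= 1.0


def test_lab_inverse_of_white_and_black():
    w = lab_to_rgb((100.0, 0.0, 0.0))
    assert (w.R, w.G, w.B) == pytest.approx((255.0, 255.0, 255.0), abs=1e-6)
    k = lab_to_rgb((0.0, 0.0, 0.0))
    assert (k.R, k.G, k.B) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)


def test_out_of_gamut_lab_is_clipped_with_flag():
    with pytest.warns(GamutWarning):
        out = lab_to_rgb((50.0, -120.0, 60.0))
    assert 0.0 <= min(out.R, out.G, out.B)
    assert max(out.R, out.G, out.B) <= 255.0
    with pytest.raises(ValueError):
        lab_to_rgb((50.0, -120.0, 60.0), clip=False)


def test_lightness_monotone_in_luminance():
    ys = np.linspace(0.0, 100.0, 60)
    Ls = [
        xyz_to_lab(TristimulusXYZ(y * D65.Xn / 100, y, y * D65.Zn / 100))[0]
        for y in ys
    ]
    assert np.all(np.diff(Ls) > 0)


def test_bstar_decreases_with_more_blue():
    """Adding blue to a green canopy color moves b* toward the blue pole."""
    bstars = []
    for B in (10, 40, 70, 100, 130):
        idx = compute_index_set(ChannelMeans(60, 140, B))
        bstars.append(idx.bstar)
    assert np.all(np.diff(bstars) < 0)


def test_unknown_configuration_rejected():
    with pytest.raises(ConfigurationError):
        ColorConfig(gamma_policy="gamma22")
    with pytest.raises(ConfigurationError):
        ColorConfig(primaries="adobe")
    with pytest.raises(ConfigurationError):
        ColorConfig(white="E")


# -- index-set assembly ------------------------------------------------------

def test_achromatic_index_set():
    idx = compute_index_set(ChannelMeans(85, 85, 85))
    assert idx.r == idx.g == idx.b == pytest.approx(1 / 3)
    assert idx.VI_Green == 0.0
    assert idx.H == 0.0
    assert "zero_chroma" in idx.flags
    assert idx.astar == pytest.approx(0.0, abs=1e-9)
    assert idx.bstar == pytest.approx(0.0, abs=1e-9)
    assert math.isnan(idx.bstar_over_astar)
    assert "astar_zero" in idx.flags


def test_green_canopy_signs():
    """A yellow-green canopy triplet has b* > 0 and VI_Green > 0."""
    idx = compute_index_set(ChannelMeans(99, 127, 75))
    assert idx.bstar > 0
    assert idx.VI_Green > 0


def test_bstar_ratio_definitional(rng):
    for _ in range(50):
        R, G, B = (int(v) for v in rng.integers(0, 256, size=3))
        idx = compute_index_set(ChannelMeans(R, G, B))
        if not math.isnan(idx.bstar_over_astar):
            assert idx.bstar_over_astar == idx.bstar / idx.astar


def test_per_pixel_mode_matches_mean_mode_for_constant_pixels():
    px = np.tile([99, 127, 75], (40, 1))
    per = compute_index_set_per_pixel(px)
    mean = compute_index_set(ChannelMeans(99, 127, 75))
    for name in ("r", "g", "b", "INT", "VI_Green", "H", "Lstar", "astar", "bstar"):
        assert getattr(per, name) == pytest.approx(getattr(mean, name), abs=1e-9)
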