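"""Color-space mathematics for canopy color indices.

Thirteen per-image indices from three color models are computed from the
mean red/green/blue digital numbers of the segmented canopy:

* RGB model: the channel means ``R, G, B``; the chromatic coordinates
  ``r = R/(R+G+B)`` etc.; the intensity ``INT = (R+G+B)/3``; and the
  vegetation index ``VI_Green = (G-R)/(G+R)``.
* HSV model: the hexcone hue ``H`` in degrees.
* CIE 1976 L*a*b*: lightness ``L*`` and the opponent chroma axes ``a*``
  (+red/-green) and ``b*`` (+yellow/-blue), plus the ratio ``b*/a*``.

The L*a*b* coordinates of an 8-bit camera triplet depend on a conversion
convention (transfer function, RGB primaries, reference white) that consumer
JPEGs leave implicit.  The convention here defaults to sRGB primaries with
the sRGB transfer function and the D65 2-degree white point, and is carried
explicitly in :class:`ColorConfig` so results are reproducible and the
choice is recorded in every output.

All functions are pure; vectorized helpers accept numpy arrays so the same
formulas drive per-pixel computation in the optional sensitivity mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "ChannelMeans",
    "TristimulusXYZ",
    "WhitePoint",
    "ColorConfig",
    "ColorIndexSet",
    "ConfigurationError",
    "DegenerateColorWarning",
    "GamutWarning",
    "D65",
    "DEFAULT_CONFIG",
    "INDEX_NAMES",
    "normalize_rgb",
    "intensity",
    "vi_green",
    "rgb_to_hue",
    "hue_degrees",
    "rgb_to_xyz",
    "xyz_to_lab",
    "lab_to_xyz",
    "lab_to_rgb",
    "compute_index_set",
    "compute_index_set_per_pixel",
]


class ConfigurationError(ValueError):
    """Unknown color-conversion configuration name."""


class DegenerateColorWarning(UserWarning):
    """Degenerate color input (zero channel sum, zero chroma, a* = 0)."""


class GamutWarning(UserWarning):
    """A Lab color fell outside the RGB gamut and was clipped."""


@dataclass(frozen=True)
class WhitePoint:
    """Tristimulus of the reference white, scaled so Yn = 100."""

    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if not (self.Xn > 0 and self.Yn > 0 and self.Zn > 0):
            raise ValueError("white point tristimulus values must be strictly positive")


#: CIE D65, 2-degree observer, Yn = 100.
D65 = WhitePoint(95.047, 100.0, 108.883)

_WHITEPOINTS = {"D65": D65, "D50": WhitePoint(96.422, 100.0, 82.521)}

# Linear sRGB -> XYZ (D65, 2-degree).  Rows are renormalized so that
# (1,1,1) maps exactly onto the D65 white point: the published 7-digit
# coefficients sum to the white only to ~1e-7, which would leave neutral
# inputs with a spurious nonzero a*.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_SRGB_TO_XYZ *= (
    np.array([D65.Xn, D65.Yn, D65.Zn]) / 100.0 / _SRGB_TO_XYZ.sum(axis=1)
)[:, None]
_PRIMARIES = {"srgb": _SRGB_TO_XYZ}
_GAMMA_POLICIES = ("srgb", "linear")


@dataclass(frozen=True)
class ChannelMeans:
    """Mean red/green/blue digital numbers over the canopy pixels."""

    R: float
    G: float
    B: float
    n_pixels: int = 1

    def __post_init__(self) -> None:
        for name in ("R", "G", "B"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 255.0:
                raise ValueError(f"channel mean {name}={v!r} outside [0, 255]")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")


@dataclass(frozen=True)
class TristimulusXYZ:
    """CIE tristimulus values on the Yn = 100 scale."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0 or self.Z < 0:
            raise ValueError("tristimulus values must be non-negative")


@dataclass(frozen=True)
class ColorConfig:
    """Convention for the RGB <-> XYZ <-> L*a*b* path.

    Parameters
    ----------
    gamma_policy:
        ``"srgb"`` (IEC 61966-2-1 transfer function, default) or
        ``"linear"`` (channels already proportional to radiance).
    primaries:
        Name of the linear-RGB -> XYZ matrix; only ``"srgb"`` is built in.
    white:
        Reference white name, ``"D65"`` (default) or ``"D50"``.
    """

    gamma_policy: str = "srgb"
    primaries: str = "srgb"
    white: str = "D65"

    def __post_init__(self) -> None:
        if self.gamma_policy not in _GAMMA_POLICIES:
            raise ConfigurationError(f"unknown gamma_policy {self.gamma_policy!r}")
        if self.primaries not in _PRIMARIES:
            raise ConfigurationError(f"unknown primaries {self.primaries!r}")
        if self.white not in _WHITEPOINTS:
            raise ConfigurationError(f"unknown white point {self.white!r}")

    @property
    def whitepoint(self) -> WhitePoint:
        return _WHITEPOINTS[self.white]

    @property
    def matrix(self) -> np.ndarray:
        return _PRIMARIES[self.primaries]

    def to_dict(self) -> dict[str, Any]:
        return {
            "gamma_policy": self.gamma_policy,
            "primaries": self.primaries,
            "white": self.white,
        }


DEFAULT_CONFIG = ColorConfig()

#: Canonical ordering of the 13 indices.
INDEX_NAMES = (
    "R", "G", "B", "r", "g", "b", "INT", "VI_Green",
    "H", "Lstar", "astar", "bstar", "bstar_over_astar",
)


@dataclass(frozen=True)
class ColorIndexSet:
    """The 13 color indices of one canopy observation.

    ``flags`` records degenerate-input conditions (``"zero_rgb_sum"``,
    ``"zero_chroma"``, ``"astar_zero"``, ``"zero_red_plus_green"``) so
    downstream consumers never have to re-derive them.
    """

    R: float
    G: float
    B: float
    r: float
    g: float
    b: float
    INT: float
    VI_Green: float
    H: float
    Lstar: float
    astar: float
    bstar: float
    bstar_over_astar: float
    flags: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        """Indices in canonical order (flags excluded)."""
        return {name: getattr(self, name) for name in INDEX_NAMES}


# ---------------------------------------------------------------------------
# RGB-model indices
# ---------------------------------------------------------------------------

def normalize_rgb(means: ChannelMeans) -> tuple[float, float, float]:
    """Chromatic coordinates r, g, b = R/(R+G+B), G/(R+G+B), B/(R+G+B).

    A pure-black input (R+G+B = 0) has undefined chromaticity; the neutral
    point (1/3, 1/3, 1/3) is returned with a :class:`DegenerateColorWarning`.
    """
    total = float(means.R) + float(means.G) + float(means.B)
    if total == 0.0:
        warnings.warn(
            "R+G+B = 0: chromatic coordinates undefined, returning (1/3, 1/3, 1/3)",
            DegenerateColorWarning,
            stacklevel=2,
        )
        return (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    return (float(means.R) / total, float(means.G) / total, float(means.B) / total)


def intensity(means: ChannelMeans) -> float:
    """INT = (R + G + B) / 3, in digital numbers."""
    return (float(means.R) + float(means.G) + float(means.B)) / 3.0


def vi_green(means: ChannelMeans) -> float:
    """VI_Green = (G - R)/(G + R), in [-1, 1]; 0 with a warning if G+R = 0."""
    denom = float(means.G) + float(means.R)
    if denom == 0.0:
        warnings.warn(
            "G + R = 0: VI_Green undefined, returning 0",
            DegenerateColorWarning,
            stacklevel=2,
        )
        return 0.0
    return (float(means.G) - float(means.R)) / denom


# ---------------------------------------------------------------------------
# HSV hue
# ---------------------------------------------------------------------------

def hue_degrees(R, G, B):
    """Hexcone HSV hue in degrees [0, 360), vectorized.

    Zero-chroma inputs map to 0.  Sector ties resolve in the natural branch
    order of the piecewise formula: R-max, then G-max, then B-max.
    """
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    mx = np.maximum(np.maximum(R, G), B)
    mn = np.minimum(np.minimum(R, G), B)
    d = mx - mn
    d_safe = np.where(d == 0.0, 1.0, d)
    h_r = 60.0 * np.mod((G - B) / d_safe, 6.0)
    h_g = 60.0 * ((B - R) / d_safe + 2.0)
    h_b = 60.0 * ((R - G) / d_safe + 4.0)
    h = np.where(mx == R, h_r, np.where(mx == G, h_g, h_b))
    return np.where(d == 0.0, 0.0, np.mod(h, 360.0))


def rgb_to_hue(means: ChannelMeans) -> float:
    """HSV hue of the channel means, degrees in [0, 360); 0 for zero chroma."""
    if means.R == means.G == means.B:
        warnings.warn(
            "zero chroma (R = G = B): hue undefined, returning 0",
            DegenerateColorWarning,
            stacklevel=2,
        )
        return 0.0
    return float(hue_degrees(means.R, means.G, means.B))


# ---------------------------------------------------------------------------
# RGB <-> XYZ <-> L*a*b*
# ---------------------------------------------------------------------------

def _decode_gamma(u: np.ndarray, policy: str) -> np.ndarray:
    """Encoded [0,1] channel -> linear radiance [0,1]."""
    if policy == "linear":
        return u
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def _encode_gamma(v: np.ndarray, policy: str) -> np.ndarray:
    """Linear radiance [0,1] -> encoded [0,1] channel."""
    if policy == "linear":
        return v
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * np.power(v, 1.0 / 2.4) - 0.055)


def rgb_arrays_to_xyz(R, G, B, config: ColorConfig = DEFAULT_CONFIG):
    """Vectorized 8-bit RGB -> XYZ on the Yn = 100 scale."""
    u = np.stack(
        [np.asarray(R, float), np.asarray(G, float), np.asarray(B, float)], axis=-1
    ) / 255.0
    lin = _decode_gamma(u, config.gamma_policy)
    xyz = 100.0 * lin @ config.matrix.T
    return xyz[..., 0], xyz[..., 1], xyz[..., 2]


def rgb_to_xyz(means: ChannelMeans, config: ColorConfig = DEFAULT_CONFIG) -> TristimulusXYZ:
    """Convert 8-bit channel means to CIE tristimulus values.

    Channels are scaled to [0, 1], linearized per ``config.gamma_policy``,
    mapped through the primaries matrix, and scaled so that the reference
    white carries Y = 100.
    """
    X, Y, Z = rgb_arrays_to_xyz(means.R, means.G, means.B, config)
    return TristimulusXYZ(float(X), float(Y), float(Z))


_LAB_EPS = (6.0 / 29.0) ** 3  # ratio threshold of the linear segment
_LAB_KAPPA = 3.0 * (6.0 / 29.0) ** 2


def _lab_f(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return np.where(t > _LAB_EPS, np.cbrt(t), t / _LAB_KAPPA + 4.0 / 29.0)


def _lab_finv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > 6.0 / 29.0, ft**3, _LAB_KAPPA * (ft - 4.0 / 29.0))


def xyz_arrays_to_lab(X, Y, Z, white: WhitePoint = D65):
    """Vectorized XYZ -> CIE 1976 L*a*b*."""
    fx = _lab_f(np.asarray(X, float) / white.Xn)
    fy = _lab_f(np.asarray(Y, float) / white.Yn)
    fz = _lab_f(np.asarray(Z, float) / white.Zn)
    L = 116.0 * fy - 16.0
    a = 500.0 * (fx - fy)
    b = 200.0 * (fy - fz)
    return L, a, b


def xyz_to_lab(
    xyz: TristimulusXYZ, white: WhitePoint = D65
) -> tuple[float, float, float]:
    """CIE 1976 L*a*b* from tristimulus values.

    Uses the cube-root compression with its linear segment below the
    (6/29)^3 ratio threshold.  The white point itself maps to (100, 0, 0);
    +b* is yellow, -b* is blue.
    """
    L, a, b = xyz_arrays_to_lab(xyz.X, xyz.Y, xyz.Z, white)
    return float(L), float(a), float(b)


def lab_to_xyz(
    lab: tuple[float, float, float], white: WhitePoint = D65
) -> TristimulusXYZ:
    """Exact inverse of :func:`xyz_to_lab`."""
    L, a, b = (float(v) for v in lab)
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - b / 200.0
    X = float(_lab_finv(fx)) * white.Xn
    Y = float(_lab_finv(fy)) * white.Yn
    Z = float(_lab_finv(fz)) * white.Zn
    return TristimulusXYZ(max(X, 0.0), max(Y, 0.0), max(Z, 0.0))


def lab_to_rgb(
    lab: tuple[float, float, float],
    config: ColorConfig = DEFAULT_CONFIG,
    clip: bool = True,
) -> ChannelMeans:
    """Inverse conversion L*a*b* -> 8-bit RGB channel values.

    Out-of-gamut colors are clipped to [0, 255] with a :class:`GamutWarning`
    (or raise ``ValueError`` when ``clip=False``).  The returned channel
    values are floats; quantize with ``round`` for raster rendering.
    """
    xyz = lab_to_xyz(lab, config.whitepoint)
    lin = np.linalg.solve(config.matrix, np.array([xyz.X, xyz.Y, xyz.Z]) / 100.0)
    out_of_gamut = bool(np.any(lin < -1e-9) or np.any(lin > 1.0 + 1e-9))
    if out_of_gamut:
        if not clip:
            raise ValueError(f"Lab color {lab} is outside the RGB gamut")
        warnings.warn(
            f"Lab color {lab} outside the RGB gamut; channels clipped",
            GamutWarning,
            stacklevel=2,
        )
    lin = np.clip(lin, 0.0, 1.0)
    enc = np.clip(_encode_gamma(lin, config.gamma_policy), 0.0, 1.0) * 255.0
    return ChannelMeans(float(enc[0]), float(enc[1]), float(enc[2]))


# ---------------------------------------------------------------------------
# Index-set assembly
# ---------------------------------------------------------------------------

def compute_index_set(
    means: ChannelMeans, config: ColorConfig = DEFAULT_CONFIG
) -> ColorIndexSet:
    """Assemble all 13 indices from canopy-mean channel values.

    Indices are computed from the mean R, G, B (not averaged per pixel);
    see :func:`compute_index_set_per_pixel` for the sensitivity-analysis
    alternative.  Degenerate inputs produce flags rather than non-finite
    values, except ``bstar_over_astar`` which is NaN when a* = 0.
    """
    flags: list[str] = []
    total = float(means.R) + float(means.G) + float(means.B)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateColorWarning)
        r, g, b = normalize_rgb(means)
        vig = vi_green(means)
        H = rgb_to_hue(means)
    if total == 0.0:
        flags.append("zero_rgb_sum")
    if float(means.G) + float(means.R) == 0.0:
        flags.append("zero_red_plus_green")
    if means.R == means.G == means.B:
        flags.append("zero_chroma")
    xyz = rgb_to_xyz(means, config)
    Lstar, astar, bstar = xyz_to_lab(xyz, config.whitepoint)
    # |a*| below 1e-9 is numerically neutral; the ratio is reported missing
    # rather than as an arbitrarily huge or roundoff-dominated value.
    if abs(astar) < 1e-9:
        flags.append("astar_zero")
        ratio = float("nan")
    else:
        ratio = bstar / astar
    return ColorIndexSet(
        R=float(means.R),
        G=float(means.G),
        B=float(means.B),
        r=r,
        g=g,
        b=b,
        INT=intensity(means),
        VI_Green=vig,
        H=H,
        Lstar=Lstar,
        astar=astar,
        bstar=bstar,
        bstar_over_astar=ratio,
        flags=tuple(flags),
    )


def compute_index_set_per_pixel(
    pixels: np.ndarray, config: ColorConfig = DEFAULT_CONFIG
) -> ColorIndexSet:
    """Per-pixel index computation averaged afterwards (sensitivity mode).

    ``pixels`` is an (N, 3) array of 8-bit RGB values.  Each index is
    evaluated pixel-wise with the same formulas as :func:`compute_index_set`
    and then arithmetically averaged; the hue average is a plain arithmetic
    mean of degrees, which is only meaningful when the pixel hues do not
    straddle the 0/360 wrap.  Nonlinear indices (chromatic coordinates, hue,
    L*a*b*) generally differ from the mean-first default; that difference is
    exactly what this mode exposes.
    """
    px = np.asarray(pixels, dtype=float)
    if px.ndim != 2 or px.shape[1] != 3 or px.shape[0] < 1:
        raise ValueError("pixels must be a non-empty (N, 3) array")
    R, G, B = px[:, 0], px[:, 1], px[:, 2]
    total = R + G + B
    total_safe = np.where(total == 0.0, 1.0, total)
    r = np.where(total == 0.0, 1.0 / 3.0, R / total_safe)
    g = np.where(total == 0.0, 1.0 / 3.0, G / total_safe)
    b = np.where(total == 0.0, 1.0 / 3.0, B / total_safe)
    gr = G + R
    vig = np.where(gr == 0.0, 0.0, (G - R) / np.where(gr == 0.0, 1.0, gr))
    H = hue_degrees(R, G, B)
    X, Y, Z = rgb_arrays_to_xyz(R, G, B, config)
    L, a, bb = xyz_arrays_to_lab(X, Y, Z, config.whitepoint)
    ratio = np.where(a == 0.0, np.nan, bb / np.where(a == 0.0, 1.0, a))
    mean_a = float(np.mean(a))
    if mean_a == 0.0:
        mean_ratio = float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_ratio = float(np.nanmean(ratio))
    return ColorIndexSet(
        R=float(np.mean(R)),
        G=float(np.mean(G)),
        B=float(np.mean(B)),
        r=float(np.mean(r)),
        g=float(np.mean(g)),
        b=float(np.mean(b)),
        INT=float(np.mean(total) / 3.0),
        VI_Green=float(np.mean(vig)),
        H=float(np.mean(H)),
        Lstar=float(np.mean(L)),
        astar=mean_a,
        bstar=float(np.mean(bb)),
        bstar_over_astar=mean_ratio,
        flags=("per_pixel",),
    )
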