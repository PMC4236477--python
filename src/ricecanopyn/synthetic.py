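"""Synthetic canopy scenes and study tables with known ground truth.

Field photographs and the paired SPAD/LNC measurements are not released
with desk-scale studies, so every pipeline stage here is exercised against
synthetic data with exact truth:

* :func:`render_canopy_image` paints elongated leaf shapes of a configured
  CIELAB color over a soil background, with per-pixel Gaussian color noise
  and optional over-exposed "white spots", returning the exact boolean leaf
  mask alongside the image.
* :func:`simulate_dataset` draws plot-level records following the two-year
  rice study template — four developmental stages per cultivar at fixed
  days-after-transplanting (DAT), with SPAD or the color index b* as
  predictors — and generates the response from one of the four calibration
  model forms plus Gaussian residual noise.
* :func:`make_study` produces a disjoint calibration/validation table pair
  emulating the two independent field seasons.

All generators are fully deterministic given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .color import DEFAULT_CONFIG, ColorConfig, lab_to_rgb
from .segmentation import CanopyImage, CanopyMask
from .stats import MODEL_SPECS, REFERENCE_FITS, STAGES

__all__ = [
    "RenderConfig",
    "CultivarDesign",
    "StudyDesign",
    "CALIBRATION_CULTIVARS",
    "VALIDATION_CULTIVARS",
    "default_calibration_design",
    "default_validation_design",
    "leaf_base_rgb",
    "render_canopy_image",
    "simulate_dataset",
    "make_study",
]


@dataclass(frozen=True)
class RenderConfig:
    """Parameters of one rendered canopy scene.

    Leaf color is specified in CIELAB so the yellow-blue axis b* — the
    index the nitrogen models use — is controlled directly.  The soil
    default (120, 100, 80) keeps G - R <= 0, the separation the G-R
    segmentation method assumes; the leaf default maps into gamut with
    G - R > 0.
    """

    shape: tuple[int, int] = (160, 160)
    canopy_fraction: float = 0.5
    leaf_lab: tuple[float, float, float] = (50.0, -20.0, 25.0)
    leaf_noise_sd: float = 5.0
    soil_rgb: tuple[int, int, int] = (120, 100, 80)
    white_spot_fraction: float = 0.0
    seed: int = 0
    fraction_tol: float = 0.03
    max_attempts: int = 50000
    color_config: ColorConfig = DEFAULT_CONFIG

    def __post_init__(self) -> None:
        if not 0.0 <= self.canopy_fraction <= 1.0:
            raise ValueError("canopy_fraction must be in [0, 1]")
        if not 0.0 <= self.white_spot_fraction <= 1.0:
            raise ValueError("white_spot_fraction must be in [0, 1]")
        if self.soil_rgb[1] > self.soil_rgb[0]:
            raise ValueError("soil color must satisfy G - R <= 0")
        if self.leaf_noise_sd < 0:
            raise ValueError("leaf_noise_sd must be non-negative")


def leaf_base_rgb(cfg: RenderConfig) -> tuple[int, int, int]:
    """The quantized 8-bit RGB triplet painted for noise-free leaf pixels."""
    means = lab_to_rgb(cfg.leaf_lab, cfg.color_config, clip=False)
    rgb = (int(round(means.R)), int(round(means.G)), int(round(means.B)))
    if rgb[1] <= rgb[0]:
        raise ValueError(
            f"leaf color {cfg.leaf_lab} maps to RGB {rgb} with G - R <= 0; "
            "it would not be separable from soil"
        )
    return rgb


def render_canopy_image(cfg: RenderConfig) -> tuple[CanopyImage, CanopyMask]:
    """Render one canopy scene and its exact ground-truth mask.

    Rotated ellipses (aspect ratio ~1:4, emulating elongated rice blades)
    are placed at random until the canopy fraction is within
    ``fraction_tol`` of the target; placements that would overshoot the
    band are skipped.  Leaf pixels get the configured Lab color (converted
    to 8-bit RGB) plus i.i.d. Gaussian channel noise, clipped to [0, 255].
    White spots overwrite a random fraction of leaf pixels with G = 255 and
    R, B in [250, 255], emulating specular over-exposure.
    """
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.shape
    img = np.empty((H, W, 3), dtype=np.uint8)
    img[:] = np.array(cfg.soil_rgb, dtype=np.uint8)
    mask = np.zeros((H, W), dtype=bool)
    base = np.array(leaf_base_rgb(cfg), dtype=float)

    target = cfg.canopy_fraction
    tol = cfg.fraction_tol
    scale = max(H, W)
    attempts = 0
    while mask.mean() < target - tol:
        attempts += 1
        if attempts > cfg.max_attempts:
            raise RuntimeError(
                f"canopy fraction {target} unreachable within {cfg.max_attempts} "
                "leaf placements"
            )
        r0 = rng.uniform(0, H)
        c0 = rng.uniform(0, W)
        semi_major = rng.uniform(scale / 16, scale / 8)
        semi_minor = semi_major * rng.uniform(0.2, 0.3)
        angle = rng.uniform(0, np.pi)
        rr, cc = ellipse(r0, c0, semi_major, semi_minor, shape=(H, W), rotation=angle)
        if rr.size == 0:
            continue
        candidate = mask.copy()
        candidate[rr, cc] = True
        if candidate.mean() > target + tol:
            continue
        mask = candidate

    n_leaf = int(mask.sum())
    if n_leaf:
        noise = rng.normal(0.0, cfg.leaf_noise_sd, size=(n_leaf, 3))
        leaf_px = np.clip(np.round(base + noise), 0, 255).astype(np.uint8)
        img[mask] = leaf_px
        n_spots = int(round(cfg.white_spot_fraction * n_leaf))
        if n_spots:
            idx = rng.choice(n_leaf, size=n_spots, replace=False)
            rows, cols = np.nonzero(mask)
            spots = np.empty((n_spots, 3), dtype=np.uint8)
            spots[:, 0] = rng.integers(250, 256, size=n_spots)
            spots[:, 1] = 255
            spots[:, 2] = rng.integers(250, 256, size=n_spots)
            img[rows[idx], cols[idx]] = spots

    image = CanopyImage(
        pixels=img,
        meta={
            "synthetic": True,
            "leaf_lab": tuple(cfg.leaf_lab),
            "leaf_rgb": tuple(int(v) for v in base),
            "soil_rgb": tuple(cfg.soil_rgb),
            "seed": cfg.seed,
            "white_spot_fraction": cfg.white_spot_fraction,
        },
    )
    true_mask = CanopyMask(
        mask=mask, coverage=float(mask.mean()), threshold_used=float("nan")
    )
    return image, true_mask


# ---------------------------------------------------------------------------
# Tabular study simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CultivarDesign:
    """Sampling-date design of one cultivar: DAT per stage, records per stage."""

    name: str
    dat: tuple[int, int, int, int]
    n_per_stage: int

    def __post_init__(self) -> None:
        if len(self.dat) != len(STAGES):
            raise ValueError(f"need one DAT per stage {STAGES}")
        if self.n_per_stage < 1:
            raise ValueError("n_per_stage must be >= 1")


#: 2011-season template (calibration): three cultivars, four stages,
#: per-stage DAT from the study design; 240 records in total.
CALIBRATION_CULTIVARS: tuple[CultivarDesign, ...] = (
    CultivarDesign("Liangyoupeijiu", (16, 29, 51, 65), 18),
    CultivarDesign("Nanjing45", (16, 29, 51, 57), 18),
    CultivarDesign("Nanjing46", (18, 35, 55, 75), 24),
)

#: 2010-season template (validation): 216 records.
VALIDATION_CULTIVARS: tuple[CultivarDesign, ...] = (
    CultivarDesign("Wuyunjing24", (25, 36, 50, 64), 18),
    CultivarDesign("Nanjing44", (22, 35, 49, 63), 18),
    CultivarDesign("Yangjing48", (22, 35, 49, 63), 18),
)


@dataclass(frozen=True)
class StudyDesign:
    """Generator settings for one synthetic study table.

    ``coefficients`` holds alpha/beta/gamma of the chosen model form;
    ``noise_sd`` the Gaussian residual standard deviation in response
    units.  Predictors are drawn uniformly over their ranges; DAT comes
    from the cultivar designs.
    """

    model_id: int = 2
    coefficients: Mapping[str, float] = field(
        default_factory=lambda: {"alpha": -0.67, "beta": -0.29, "gamma": 69.27}
    )
    noise_sd: float = 3.36
    cultivars: tuple[CultivarDesign, ...] = CALIBRATION_CULTIVARS
    spad_range: tuple[float, float] = (25.0, 45.0)
    bstar_range: tuple[float, float] = (-10.0, 20.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_SPECS:
            raise ValueError(f"model_id must be 1-4, got {self.model_id!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        spec = MODEL_SPECS[self.model_id]
        needed = {"alpha", "gamma"} | ({"beta"} if spec.has_dat else set())
        if not needed <= set(self.coefficients):
            raise ValueError(f"coefficients must provide {sorted(needed)}")

    @property
    def n_total(self) -> int:
        return sum(c.n_per_stage * len(STAGES) for c in self.cultivars)


def default_calibration_design(model_id: int = 2, seed: int = 0) -> StudyDesign:
    """Study template with the published Model coefficients as truth and the
    published calibration RMSE as the residual noise scale (n = 240)."""
    ref = REFERENCE_FITS[model_id]
    coeffs = {"alpha": ref["alpha"], "gamma": ref["gamma"]}
    if ref["beta"] is not None:
        coeffs["beta"] = ref["beta"]
    return StudyDesign(
        model_id=model_id,
        coefficients=coeffs,
        noise_sd=float(ref["rmse"]),
        cultivars=CALIBRATION_CULTIVARS,
        seed=seed,
    )


def default_validation_design(model_id: int = 2, seed: int = 1) -> StudyDesign:
    """As :func:`default_calibration_design` but on the 2010-season template."""
    return replace(
        default_calibration_design(model_id=model_id, seed=seed),
        cultivars=VALIDATION_CULTIVARS,
    )


def simulate_dataset(design: StudyDesign) -> pd.DataFrame:
    """Draw one study table from the design.

    Columns: ``plot_id, cultivar, stage, DAT, SPAD, bstar, LNC``.  The
    response column of the chosen model is generated as the linear form
    plus Gaussian(0, noise_sd); predictor columns are uniform draws.  The
    response column the model does not involve is left NaN rather than
    invented from an auxiliary relation.
    """
    spec = MODEL_SPECS[design.model_id]
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    plot = 0
    for cult in design.cultivars:
        for stage, dat in zip(STAGES, cult.dat):
            for _ in range(cult.n_per_stage):
                plot += 1
                rows.append(
                    {
                        "plot_id": f"P{plot:04d}",
                        "cultivar": cult.name,
                        "stage": stage,
                        "DAT": dat,
                    }
                )
    df = pd.DataFrame(rows)
    n = len(df)
    df["bstar"] = rng.uniform(*design.bstar_range, size=n)
    if "SPAD" in spec.predictors:
        df["SPAD"] = rng.uniform(*design.spad_range, size=n)
    x1 = df[spec.predictors[0]].to_numpy()
    linear = design.coefficients["alpha"] * x1 + design.coefficients["gamma"]
    if spec.has_dat:
        linear = linear + design.coefficients["beta"] * df["DAT"].to_numpy()
    response = linear + rng.normal(0.0, design.noise_sd, size=n)
    df[spec.response] = response
    for col in ("SPAD", "LNC"):
        if col not in df.columns:
            df[col] = np.nan
    return df.loc[:, ["plot_id", "cultivar", "stage", "DAT", "SPAD", "bstar", "LNC"]]


def make_study(
    calibration: StudyDesign | None = None,
    validation: StudyDesign | None = None,
    model_id: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a disjoint calibration/validation table pair.

    Defaults reproduce the study layout: the calibration draw on the
    three-cultivar 2011-style template (240 records) and the validation
    draw on the 2010-style template (216 records), with independent seeds
    (``seed`` and ``seed + 1``).  Identical seeds trigger a warning since
    the two random streams would coincide.
    """
    if calibration is None:
        calibration = default_calibration_design(model_id=model_id, seed=seed)
    if validation is None:
        validation = default_validation_design(model_id=model_id, seed=seed + 1)
    if calibration.seed == validation.seed:
        warnings.warn(
            "calibration and validation share a seed: random streams overlap",
            UserWarning,
            stacklevel=2,
        )
    return simulate_dataset(calibration), simulate_dataset(validation)
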