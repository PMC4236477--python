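"""End-to-end orchestration: images -> masks -> indices -> models.

A run is described by a :class:`RunConfig` (loadable from YAML): an image
manifest (path, plot id, cultivar, DAT per row), an optional sample table
with SPAD/LNC measurements, segmentation and color-conversion settings, the
model ids to fit, an output directory and a seed.  Outputs are CSV tables,
plain-text model files and a machine-readable JSONL event log; every output
carries the hash of the configuration that produced it, and reruns with the
same config are byte-identical.  Failures are per-item: one unreadable
image becomes an error row, never an aborted run.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .color import ColorConfig, INDEX_NAMES
from .segmentation import (
    CanopyImage,
    canopy_channel_means,
    image_index_set,
    segment_canopy,
)
from .stats import MODEL_SPECS, NitrogenLinearModel, ValidationReport

__all__ = ["RunConfig", "RunResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    manifest: str
    output_dir: str
    samples: str | None = None
    validation_samples: str | None = None
    segmentation: dict[str, Any] = field(default_factory=dict)
    color: dict[str, Any] = field(default_factory=dict)
    models: tuple[int, ...] = (4,)
    per_pixel_indices: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.models = tuple(int(m) for m in self.models)
        for m in self.models:
            if m not in MODEL_SPECS:
                raise ValueError(f"unknown model id {m}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "manifest": self.manifest,
            "output_dir": self.output_dir,
            "samples": self.samples,
            "validation_samples": self.validation_samples,
            "segmentation": dict(self.segmentation),
            "color": dict(self.color),
            "models": list(self.models),
            "per_pixel_indices": self.per_pixel_indices,
            "seed": self.seed,
            "version": __version__,
        }

    @property
    def hash(self) -> str:
        # output_dir does not influence results and is excluded, so reruns
        # into different directories keep the same provenance hash
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class RunResult:
    """Everything a run produced, in memory."""

    manifest: pd.DataFrame
    joined: pd.DataFrame | None
    fits: dict[int, NitrogenLinearModel]
    reports: dict[int, ValidationReport]
    join_misses: list[tuple[str, int]]
    config_hash: str
    output_dir: Path


def _log(events: list[dict], outdir: Path, **event) -> None:
    events.append(event)
    with open(outdir / "events.jsonl", "a") as fh:
        fh.write(json.dumps(event, sort_keys=True) + "\n")


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute segment -> means -> indices -> join -> fit -> validate."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "events.jsonl").unlink(missing_ok=True)
    events: list[dict] = []
    chash = cfg.hash
    color_cfg = ColorConfig(**cfg.color)
    seg_kwargs = dict(cfg.segmentation)

    manifest = pd.read_csv(cfg.manifest)
    if manifest.empty:
        raise ValueError(f"empty image manifest {cfg.manifest!r}: nothing to process")
    required = {"path", "plot_id", "DAT"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")

    _log(events, outdir, event="start", config_hash=chash, n_images=len(manifest),
         segmentation=seg_kwargs, color=color_cfg.to_dict())

    rows: list[dict] = []
    for rec in manifest.to_dict("records"):
        row: dict[str, Any] = {
            "path": rec["path"],
            "plot_id": rec["plot_id"],
            "cultivar": rec.get("cultivar"),
            "DAT": rec["DAT"],
            "error": "",
            "warnings": "",
        }
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                image = CanopyImage.from_file(
                    rec["path"],
                    plot_id=str(rec["plot_id"]),
                    cultivar=rec.get("cultivar"),
                    dat=int(rec["DAT"]),
                )
                mask = segment_canopy(image, **seg_kwargs)
                row["coverage"] = mask.coverage
                row["threshold"] = mask.threshold_used
                if mask.coverage > 0:
                    means = canopy_channel_means(image, mask)
                    row["n_pixels"] = means.n_pixels
                    idx = image_index_set(
                        image, mask, color_cfg, per_pixel=cfg.per_pixel_indices
                    )
                    row.update(idx.as_dict())
                    row["flags"] = ";".join(idx.flags)
            row["warnings"] = ";".join(str(w.message) for w in caught)
        except Exception as exc:  # per-item failure, never global
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
        _log(events, outdir, event="image", path=str(rec["path"]),
             error=row["error"], coverage=row.get("coverage"))

    result_manifest = pd.DataFrame(rows)
    result_manifest["config_hash"] = chash
    result_manifest.to_csv(outdir / "indices.csv", index=False)

    joined = None
    join_misses: list[tuple[str, int]] = []
    fits: dict[int, NitrogenLinearModel] = {}
    reports: dict[int, ValidationReport] = {}

    if cfg.samples is not None:
        samples = pd.read_csv(cfg.samples)
        good = result_manifest[
            (result_manifest["error"] == "") & (result_manifest.get("coverage", 0) > 0)
        ].copy()
        n_excluded = len(result_manifest) - len(good)
        if n_excluded:
            _log(events, outdir, event="excluded_images", n=n_excluded)
        good["plot_id"] = good["plot_id"].astype(str)
        samples["plot_id"] = samples["plot_id"].astype(str)
        joined = good.merge(samples, on=["plot_id", "DAT"], how="left", suffixes=("", "_sample"))
        response_cols = [c for c in ("SPAD", "LNC") if c in samples.columns]
        miss_mask = joined[response_cols].isna().all(axis=1) if response_cols else joined.index < 0
        join_misses = [
            (str(r["plot_id"]), int(r["DAT"]))
            for _, r in joined[miss_mask].iterrows()
        ]
        if join_misses:
            _log(events, outdir, event="join_misses", keys=join_misses)
        joined = joined[~miss_mask].copy()
        joined["config_hash"] = chash
        joined.to_csv(outdir / "joined.csv", index=False)

        for model_id in cfg.models:
            fit = NitrogenLinearModel(model_id=model_id).fit(joined)
            fits[model_id] = fit
            fit.save(
                outdir / f"model{model_id}.txt",
                extra={"config_hash": chash, **{f"color.{k}": v for k, v in color_cfg.to_dict().items()}},
            )
            _log(events, outdir, event="fit", model_id=model_id,
                 alpha=fit.alpha_, beta=fit.beta_, gamma=fit.gamma_,
                 r2=fit.r2_, rmse=fit.rmse_, n=fit.n_)

        if cfg.validation_samples is not None:
            vdf = pd.read_csv(cfg.validation_samples)
            vrows = []
            for model_id, fit in fits.items():
                rep = fit.validate(vdf)
                reports[model_id] = rep
                vrows.append(
                    {"model_id": model_id, "rmse": rep.rmse, "r2": rep.r2,
                     "nmb": rep.nmb, "n": rep.n, "config_hash": chash}
                )
                _log(events, outdir, event="validate", model_id=model_id,
                     rmse=rep.rmse, r2=rep.r2, nmb=rep.nmb)
            pd.DataFrame(vrows).to_csv(outdir / "validation.csv", index=False)

    with open(outdir / "config.json", "w") as fh:
        json.dump({"config_hash": chash, **cfg.to_dict()}, fh, sort_keys=True, indent=1)
    _log(events, outdir, event="done", config_hash=chash)

    return RunResult(
        manifest=result_manifest,
        joined=joined,
        fits=fits,
        reports=reports,
        join_misses=join_misses,
        config_hash=chash,
        output_dir=outdir,
    )
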