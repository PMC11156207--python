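"""End-to-end pipeline: manifest of B-scans -> masks + metrics table.

The pipeline reads a manifest CSV (columns ``filename, scale_x, scale_y,
device, scan_type`` plus optional ``eye, fovea_col, region_mask,
vessel_mask``), produces a segmentation for every scan — either from a
trained network checkpoint or from one of the classical vessel
segmenters applied inside a supplied region mask — and derives the
fovea-centred choroidal metrics. Per-file failures are recorded and the
remaining scans still processed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .core import BScan, Device, ScanType, SegmentationOutput
from .fovea import FoveaTargetConfig, build_fovea_target
from .io_prep import load_bscan
from .metrics import ChoroidMetrics, analyze_scan
from .mmcq import EnsembleConfig, MMCQConfig, ensemble_majority_vote
from .niblack import NiblackConfig, segment_vessels_niblack
from .nn import TrainConfig, UNetConfig, load_checkpoint, predict

logger = logging.getLogger("choroidpipe")

__all__ = ["PipelineConfig", "save_config", "load_config", "run_pipeline",
           "write_mask", "read_mask"]

METRICS_COLUMNS = [
    "filename", "fovea_col", "thickness_t", "thickness_c", "thickness_n",
    "thickness_mean_um", "area_mm2", "cvi", "soft_cvi", "flags",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable bundle of every stage's settings."""

    method: str = "model"                 # model | mmcq | niblack
    checkpoint: Optional[str] = None
    region_threshold: float = 0.5
    vessel_threshold: float = 0.5
    peripapillary_vessel_threshold: float = 0.25
    roi_half_width_um: float = 3000.0
    seed: int = 0
    verbosity: str = "info"
    mmcq: MMCQConfig = field(default_factory=MMCQConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    niblack: NiblackConfig = field(default_factory=NiblackConfig)
    unet: UNetConfig = field(default_factory=UNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    fovea: FoveaTargetConfig = field(default_factory=FoveaTargetConfig)


_SUBCONFIGS = {
    "mmcq": MMCQConfig,
    "ensemble": EnsembleConfig,
    "niblack": NiblackConfig,
    "unet": UNetConfig,
    "train": TrainConfig,
    "fovea": FoveaTargetConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    plain = _to_plain(config)
    Path(path).write_text(yaml.safe_dump(plain, sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    plain = yaml.safe_load(Path(path).read_text())
    kwargs = {}
    for key, val in plain.items():
        if key in _SUBCONFIGS:
            kwargs[key] = _from_plain(_SUBCONFIGS[key], val)
        else:
            kwargs[key] = val
    return PipelineConfig(**kwargs)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a 0/255 grayscale PNG."""
    iio.imwrite(Path(path), (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def _segment_row(
    config: PipelineConfig, bscan: BScan, row: pd.Series, root: Path
) -> SegmentationOutput:
    if config.method == "model":
        if config.checkpoint is None:
            raise ValueError("method 'model' requires a checkpoint")
        model = _segment_row._models.setdefault(  # type: ignore[attr-defined]
            config.checkpoint, load_checkpoint(config.checkpoint)
        )
        return predict(model, bscan)
    # classical methods need a region mask to constrain the search
    if "region_mask" not in row or not isinstance(row["region_mask"], str):
        raise ValueError(f"method {config.method!r} requires a region_mask column")
    region = read_mask(root / row["region_mask"])
    if config.method == "mmcq":
        vessel = ensemble_majority_vote(
            bscan.image, region, config.mmcq, config.ensemble
        )
    elif config.method == "niblack":
        vessel = segment_vessels_niblack(bscan.image, region, config.niblack)
    else:
        raise ValueError(f"unknown method {config.method!r}")
    if "fovea_col" in row and not pd.isna(row["fovea_col"]):
        h, w = bscan.shape
        rrows = np.flatnonzero(region[:, int(row["fovea_col"])])
        frow = int(rrows[0]) if rrows.size else h // 2
        fovea = build_fovea_target(
            bscan.shape, int(row["fovea_col"]), frow, config.fovea
        )
    else:
        fovea = np.zeros(bscan.shape)
    return SegmentationOutput(
        region_prob=region.astype(float),
        vessel_prob=vessel.astype(float),
        fovea_prob=fovea,
    )


_segment_row._models = {}  # type: ignore[attr-defined]


def _metrics_row(filename: str, m: ChoroidMetrics) -> dict:
    t, c, n = m.thickness_um
    return {
        "filename": filename,
        "fovea_col": m.fovea_col if m.fovea_col is not None else "",
        "thickness_t": t,
        "thickness_c": c,
        "thickness_n": n,
        "thickness_mean_um": m.thickness_mean_um,
        "area_mm2": m.area_mm2,
        "cvi": m.cvi,
        "soft_cvi": m.soft_cvi,
        "flags": ";".join(m.flags),
    }


def run_pipeline(
    config: PipelineConfig,
    manifest: str | Path,
    out_dir: str | Path,
) -> tuple[pd.DataFrame, int]:
    """Process every scan in ``manifest``; returns (metrics table, n_errors).

    Writes ``metrics.csv``, per-scan 0/255 mask PNGs (region, vessel,
    fovea), per-scan probability maps (``.npy``) and a YAML snapshot of
    the configuration next to the outputs.
    """
    manifest = Path(manifest)
    root = manifest.parent
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(manifest)

    rows: list[dict] = []
    n_errors = 0
    for _, row in table.iterrows():
        name = str(row["filename"])
        try:
            bscan = load_bscan(
                root / name,
                scale_x=float(row["scale_x"]),
                scale_y=float(row["scale_y"]),
                device=row.get("device", Device.UNKNOWN),
                scan_type=row.get("scan_type", ScanType.HLINE),
            )
            seg = _segment_row(config, bscan, row, root)
            stem = Path(name).stem
            np.save(out / f"{stem}_probs.npy", seg.stack().astype(np.float32))
            m = analyze_scan(
                bscan,
                seg,
                region_threshold=config.region_threshold,
                vessel_threshold=config.vessel_threshold,
                peripapillary_vessel_threshold=config.peripapillary_vessel_threshold,
                fovea_config=config.fovea,
            )
            write_mask(m.region_mask, out / f"{stem}_region.png")
            write_mask(m.vessel_mask, out / f"{stem}_vessel.png")
            write_mask(np.asarray(seg.fovea_prob) > 0.5, out / f"{stem}_fovea.png")
            rows.append(_metrics_row(name, m))
        except Exception as exc:  # keep going; report at the end
            logger.error("failed on %s: %s", name, exc)
            rows.append({"filename": name, "flags": f"error: {exc}"})
            n_errors += 1

    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(out / "metrics.csv", index=False)
    save_config(config, out / "config_snapshot.yaml")
    return df, n_errors
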