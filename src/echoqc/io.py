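"""File I/O: frame directories, reports, run manifests, YAML configs.

Videos are directories of frame-index-named 8-bit grayscale PNGs with one
JSON sidecar per frame and a per-frame mask directory of binary PNGs; this
keeps the toolkit codec-free and every artifact diffable.  Every written
artifact embeds a reproducibility manifest (tool version, seed, config
hash).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from .autocapture import CompletenessReport
from .metrics import AccuracyReport
from .phantom import (DegradationConfig, PhantomFrame, PlaneSpec, Segment,
                      VideoScript, default_plane_specs, degradation_sweep)


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable config."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def manifest(seed: Optional[int] = None,
             config: Optional[dict] = None) -> dict:
    return {
        "tool": "echoqc",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(config or {}),
    }


# --------------------------------------------------------------------------
# Frame directories
# --------------------------------------------------------------------------


def _frame_stem(index: int) -> str:
    return f"frame_{index:06d}"


def write_frames(frames: Sequence[PhantomFrame], out_dir,
                 seed: Optional[int] = None,
                 config: Optional[dict] = None) -> None:
    """Write frames as PNGs with mask directories and JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for f in frames:
        stem = _frame_stem(f.frame_index)
        img8 = np.round(np.clip(f.image, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(out / f"{stem}.png", img8)
        mask_dir = out / f"{stem}_masks"
        mask_dir.mkdir(exist_ok=True)
        for name, mask in f.masks.items():
            iio.imwrite(mask_dir / f"{name}.png",
                        (mask.astype(np.uint8) * 255))
        sidecar = {
            "plane": f.plane,
            "qs_true": int(f.qs_true),
            "frame_index": int(f.frame_index),
            "structures": sorted(f.masks.keys()),
            **manifest(seed=seed, config=config),
        }
        with open(out / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)


@dataclass
class FrameDirResult:
    frames: List[PhantomFrame]
    errors: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)


def read_frame_dir(path) -> FrameDirResult:
    """Read a frame directory back, ordered by sidecar frame_index.

    Unreadable images and incomplete sidecars are collected in an error
    manifest instead of being silently dropped.
    """

    path = Path(path)
    result = FrameDirResult(frames=[])
    pngs = sorted(p for p in path.glob("frame_*.png"))
    if not pngs:
        result.warnings.append(f"no frames found in {path}")
        return result
    records = []
    for png in pngs:
        stem = png.stem
        sidecar_path = path / f"{stem}.json"
        try:
            img = np.asarray(iio.imread(png), dtype=np.float32) / 255.0
        except Exception as exc:  # noqa: BLE001 - error manifest contract
            result.errors.append(f"{png.name}: unreadable image ({exc})")
            continue
        meta = {}
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                meta = json.load(fh)
        for key in ("plane", "qs_true", "frame_index"):
            if key not in meta:
                result.errors.append(f"{stem}: sidecar missing {key!r}")
        masks: Dict[str, np.ndarray] = {}
        mask_dir = path / f"{stem}_masks"
        if mask_dir.is_dir():
            for mp in sorted(mask_dir.glob("*.png")):
                masks[mp.stem] = np.asarray(iio.imread(mp)) > 127
        try:
            frame = PhantomFrame(
                image=img,
                masks=masks,
                qs_true=int(meta.get("qs_true", 1)),
                plane=meta.get("plane", "NonHeart"),
                frame_index=int(meta.get("frame_index",
                                         int(stem.split("_")[1]))),
            )
        except Exception as exc:  # noqa: BLE001
            result.errors.append(f"{stem}: invalid frame ({exc})")
            continue
        records.append(frame)
    records.sort(key=lambda f: f.frame_index)
    result.frames = records
    return result


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------


def write_report(report, path, format: str = "csv",
                 seed: Optional[int] = None,
                 config: Optional[dict] = None) -> None:
    """Write an AccuracyReport (csv/json) or CompletenessReport (json)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(report, AccuracyReport):
        if format == "csv":
            report.per_structure.to_csv(path, index=False)
        elif format == "json":
            payload = {
                "per_structure": report.per_structure.to_dict(
                    orient="records"),
                "per_plane": {
                    plane: (None if v is None else
                            {"mean": v[0], "sd": v[1], "n": v[2]})
                    for plane, v in report.per_plane.items()
                },
                "qs_threshold": report.qs_threshold,
                "n_images": report.n_images,
                "manifest": manifest(seed=seed, config=config),
            }
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
        else:
            raise ValueError(f"unknown format {format!r}")
    elif isinstance(report, CompletenessReport):
        if format != "json":
            raise ValueError("completeness reports are written as JSON")
        payload = report.to_dict()
        payload["manifest"] = manifest(seed=seed, config=config)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    else:
        raise TypeError(f"cannot serialise {type(report).__name__}")


def read_completeness_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# --------------------------------------------------------------------------
# Video scripts from YAML
# --------------------------------------------------------------------------


def script_from_dict(data: dict) -> VideoScript:
    """Build a VideoScript from a YAML/JSON-style mapping.

    Each segment names a plane and a frame count, plus either a constant
    ``degradation`` mapping or a ``sweep`` (clean to heavily degraded).
    """

    specs = default_plane_specs()
    segments = []
    for seg in data["segments"]:
        plane = seg["plane"]
        if plane not in specs:
            raise ValueError(f"unknown plane {plane!r}")
        n = int(seg["n_frames"])
        if "sweep" in seg:
            sw = seg["sweep"] or {}
            sched = degradation_sweep(
                n, max_shadow=float(sw.get("max_shadow", 1.0)),
                max_blur=float(sw.get("max_blur", 3.0)))
            segments.append(Segment(specs[plane], sched, n))
        else:
            deg = DegradationConfig(**(seg.get("degradation") or {}))
            segments.append(Segment(specs[plane], deg, n))
    return VideoScript(segments=tuple(segments),
                       seed=int(data.get("seed", 0)))


def load_script(path) -> VideoScript:
    with open(path) as fh:
        return script_from_dict(yaml.safe_load(fh))
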