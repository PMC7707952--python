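"""File formats: boundary CSVs, feature tables, images, and run manifests.

Boundaries travel as long-format CSV (one row per vertex) with columns
``structure_id, case_id, vertex_index, x, y`` and an optional ``image``
column naming the source image file; feature tables are wide CSV with
``case_id, structure_id[, label]`` followed by the 23 feature columns in
fixed order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .morphometry import FEATURE_NAMES, ImagePatch, NucleusBoundary

BOUNDARY_COLUMNS = ["structure_id", "case_id", "vertex_index", "x", "y"]


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_boundaries(path: str | Path) -> pd.DataFrame:
    """Read a vertex-list CSV; validates columns and sorts vertices in order."""
    df = pd.read_csv(path)
    missing = set(BOUNDARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"boundary CSV missing column(s): {sorted(missing)}")
    return df.sort_values(["case_id", "structure_id", "vertex_index"])


def boundaries_from_frame(df: pd.DataFrame):
    """Yield (case_id, structure_id, image_name | None, vertices array)."""
    for (case_id, structure_id), grp in df.groupby(
        ["case_id", "structure_id"], sort=False
    ):
        image = grp["image"].iloc[0] if "image" in grp.columns else None
        yield case_id, structure_id, image, grp[["x", "y"]].to_numpy(float)


def write_boundary(
    boundary: NucleusBoundary, structure_id: str, case_id: str,
    path: str | Path, image: str | None = None,
) -> None:
    v = boundary.vertices
    df = pd.DataFrame({
        "structure_id": structure_id,
        "case_id": case_id,
        "vertex_index": np.arange(len(v)),
        "x": v[:, 0],
        "y": v[:, 1],
    })
    if image is not None:
        df["image"] = image
    df.to_csv(path, index=False)


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    lead = [c for c in ("case_id", "structure_id", "label", "latent_class")
            if c in df.columns]
    df[lead + list(FEATURE_NAMES)].to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing column(s): {sorted(missing)}")
    return df


def save_render_fixture(
    out_dir: str | Path, name: str,
    patch: ImagePatch, boundary: NucleusBoundary, truth: dict,
    case_id: str = "fixture",
) -> dict[str, Path]:
    """Write a rendered nucleus as PNG + boundary CSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{name}.png",
        "boundary": out / f"{name}_boundary.csv",
        "truth": out / f"{name}_truth.json",
    }
    write_image(patch.pixels, paths["image"])
    write_boundary(boundary, name, case_id, paths["boundary"],
                   image=paths["image"].name)
    paths["truth"].write_text(json.dumps(truth, indent=1, default=list))
    return paths


# -- run manifests -----------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path, config, seeds: dict[str, int],
    outputs: list[str | Path],
) -> Path:
    """Record config snapshot, seeds, and output digests for reproducibility."""
    from . import __version__

    out = Path(out_dir)
    if dataclasses.is_dataclass(config):
        cfg = dataclasses.asdict(config)
    else:
        cfg = dict(config) if config is not None else {}
    manifest = {
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": cfg,
        "seeds": seeds,
        "outputs": {
            str(Path(p).name): _sha256(Path(p)) for p in outputs
        },
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every listed output; True iff all digests match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(
        (out / name).exists() and _sha256(out / name) == digest
        for name, digest in manifest["outputs"].items()
    )
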