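"""Shared readers/writers, run configuration and result manifests.

Conventions: all CSV coordinates are 0-based pixel-centre coordinates,
x rightward, y downward; arclength coordinates start at 0 at the
flagellum base.  Images travel as grayscale TIFF (8/16-bit integer or
32-bit float); tables as CSV with a header row and strict schemas.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "read_image",
    "write_image",
    "read_table",
    "write_table",
    "SCHEMAS",
    "RunConfig",
    "ResultManifest",
]

#: Column schemas (name -> pandas dtype) for every table the CLI consumes
#: or emits.
SCHEMAS = {
    "trace": {"cell_id": str, "point_index": int, "x_px": float, "y_px": float},
    "centroids": {"cell_id": str, "x_px": float, "y_px": float},
    "doublet_centres": {"image_id": str, "doublet_index": int,
                        "x_px": float, "y_px": float},
    "waveforms": {"cell_id": str, "frame": int, "point_index": int,
                  "x_um": float, "y_um": float},
    "tracks": {"track_id": str, "t_s": float, "x_um": float, "y_um": float},
    "manifest_groups": {"image_id": str, "group": str, "region": str},
    "beat_labels": {"cell_id": str, "label": str},
}


def read_image(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF as float64 with provenance metadata.

    Multi-channel / RGB input is rejected: extract the channel of interest
    first (e.g. ``tifffile`` page selection).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-channel 2-D image, got shape "
            f"{data.shape}; extract one channel before loading"
        )
    meta = {"path": str(path), "dtype": str(data.dtype), "inverted": False}
    return data.astype(float), meta


def write_image(path: str | Path, image: np.ndarray, as_float: bool = False) -> None:
    """Write a grayscale TIFF: 16-bit for raw integer data, 32-bit float
    for templates/averages."""
    image = np.asarray(image)
    if as_float or np.issubdtype(image.dtype, np.floating):
        tifffile.imwrite(path, image.astype(np.float32))
    else:
        tifffile.imwrite(path, image.astype(np.uint16))


def read_table(path: str | Path, schema: str | dict) -> pd.DataFrame:
    """Read a CSV with strict schema validation.

    ``schema`` is a schema name from :data:`SCHEMAS` or a column->dtype
    mapping.  Missing or extra columns raise with the exact difference.
    """
    spec = SCHEMAS[schema] if isinstance(schema, str) else schema
    df = pd.read_csv(path)
    missing = set(spec) - set(df.columns)
    extra = set(df.columns) - set(spec)
    if missing or extra:
        raise ValueError(
            f"{Path(path).name}: schema mismatch — missing columns "
            f"{sorted(missing)}, unexpected columns {sorted(extra)}"
        )
    return df.astype(spec)[list(spec)]


def write_table(path: str | Path, df: pd.DataFrame, schema: str | dict | None = None) -> None:
    """Write a CSV; when a schema is given, validate and order columns first."""
    if schema is not None:
        spec = SCHEMAS[schema] if isinstance(schema, str) else schema
        missing = set(spec) - set(df.columns)
        extra = set(df.columns) - set(spec)
        if missing or extra:
            raise ValueError(
                f"schema mismatch on write — missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        df = df[list(spec)]
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Declarative configuration driving all pipelines.

    Each block holds the tunable parameters of one pipeline; every
    threshold is echoed into output metadata so results are traceable to
    the exact gates that produced them.  Unknown keys are rejected.
    """

    profile: dict = field(default_factory=lambda: {
        "linewidth": 3, "n_points": 100, "background": None})
    onset: dict = field(default_factory=lambda: {
        "r_max": 40.0, "dr": 0.5, "pixel_size": 0.1,
        "slope_min": 0.7, "max_min": 1000.0, "r2_min": 0.95})
    beat: dict = field(default_factory=lambda: {
        "n_points": 50, "smooth_s": 0.0, "smooth_t": 0.0,
        "cv_max": 0.05, "r2_min": 0.5})
    emavg: dict = field(default_factory=lambda: {
        "alpha": 0.05, "correction": "bonferroni", "mask_factor": 1.4,
        "rotation": True})
    motility: dict = field(default_factory=lambda: {"min_duration_s": 0.0})
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in raw.items():
            default = getattr(cfg, key)
            if isinstance(default, dict):
                bad = set(value) - set(default)
                if bad:
                    raise ValueError(f"unknown keys in '{key}' block: {sorted(bad)}")
                default.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_metadata(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


@dataclass
class ResultManifest:
    """Record of one CLI run: inputs (with checksums), parameters, outputs."""

    command: str
    parameters: dict
    inputs: list[dict] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    package_version: str = ""

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.inputs.append({"path": str(path), "sha256": _sha256(path)})

    def write(self, path: str | Path) -> None:
        from . import __version__

        self.package_version = __version__
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
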