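"""TIFF/CSV/JSON input-output and run configuration.

Volumes travel as multi-page TIFF stacks with a JSON sidecar declaring
voxel pitch and channel labels; measurement tables are CSV with a fixed
column order so reruns at the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DEFAULT_PITCH_XY, DEFAULT_PITCH_Z, ImageVolume

logger = logging.getLogger("ktquant")

#: Fixed float formatting for table output, keeping reruns byte-identical.
FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Pipeline configuration with the analysis defaults.

    Every physical default is either a printed constant of the protocol
    (size filter 245 nm = 1.75 px, 2 µm phase threshold, 5 projection
    slices, 8x/4x upscales, 75% contour, 100 Monte Carlo refits, 300 nm z
    step) or a repository choice recorded in the provenance output.
    """

    pitch_xy: float = DEFAULT_PITCH_XY
    pitch_z: float = DEFAULT_PITCH_Z
    divisor: int = 1000
    sd_max_nm: float = 245.0
    phase_threshold_um: float = 2.0
    n_proj_slices: int = 5
    upscale: int = 8
    contour_extra_upscale: int = 4
    contour_fraction: float = 0.75
    n_mc: int = 100
    n_kinetochores: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pitch_xy", "pitch_z", "sd_max_nm", "phase_threshold_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.divisor not in (1000, 10000):
            raise ValueError("divisor must be 1000 or 10000")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus a JSON pitch sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.voxels.astype(np.float32), photometric="minisblack")
    sidecar = {
        "pitch_xy_nm": volume.pitch_xy,
        "pitch_z_nm": volume.pitch_z,
        "channel": volume.channel,
        "axes": "ZYX",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_volume(path: str | Path, config: RunConfig | None = None) -> ImageVolume:
    """Read a TIFF stack, taking pitches from the sidecar when present.

    Missing sidecar metadata falls back to the configured (or package)
    defaults with a logged warning.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 2D or 3D TIFF, got ndim={data.ndim}")
    config = config or RunConfig()
    pitch_xy, pitch_z, channel = config.pitch_xy, config.pitch_z, "GFP"
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        pitch_xy = float(sidecar.get("pitch_xy_nm", pitch_xy))
        pitch_z = float(sidecar.get("pitch_z_nm", pitch_z))
        channel = sidecar.get("channel", channel)
    else:
        logger.warning(
            "%s: no pitch sidecar; using defaults %g/%g nm", path, pitch_xy, pitch_z
        )
    return ImageVolume(data, pitch_xy=pitch_xy, pitch_z=pitch_z, channel=channel)


def write_table(records: Sequence[dict] | pd.DataFrame, path: str | Path, columns=None) -> None:
    """Write records as CSV with deterministic column order and precision."""
    frame = pd.DataFrame(records) if not isinstance(records, pd.DataFrame) else records
    if columns is not None:
        frame = frame.reindex(columns=list(columns))
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-cell annotation table (cell_id, phase, x, y, z in nm)."""
    frame = pd.read_csv(path)
    required = {"cell_id", "phase"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return frame


def write_provenance(path: str | Path, config: RunConfig, extra: dict | None = None) -> None:
    """Record config, seed and versions alongside every pipeline output."""
    import ktquant

    record = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {"ktquant": ktquant.__version__, "numpy": np.__version__},
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
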