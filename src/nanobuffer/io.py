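"""Table, image-stack and configuration I/O with schema validation.

Conventions: CSV with a header row and unit-suffixed column names
(``time_s``, ``added_acid_mmol``...), decimal point, UTF-8.  TIFF stacks
are 16-bit multi-page, pages ordered channel-major (all Z slices of the
first channel, then the next channel); the channel map and voxel size live
in a YAML sidecar or the run config, never in TIFF private tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import ConfigError, SchemaError
from .imaging import ChannelImage

__all__ = [
    "TABLE_SCHEMAS",
    "read_table",
    "write_table",
    "read_stack",
    "write_stack",
    "load_config",
    "write_provenance",
]

#: Required columns per named table schema.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "titration": ["step", "added_acid_mmol", "volume_ml", "pH"],
    "uptake": ["well_id", "dose_ug_ml", "total_fluorescence", "cell_count"],
    "trajectory": ["time_s", "pH", "fraction_protonated", "protons_pumped"],
    "punctae": ["punta_id", "y", "x", "F1", "B1", "F2", "B2", "R"],
    "calibration_points": ["pH", "R"],
}

_NON_NUMERIC_OK = {"well_id", "flag"}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Raises :class:`SchemaError` naming the first missing column, or the row
    index of the first non-numeric cell in a numeric column.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise ConfigError(
            f"unknown table schema {schema_name!r}; known: {sorted(TABLE_SCHEMAS)}"
        )
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"table not found: {path}")
    df = pd.read_csv(path)
    for col in TABLE_SCHEMAS[schema_name]:
        if col not in df.columns:
            raise SchemaError(f"table {path} is missing required column {col!r}")
    if len(df) < 1:
        raise SchemaError(f"table {path} has no data rows")
    for col in TABLE_SCHEMAS[schema_name]:
        if col in _NON_NUMERIC_OK:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"table {path}, column {col!r}: non-numeric cell at row {row}"
            )
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a table as UTF-8 CSV with a header row."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_stack(
    path: str | Path,
    channel_map: Sequence[str],
    voxel_size: Sequence[float] | None = None,
) -> list[ChannelImage]:
    """Read a multi-page TIFF into per-channel images.

    Pages are grouped channel-major: with C channels and P pages, channel i
    owns pages [i*P/C, (i+1)*P/C).  A page count not divisible by the
    channel count is a layout error.  Single-slice channels come back 2D.
    """
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    n_pages = data.shape[0]
    n_ch = len(channel_map)
    if n_ch == 0:
        raise ConfigError("channel_map must name at least one channel")
    if n_pages % n_ch != 0:
        raise ConfigError(
            f"layout error: {n_pages} pages are not divisible by {n_ch} channels"
        )
    z = n_pages // n_ch
    if voxel_size is None:
        voxel_size = (1.0,) * (2 if z == 1 else 3)
    images = []
    for i, cid in enumerate(channel_map):
        block = data[i * z : (i + 1) * z]
        arr = block[0] if z == 1 else block
        images.append(
            ChannelImage(arr.astype(float), channel_id=cid, voxel_size=tuple(voxel_size))
        )
    return images


def write_stack(path: str | Path, images: Sequence[ChannelImage]) -> None:
    """Write channels to one 16-bit multi-page TIFF, channel-major order."""
    pages = []
    for img in images:
        arr = np.clip(np.round(img.intensities), 0, 65535).astype(np.uint16)
        pages.extend(arr[None] if arr.ndim == 2 else arr)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.stack(pages))


def load_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """Load a YAML run config, rejecting unknown keys by name."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)}; allowed: {sorted(allowed_keys)}"
        )
    return cfg


def write_provenance(path: str | Path, command: str, parameters: dict) -> None:
    """Record the parameters, seed and package version of a run as YAML."""
    record = {
        "command": command,
        "package_version": __version__,
        "parameters": parameters,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(record, fh, sort_keys=True)
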