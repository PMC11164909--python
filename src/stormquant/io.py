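"""Reading and writing localization tables, region masks and run configuration.

The package's universal currency is the *localization table*: one row per
detected blink event of a single emitter, with sub-pixel coordinates in
nanometres.  The canonical on-disk dialect is comma-separated text with a
header row and the columns

    ``x_nm, y_nm, frame, photons, precision_nm, channel, source_flag``

Coordinates are point locations (not pixel indices), origin at the top-left
of the field, y increasing downward.  ``frame`` is the 0-based acquisition
frame index; ``precision_nm`` is the per-localization lateral precision.
``photons`` defaults to 1.0 and ``precision_nm`` to 0.0 when the source file
does not carry them; ``channel`` defaults to ``"ch0"`` and ``source_flag``
(one of ``sample``/``fiducial``/``unknown``) to ``"unknown"``.

Common SMLM export headers (ThunderSTORM-style ``x [nm]``,
``uncertainty_xy [nm]`` and friends) are recognised through a synonym table;
arbitrary dialects are described with :class:`Dialect` (column renames plus
unit multipliers).  Unknown columns are carried through untouched.

Masks are binary rasters with a physical pixel size and an origin offset in
nm.  Point-in-mask queries use ``floor((coord - origin)/pixel_size)`` with
0-based, half-open pixel bins: the point (105, 95) nm on a 10 nm/px grid
falls in pixel column 10, row 9.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger(__name__)

#: canonical column order of the localization-table dialect
COLUMNS = ["x_nm", "y_nm", "frame", "photons", "precision_nm", "channel", "source_flag"]

REQUIRED_COLUMNS = ["x_nm", "y_nm", "frame"]

COLUMN_DEFAULTS = {
    "photons": 1.0,
    "precision_nm": 0.0,
    "channel": "ch0",
    "source_flag": "unknown",
}

#: lower-cased header synonyms for common SMLM exports
SYNONYMS: dict[str, tuple[str, ...]] = {
    "x_nm": ("x_nm", "x [nm]", "x(nm)", "xnm", "x"),
    "y_nm": ("y_nm", "y [nm]", "y(nm)", "ynm", "y"),
    "frame": ("frame", "frame_idx", "t"),
    "photons": ("photons", "intensity [photon]", "intensity", "n_photons"),
    "precision_nm": (
        "precision_nm",
        "uncertainty_xy",
        "uncertainty_xy [nm]",
        "uncertainty [nm]",
        "precision",
        "loc_precision",
    ),
    "channel": ("channel", "ch"),
    "source_flag": ("source_flag",),
}


@dataclass
class Dialect:
    """Description of a foreign localization-table layout.

    Parameters
    ----------
    columns
        Mapping from canonical names (``x_nm`` ...) to the source file's
        column names.  Canonical columns not listed fall back to the synonym
        table.
    multipliers
        Unit multipliers applied after renaming, keyed by canonical name —
        e.g. ``{"x_nm": 1000.0}`` for a file with x in micrometres.
    sep
        Field separator of the file.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    multipliers: Mapping[str, float] = field(default_factory=dict)
    sep: str = ","


def new_table(
    x_nm: np.ndarray,
    y_nm: np.ndarray,
    frame: np.ndarray,
    photons: np.ndarray | float = 1.0,
    precision_nm: np.ndarray | float = 0.0,
    channel: np.ndarray | str = "ch0",
    source_flag: np.ndarray | str = "sample",
    **extra: np.ndarray,
) -> pd.DataFrame:
    """Assemble a canonical localization table from per-row arrays."""
    n = len(np.atleast_1d(x_nm))
    data = {
        "x_nm": np.asarray(x_nm, dtype=float),
        "y_nm": np.asarray(y_nm, dtype=float),
        "frame": np.asarray(frame, dtype=np.int64),
        "photons": np.broadcast_to(np.asarray(photons, dtype=float), (n,)).copy(),
        "precision_nm": np.broadcast_to(np.asarray(precision_nm, dtype=float), (n,)).copy(),
        "channel": np.broadcast_to(np.asarray(channel, dtype=object), (n,)).copy(),
        "source_flag": np.broadcast_to(np.asarray(source_flag, dtype=object), (n,)).copy(),
    }
    data.update({k: np.asarray(v) for k, v in extra.items()})
    table = pd.DataFrame(data)
    validate_table(table)
    return table


def validate_table(table: pd.DataFrame) -> None:
    """Check the invariants of a canonical table; raise ``ValueError`` on breach."""
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"localization table is missing required column {col!r}")
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(xy)):
        bad = int(np.flatnonzero(~np.isfinite(xy).all(axis=1))[0])
        raise ValueError(f"non-finite coordinate at row {bad}")
    if (table["frame"] < 0).any():
        raise ValueError("negative frame index")
    if "precision_nm" in table.columns and (table["precision_nm"] < 0).any():
        raise ValueError("negative localization precision")


def read_localizations(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read a delimited-text localization table into the canonical dialect.

    Missing required columns raise ``ValueError`` naming the column;
    a non-numeric cell raises ``ValueError`` with its (0-based, data) row
    number.  Unknown columns are preserved as opaque extras.
    """
    dialect = dialect or Dialect()
    raw = pd.read_csv(path, sep=dialect.sep)
    rename: dict[str, str] = {}
    lower = {str(c).strip().lower(): c for c in raw.columns}
    for canonical in COLUMNS:
        if canonical in dialect.columns:
            src = dialect.columns[canonical]
            if src not in raw.columns:
                raise ValueError(
                    f"column {src!r} (for {canonical!r}) not found in {path}"
                )
            rename[src] = canonical
            continue
        for syn in SYNONYMS[canonical]:
            if syn in lower:
                rename[lower[syn]] = canonical
                break
    table = raw.rename(columns=rename)
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(
                f"localization file {path} is missing required column {col!r}"
            )
    for col, default in COLUMN_DEFAULTS.items():
        if col not in table.columns:
            table[col] = default
    for col in ("x_nm", "y_nm", "frame", "photons", "precision_nm"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        table[col] = coerced
    for col, mult in dialect.multipliers.items():
        table[col] = table[col] * mult
    table["frame"] = table["frame"].astype(np.int64)
    extras = [c for c in table.columns if c not in COLUMNS]
    table = table[COLUMNS + extras]
    validate_table(table)
    return table


def write_localizations(table: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical localization table as comma-separated text."""
    validate_table(table)
    cols = [c for c in COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in COLUMNS]
    table[cols].to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# masks


@dataclass
class Mask:
    """Binary region raster with physical pixel size and origin offset.

    ``data[row, col]`` covers the half-open physical rectangle
    ``[origin + (col, row)*px, origin + (col+1, row+1)*px)`` with
    ``(x, y) = (col, row)`` ordering.
    """

    data: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    label: str = "cell"

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask raster must be 2-D")

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def require_nonempty(self) -> "Mask":
        if self.n_foreground == 0:
            raise ValueError(f"empty region: mask {self.label!r} has no foreground pixels")
        return self

    def area_nm2(self) -> float:
        return self.n_foreground * self.pixel_size_nm**2

    def pixel_of(self, x_nm, y_nm) -> tuple[np.ndarray, np.ndarray]:
        """(col, row) pixel indices under the floor / half-open convention."""
        col = np.floor((np.asarray(x_nm, dtype=float) - self.origin_nm[0]) / self.pixel_size_nm)
        row = np.floor((np.asarray(y_nm, dtype=float) - self.origin_nm[1]) / self.pixel_size_nm)
        return col.astype(np.int64), row.astype(np.int64)

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Vectorized point-in-mask test; points off the raster are outside."""
        col, row = self.pixel_of(x_nm, y_nm)
        h, w = self.data.shape
        inside = (col >= 0) & (col < w) & (row >= 0) & (row < h)
        out = np.zeros_like(inside, dtype=bool)
        out[inside] = self.data[row[inside], col[inside]]
        return out


def write_mask(mask: Mask, path: str | Path) -> None:
    """Write a mask as a single-channel 0/255 raster (TIFF or PNG by suffix)."""
    img = (mask.data.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(
    path: str | Path,
    pixel_size_nm: float,
    origin_nm: tuple[float, float] = (0.0, 0.0),
    label: str = "cell",
) -> Mask:
    """Read a single-channel raster as a binary mask (nonzero = foreground)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(
            f"mask {path} has {img.ndim} dimensions; expected a single-channel raster"
        )
    return Mask(img != 0, pixel_size_nm, origin_nm, label)


# ---------------------------------------------------------------------------
# run configuration

#: defaults for the end-to-end pipeline configuration file
CONFIG_DEFAULTS: dict = {
    "seed": 0,
    "n_cells_per_arm": 5,
    "arms": {"quiescent": {}, "activated": {}},
    "detection": {},
    "drift_window": 200,
    "metrics": ["mean_fwhm_nm", "mean_locs_per_domain"],
    "mask_pixel_size_nm": 50.0,
    "render_pixel_size_nm": 10.0,
    "cells": None,  # optional list of real-data cell inputs (paths)
}

_RANGE_CHECKS = {
    "n_cells_per_arm": lambda v: v >= 1,
    "drift_window": lambda v: v >= 1,
    "mask_pixel_size_nm": lambda v: v > 0,
    "render_pixel_size_nm": lambda v: v > 0,
}


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> dict:
    """Load a YAML run configuration, fill defaults and validate ranges.

    Unknown top-level keys produce a warning; out-of-range values raise.
    Every effective parameter is echoed to the module logger.
    """
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in CONFIG_DEFAULTS.items()}
    loaded: Mapping = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
    merged = dict(loaded)
    if overrides:
        merged.update(overrides)
    for key, value in merged.items():
        if key not in cfg:
            warnings.warn(f"unknown configuration key {key!r} ignored", stacklevel=2)
            continue
        if isinstance(cfg[key], dict) and isinstance(value, Mapping):
            cfg[key].update(value)
        else:
            cfg[key] = value
    for key, check in _RANGE_CHECKS.items():
        if not check(cfg[key]):
            raise ValueError(f"configuration value out of range: {key}={cfg[key]!r}")
    for key, value in cfg.items():
        logger.info("config %s = %r", key, value)
    return cfg


def dump_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
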