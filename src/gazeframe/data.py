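"""Data model for fixation tables and 2-D salience/density maps.

Coordinate convention: ``x`` is the column coordinate, ``y`` the row
coordinate, origin at the top-left corner of the screen, 0-based, with
half-open pixel intervals ``[0, W) x [0, H)``.  Angular distances are
converted to pixels with per-axis linear (small-angle) factors.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import EmptyDatasetError, FormatError, GeometryError

logger = logging.getLogger(__name__)

FIXATION_COLUMNS = ["subject", "image", "category", "trial_index", "x", "y"]


@dataclass(frozen=True)
class DisplayGeometry:
    """Screen resolution in pixels and stimulus extent in degrees.

    Parameters
    ----------
    width_px, height_px : int
        Screen resolution.
    width_deg, height_deg : float
        Stimulus extent in degrees of visual angle.
    """

    width_px: int
    height_px: int
    width_deg: float
    height_deg: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise GeometryError("pixel dimensions must be >= 1")
        if not (self.width_deg > 0 and self.height_deg > 0):
            raise GeometryError("angular extent must be > 0")
        if not (math.isfinite(self.width_deg) and math.isfinite(self.height_deg)):
            raise GeometryError("angular extent must be finite")

    @property
    def px_per_deg_x(self) -> float:
        return self.width_px / self.width_deg

    @property
    def px_per_deg_y(self) -> float:
        return self.height_px / self.height_deg

    def deg_to_px(self, d: float, axis: str = "x") -> float:
        """Convert an angular distance to pixels along one axis.

        Uses the linear small-angle conversion ``d * px_per_deg``; no
        tangent correction is applied because only a single global
        stimulus extent is known.
        """
        if d < 0:
            raise ValueError("angular distance must be >= 0")
        if axis == "x":
            return d * self.px_per_deg_x
        if axis == "y":
            return d * self.px_per_deg_y
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    @classmethod
    def from_mapping(cls, m: Mapping) -> "DisplayGeometry":
        try:
            return cls(int(m["width_px"]), int(m["height_px"]),
                       float(m["width_deg"]), float(m["height_deg"]))
        except KeyError as exc:  # pragma: no cover - trivial
            raise FormatError(f"geometry mapping missing key {exc}") from exc


#: The display used throughout the documentation examples: a 1280x960
#: screen subtending about 28.4 x 21.3 degrees of visual angle.
DEFAULT_GEOMETRY = DisplayGeometry(1280, 960, 28.4, 21.3)


def deg_to_px(geometry: DisplayGeometry, d: float, axis: str = "x") -> float:
    """Module-level alias for :meth:`DisplayGeometry.deg_to_px`."""
    return geometry.deg_to_px(d, axis)


class FixationDataset:
    """A validated, tidy table of fixations plus display geometry.

    One row per fixation with columns ``subject, image, category,
    trial_index, x, y``.  Invariants enforced at construction: all
    coordinates inside ``[0, W) x [0, H)``, each image belongs to exactly
    one category, and each (subject, image) trial holds at most
    ``max_fixations`` records (earliest ``trial_index`` kept).
    """

    def __init__(self, records: pd.DataFrame, geometry: DisplayGeometry,
                 max_fixations: int = 15, policy: str = "drop-record"):
        if policy not in ("drop-record", "reject-file"):
            raise ValueError(f"unknown out-of-bounds policy {policy!r}")
        df = records.copy()
        missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        df = df.loc[:, FIXATION_COLUMNS]
        for col in ("x", "y"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        df["trial_index"] = df["trial_index"].astype(int)
        if (df["trial_index"] < 1).any():
            raise FormatError("trial_index must be >= 1")

        in_bounds = ((df["x"] >= 0) & (df["x"] < geometry.width_px)
                     & (df["y"] >= 0) & (df["y"] < geometry.height_px)
                     & np.isfinite(df["x"]) & np.isfinite(df["y"]))
        n_bad = int((~in_bounds).sum())
        if n_bad:
            if policy == "reject-file":
                raise FormatError(f"{n_bad} fixation(s) outside the screen")
            warnings.warn(f"dropped {n_bad} out-of-bounds fixation(s)",
                          stacklevel=2)
            logger.info("dropped %d out-of-bounds fixation(s)", n_bad)
            df = df.loc[in_bounds]

        cats = df.groupby("image")["category"].nunique()
        if (cats > 1).any():
            bad = list(cats.index[cats > 1])
            raise FormatError(f"images with more than one category: {bad}")

        if max_fixations is not None:
            df = (df.sort_values(["subject", "image", "trial_index"],
                                 kind="mergesort")
                    .groupby(["subject", "image"], sort=False)
                    .head(max_fixations))
        df = df.sort_values(["subject", "image", "trial_index"],
                            kind="mergesort").reset_index(drop=True)
        self.records = df
        self.geometry = geometry
        self.n_dropped = n_bad if policy == "drop-record" else 0

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list:
        return sorted(self.records["subject"].unique().tolist())

    @property
    def images(self) -> list:
        return sorted(self.records["image"].unique().tolist())

    @property
    def categories(self) -> list:
        return sorted(self.records["category"].unique().tolist())

    def category_of(self, image) -> str:
        sub = self.records.loc[self.records["image"] == image, "category"]
        if sub.empty:
            raise KeyError(f"unknown image {image!r}")
        return sub.iloc[0]

    def select(self, subjects: Iterable | None = None,
               images: Iterable | None = None,
               category: str | None = None) -> "FixationDataset":
        """Subset by subjects, images and/or category (no re-validation)."""
        df = self.records
        if category is not None:
            df = df[df["category"] == category]
        if subjects is not None:
            df = df[df["subject"].isin(list(subjects))]
        if images is not None:
            df = df[df["image"].isin(list(images))]
        out = object.__new__(FixationDataset)
        out.records = df.reset_index(drop=True)
        out.geometry = self.geometry
        out.n_dropped = 0
        return out

    def xy(self) -> np.ndarray:
        """Fixation positions as an (n, 2) float array of (x, y)."""
        return self.records[["x", "y"]].to_numpy(float)


def read_fixations(path, geometry: DisplayGeometry,
                   policy: str = "drop-record",
                   max_fixations: int = 15) -> FixationDataset:
    """Read a delimited fixation table (CSV or TSV, sniffed by header).

    Raises :class:`FormatError` for missing columns or non-numeric
    coordinates and :class:`EmptyDatasetError` for a file without rows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise EmptyDatasetError(f"{path} is empty") from exc
    except ValueError as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(df) == 0:
        raise EmptyDatasetError(f"{path} contains a header but no records")
    try:
        return FixationDataset(df, geometry, max_fixations=max_fixations,
                               policy=policy)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"invalid value in {path}: {exc}") from exc


def write_fixations(dataset: FixationDataset, path) -> None:
    """Write a fixation table as UTF-8 CSV in deterministic row order."""
    df = dataset.records.sort_values(["subject", "image", "trial_index"],
                                     kind="mergesort")
    df.to_csv(path, index=False, encoding="utf-8")


@dataclass
class SalienceMap:
    """A 2-D grid of real values covering the screen.

    ``scale`` is the number of grid cells per screen pixel (<= 1); a
    1280x960 screen at scale 1/4 is represented by a 240x320 grid.
    """

    values: np.ndarray
    geometry: DisplayGeometry
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("map values must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("map values must be finite")
        rows, cols = self.values.shape
        exp_rows = self.geometry.height_px * self.scale
        exp_cols = self.geometry.width_px * self.scale
        if abs(rows - exp_rows) > 0.5 or abs(cols - exp_cols) > 0.5:
            raise GeometryError(
                f"shape {self.values.shape} inconsistent with geometry "
                f"{self.geometry.height_px}x{self.geometry.width_px} "
                f"at scale {self.scale}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Grid cell (row, col) containing screen positions (x, y)."""
        rows, cols = self.values.shape
        col = np.clip((np.asarray(x, float) * cols
                       // self.geometry.width_px).astype(int), 0, cols - 1)
        row = np.clip((np.asarray(y, float) * rows
                       // self.geometry.height_px).astype(int), 0, rows - 1)
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        """Salience value at screen positions — nearest-cell lookup."""
        row, col = self.cell_of(x, y)
        return self.values[row, col]


class DensityMap(SalienceMap):
    """A :class:`SalienceMap` that is a probability mass function.

    All values non-negative and summing to one within 1e-9.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise GeometryError("density values must be >= 0")
        total = float(self.values.sum())
        if abs(total - 1.0) > 1e-9:
            raise GeometryError(f"density must sum to 1, got {total}")

    @classmethod
    def from_values(cls, values, geometry: DisplayGeometry,
                    scale: float = 1.0) -> "DensityMap":
        """Normalize a non-negative grid to unit mass."""
        values = np.asarray(values, dtype=float)
        total = values.sum()
        if not total > 0:
            raise GeometryError("cannot normalize a map with zero mass")
        return cls(values / total, geometry, scale)


def read_map(path, geometry: DisplayGeometry) -> SalienceMap:
    """Read a salience map from a text matrix or a grayscale raster.

    Plain-text matrices are whitespace-delimited rows; rasters (PGM, PNG,
    TIFF, ...) are read as 8/16-bit grayscale intensities.  The grid
    scale is inferred from the shape, which must divide the screen shape
    by a common integer factor.
    """
    path = Path(path)
    if path.suffix.lower() in (".txt", ".dat", ".map", ""):
        try:
            values = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise FormatError(f"ragged or non-numeric matrix in {path}: {exc}") from exc
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse an RGB(A) raster that is in fact gray
            if not np.all(arr[..., :3] == arr[..., :1]):
                raise FormatError(f"{path} is not a grayscale raster")
            arr = arr[..., 0]
        values = arr.astype(float)
    rows, cols = values.shape
    if geometry.height_px % rows or geometry.width_px % cols:
        raise GeometryError(
            f"map shape {values.shape} does not divide screen "
            f"{geometry.height_px}x{geometry.width_px}")
    fy = geometry.height_px // rows
    fx = geometry.width_px // cols
    if fy != fx:
        raise GeometryError(f"anisotropic downscale factors {fy} vs {fx}")
    return SalienceMap(values, geometry, scale=1.0 / fx)


def write_map(map_: SalienceMap, path) -> None:
    """Write a map as a whitespace-delimited text matrix."""
    np.savetxt(path, map_.values)


def grid_shape(geometry: DisplayGeometry, scale: float) -> tuple[int, int]:
    """(rows, cols) of the grid covering the screen at ``scale``."""
    rows = round(geometry.height_px * scale)
    cols = round(geometry.width_px * scale)
    if rows < 1 or cols < 1:
        raise GeometryError(f"scale {scale} collapses the grid")
    return rows, cols
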