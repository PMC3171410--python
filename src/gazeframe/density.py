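"""Fixation density map (FDM) estimation and pooling.

An FDM is the smoothed, unit-mass 2-D histogram of fixation positions:
an empirical estimate of the probability that each location is fixated.
Smoothing uses a Gaussian kernel specified by its full width at half
maximum (FWHM) in degrees of visual angle, 2 degrees by default, which
matches the eye-tracker calibration error and the size of the fovea.
The kernel is truncated at the screen border and the map renormalized
afterwards, so interior values are unaffected by border correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import DensityMap, DisplayGeometry, FixationDataset, grid_shape
from .exceptions import EmptyDatasetError, GeometryError

#: sigma = FWHM / (2 sqrt(2 ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SmoothingSpec:
    """Gaussian smoothing kernel given by its FWHM in degrees."""

    fwhm_deg: float = 2.0
    kernel: str = "gaussian"

    def __post_init__(self) -> None:
        if not self.fwhm_deg > 0:
            raise ValueError("fwhm_deg must be > 0")
        if self.kernel != "gaussian":
            raise ValueError(f"unsupported kernel {self.kernel!r}")

    def sigma_cells(self, geometry: DisplayGeometry,
                    scale: float) -> tuple[float, float]:
        """Kernel sigma in grid cells, (row axis, column axis).

        Pixels per degree differ slightly between axes, so sigma is kept
        per-axis rather than averaged.
        """
        sx = geometry.deg_to_px(self.fwhm_deg, "x") * scale * FWHM_TO_SIGMA
        sy = geometry.deg_to_px(self.fwhm_deg, "y") * scale * FWHM_TO_SIGMA
        return sy, sx


def histogram2d(fixations: FixationDataset,
                grid: tuple[int, int]) -> np.ndarray:
    """2-D fixation count histogram on equal half-open cells.

    Bin edges partition ``[0, W) x [0, H)``; the total count equals the
    number of fixations.  An empty selection yields an all-zero grid.
    """
    rows, cols = grid
    if rows < 1 or cols < 1:
        raise GeometryError("grid dimensions must be >= 1")
    geom = fixations.geometry
    xy = fixations.xy()
    counts = np.zeros((rows, cols), dtype=np.int64)
    if len(xy) == 0:
        return counts
    col = np.clip((xy[:, 0] * cols // geom.width_px).astype(int), 0, cols - 1)
    row = np.clip((xy[:, 1] * rows // geom.height_px).astype(int), 0, rows - 1)
    np.add.at(counts, (row, col), 1)
    return counts


def smooth_counts(counts: np.ndarray, geometry: DisplayGeometry,
                  smoothing: SmoothingSpec, scale: float) -> DensityMap:
    """Smooth a count grid with the angular kernel and normalize."""
    total = counts.sum()
    if not total > 0:
        raise EmptyDatasetError("an FDM of zero fixations is undefined")
    sigma = smoothing.sigma_cells(geometry, scale)
    smoothed = ndimage.gaussian_filter(counts.astype(float), sigma=sigma,
                                       mode="constant", cval=0.0)
    return DensityMap.from_values(smoothed, geometry, scale)


def fdm(fixations: FixationDataset,
        smoothing: SmoothingSpec = SmoothingSpec(),
        scale: float = 1.0) -> DensityMap:
    """Fixation density map of a dataset (or of a selection of one).

    Histograms fixations on the grid at ``scale``, smooths with the
    angular Gaussian kernel (rescaled to the grid) and normalizes to
    unit mass.

    Raises
    ------
    EmptyDatasetError
        If the selection contains no fixations.
    """
    if len(fixations) == 0:
        raise EmptyDatasetError("an FDM of zero fixations is undefined")
    grid = grid_shape(fixations.geometry, scale)
    counts = histogram2d(fixations, grid)
    return smooth_counts(counts, fixations.geometry, smoothing, scale)


def downsample(map_: DensityMap, factor: int) -> DensityMap:
    """Aggregate a density map by block sum; unit mass is preserved.

    ``factor`` must divide both grid dimensions exactly.
    """
    if factor < 1 or int(factor) != factor:
        raise GeometryError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return map_
    rows, cols = map_.values.shape
    if rows % factor or cols % factor:
        raise GeometryError(
            f"factor {factor} does not divide grid {rows}x{cols}")
    blocks = map_.values.reshape(rows // factor, factor,
                                 cols // factor, factor).sum(axis=(1, 3))
    return DensityMap(blocks, map_.geometry, map_.scale / factor)


def spatial_bias(dataset: FixationDataset,
                 subjects=None, images=None,
                 smoothing: SmoothingSpec = SmoothingSpec(),
                 scale: float = 1.0,
                 category: str | None = None) -> DensityMap:
    """FDM pooled over the selected subjects and images.

    With all data selected this is the image- and subject-independent
    distribution of fixation locations (the spatial / central bias).
    """
    sel = dataset.select(subjects=subjects, images=images, category=category)
    if len(sel) == 0:
        raise EmptyDatasetError("empty subject/image selection")
    return fdm(sel, smoothing=smoothing, scale=scale)


def coarse_grid(geometry: DisplayGeometry) -> tuple[int, int]:
    """Grid whose cell area matches a 2-degree-diameter disc.

    Used for entropy/KL work, where fine grids make small-sample bias
    unmanageable.  On a 1280x960 screen spanning 28.4 x 21.3 degrees
    this yields 12 x 16 bins (N = 192).
    """
    disc_area = np.pi * geometry.deg_to_px(1.0, "x") * geometry.deg_to_px(1.0, "y")
    side = np.sqrt(disc_area)
    rows = max(1, round(geometry.height_px / side))
    cols = max(1, round(geometry.width_px / side))
    return rows, cols
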