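"""Synthetic multi-subject, multi-image fixation datasets.

The generator emulates the structure of a free-viewing eye-tracking
study: each fixation is drawn from a three-component mixture of

* a category-dependent central bias (a 2-D Gaussian around the screen
  center, tighter for "naturals" than for "urbans"),
* image-specific hotspots shared across subjects (a small number of
  tight Gaussians per image, placed once per image), and
* a subject-specific spatial bias (a Gaussian displaced from the screen
  center by a per-subject offset that is a linear combination of a few
  fixed component fields — the planted subject idiosyncrasy).

Samples falling outside the screen are rejected and redrawn, so every
component density is a properly truncated, renormalized distribution.
Each consumer (image layout, subject weights, per-trial fixations)
derives its own random stream from the root seed, so changing the
number of subjects does not reshuffle the image layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DEFAULT_GEOMETRY, DensityMap, DisplayGeometry, \
    FixationDataset, grid_shape
from .exceptions import ConfigError

__all__ = ["CategorySpec", "SyntheticConfig", "SyntheticTruth",
           "make_dataset", "ground_truth_density"]


@dataclass(frozen=True)
class CategorySpec:
    """Central-bias shape of one stimulus category.

    ``center`` in screen fractions, ``sd_deg`` per axis (x, y) in
    degrees of visual angle.
    """

    name: str
    center: tuple[float, float] = (0.5, 0.5)
    sd_deg: tuple[float, float] = (5.0, 4.0)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror a scaled-down free-viewing study: 15 fixations per
    6-second trial on a 1280x960 screen spanning 28.4 x 21.3 degrees,
    with a tighter central bias on natural than on urban scenes.
    ``mixture_weights`` are (central, hotspot, subject) and must sum to
    one.
    """

    n_subjects: int = 12
    n_images: int = 16
    fixations_per_trial: int = 15
    categories: tuple[CategorySpec, ...] = (
        CategorySpec("naturals", sd_deg=(5.0, 4.0)),
        CategorySpec("urbans", sd_deg=(7.5, 6.0)),
    )
    hotspots_per_image: int = 2
    hotspot_sd_deg: float = 1.5
    subject_sd_deg: float = 4.0
    mixture_weights: tuple[float, float, float] = (0.35, 0.45, 0.20)
    n_subject_components: int = 2
    subject_weight_sd: float = 1.5
    geometry: DisplayGeometry = DEFAULT_GEOMETRY
    seed: int = 0

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, float)
        if w.size != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("mixture_weights must be 3 nonnegative "
                              "values summing to 1")
        for name, v in [("hotspot_sd_deg", self.hotspot_sd_deg),
                        ("subject_sd_deg", self.subject_sd_deg),
                        ("subject_weight_sd", self.subject_weight_sd)]:
            if not v > 0:
                raise ConfigError(f"{name} must be > 0")
        for cat in self.categories:
            if not (cat.sd_deg[0] > 0 and cat.sd_deg[1] > 0):
                raise ConfigError(f"category {cat.name}: sd_deg must be > 0")
        for name, v in [("n_subjects", self.n_subjects),
                        ("n_images", self.n_images),
                        ("fixations_per_trial", self.fixations_per_trial),
                        ("hotspots_per_image", self.hotspots_per_image),
                        ("n_subject_components", self.n_subject_components)]:
            if v < 1:
                raise ConfigError(f"{name} must be >= 1")


def _component_fields(k: int) -> np.ndarray:
    """Fixed unit direction vectors (in degrees) of the subject fields."""
    angles = np.pi * np.arange(k) / k
    return np.column_stack([np.cos(angles), np.sin(angles)])


@dataclass
class SyntheticTruth:
    """Ground-truth bundle: layouts, offsets and exact mixture densities."""

    config: SyntheticConfig
    image_ids: list
    image_category: dict
    hotspot_centers_px: dict        # image id -> (hotspots, 2) array of (x, y)
    subject_ids: list
    subject_offsets_px: dict        # subject id -> (dx, dy)
    subject_weights: dict           # subject id -> component weights (deg)
    component_fields: np.ndarray = field(repr=False, default=None)

    # -- densities ---------------------------------------------------------

    def _grid_centers(self, shape):
        geom = self.config.geometry
        rows, cols = shape
        cx = (np.arange(cols) + 0.5) * geom.width_px / cols
        cy = (np.arange(rows) + 0.5) * geom.height_px / rows
        return cx, cy

    def _gauss(self, shape, center_px, sd_px) -> np.ndarray:
        """Truncated (grid-renormalized) separable Gaussian, unit mass."""
        cx, cy = self._grid_centers(shape)
        gx = np.exp(-0.5 * ((cx - center_px[0]) / sd_px[0]) ** 2)
        gy = np.exp(-0.5 * ((cy - center_px[1]) / sd_px[1]) ** 2)
        g = gy[:, None] * gx[None, :]
        return g / g.sum()

    def _sd_px(self, sd_deg_xy) -> tuple[float, float]:
        geom = self.config.geometry
        return (geom.deg_to_px(sd_deg_xy[0], "x"),
                geom.deg_to_px(sd_deg_xy[1], "y"))

    def central_density(self, category: str, shape) -> np.ndarray:
        geom = self.config.geometry
        spec = next(c for c in self.config.categories if c.name == category)
        center = (spec.center[0] * geom.width_px,
                  spec.center[1] * geom.height_px)
        return self._gauss(shape, center, self._sd_px(spec.sd_deg))

    def hotspot_density(self, image, shape) -> np.ndarray:
        sd = self._sd_px((self.config.hotspot_sd_deg,
                          self.config.hotspot_sd_deg))
        centers = self.hotspot_centers_px[image]
        return np.mean([self._gauss(shape, c, sd) for c in centers], axis=0)

    def subject_density(self, subject, shape) -> np.ndarray:
        geom = self.config.geometry
        off = self.subject_offsets_px[subject]
        center = (0.5 * geom.width_px + off[0], 0.5 * geom.height_px + off[1])
        return self._gauss(shape, center,
                           self._sd_px((self.config.subject_sd_deg,) * 2))

    def density(self, image=None, subject=None, scale: float = 1.0,
                category: str | None = None) -> DensityMap:
        """Exact mixture density on the grid at ``scale``.

        ``image=None`` averages the hotspot term over all images of the
        (given or unique) category; ``subject=None`` pools the subject
        term over all subjects.
        """
        cfg = self.config
        shape = grid_shape(cfg.geometry, scale)
        if image is not None:
            if image not in self.image_category:
                raise KeyError(f"unknown image {image!r}")
            category = self.image_category[image]
            hot = self.hotspot_density(image, shape)
        else:
            if category is None:
                cats = {c.name for c in cfg.categories}
                if len(cats) != 1:
                    raise ValueError("category required when pooling images")
                category = next(iter(cats))
            members = [i for i, c in self.image_category.items()
                       if c == category]
            hot = np.mean([self.hotspot_density(i, shape) for i in members],
                          axis=0)
        if subject is not None:
            if subject not in self.subject_offsets_px:
                raise KeyError(f"unknown subject {subject!r}")
            subj = self.subject_density(subject, shape)
        else:
            subj = np.mean([self.subject_density(s, shape)
                            for s in self.subject_ids], axis=0)
        w_c, w_h, w_s = cfg.mixture_weights
        mix = w_c * self.central_density(category, shape) + w_h * hot + w_s * subj
        return DensityMap.from_values(mix, cfg.geometry, scale)


def _truncated_normal(rng, center, sd, geometry) -> tuple[float, float]:
    # rejection sampling keeps the component a proper truncated density
    for _ in range(10_000):
        x = rng.normal(center[0], sd[0])
        y = rng.normal(center[1], sd[1])
        if 0 <= x < geometry.width_px and 0 <= y < geometry.height_px:
            return x, y
    raise RuntimeError("rejection sampling failed; component far off screen")


def make_dataset(config: SyntheticConfig) -> tuple[FixationDataset,
                                                   SyntheticTruth]:
    """Generate a fixation dataset and its ground-truth bundle."""
    geom = config.geometry
    image_ids = [f"img{i:03d}" for i in range(config.n_images)]
    subject_ids = [f"sub{s:02d}" for s in range(config.n_subjects)]
    cat_names = [c.name for c in config.categories]
    image_category = {img: cat_names[i % len(cat_names)]
                      for i, img in enumerate(image_ids)}

    # image layout stream: hotspot centers uniform over the central 80%
    # of the screen, to keep border truncation from dominating
    layout_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    hotspot_centers = {}
    for img in image_ids:
        cx = layout_rng.uniform(0.1 * geom.width_px, 0.9 * geom.width_px,
                                config.hotspots_per_image)
        cy = layout_rng.uniform(0.1 * geom.height_px, 0.9 * geom.height_px,
                                config.hotspots_per_image)
        hotspot_centers[img] = np.column_stack([cx, cy])

    # subject stream: idiosyncratic offsets from the planted fields
    fields = _component_fields(config.n_subject_components)
    subj_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    subject_weights = {}
    subject_offsets = {}
    for sid in subject_ids:
        w = subj_rng.normal(0.0, config.subject_weight_sd,
                            config.n_subject_components)
        off_deg = w @ fields
        subject_weights[sid] = w
        subject_offsets[sid] = (geom.deg_to_px(abs(off_deg[0]), "x")
                                * np.sign(off_deg[0]),
                                geom.deg_to_px(abs(off_deg[1]), "y")
                                * np.sign(off_deg[1]))

    truth = SyntheticTruth(config, image_ids, image_category,
                           hotspot_centers, subject_ids, subject_offsets,
                           subject_weights, fields)

    cat_by_name = {c.name: c for c in config.categories}
    hot_sd = (geom.deg_to_px(config.hotspot_sd_deg, "x"),
              geom.deg_to_px(config.hotspot_sd_deg, "y"))
    subj_sd = (geom.deg_to_px(config.subject_sd_deg, "x"),
               geom.deg_to_px(config.subject_sd_deg, "y"))
    weights = np.asarray(config.mixture_weights, float)

    rows = []
    for s_idx, sid in enumerate(subject_ids):
        s_center = (0.5 * geom.width_px + subject_offsets[sid][0],
                    0.5 * geom.height_px + subject_offsets[sid][1])
        for i_idx, img in enumerate(image_ids):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 3, s_idx, i_idx]))
            spec = cat_by_name[image_category[img]]
            c_center = (spec.center[0] * geom.width_px,
                        spec.center[1] * geom.height_px)
            c_sd = (geom.deg_to_px(spec.sd_deg[0], "x"),
                    geom.deg_to_px(spec.sd_deg[1], "y"))
            for t in range(1, config.fixations_per_trial + 1):
                comp = rng.choice(3, p=weights)
                if comp == 0:
                    x, y = _truncated_normal(rng, c_center, c_sd, geom)
                elif comp == 1:
                    h = rng.integers(config.hotspots_per_image)
                    x, y = _truncated_normal(
                        rng, hotspot_centers[img][h], hot_sd, geom)
                else:
                    x, y = _truncated_normal(rng, s_center, subj_sd, geom)
                rows.append((sid, img, image_category[img], t, x, y))

    df = pd.DataFrame(rows, columns=["subject", "image", "category",
                                     "trial_index", "x", "y"])
    dataset = FixationDataset(df, geom,
                              max_fixations=config.fixations_per_trial)
    return dataset, truth


def ground_truth_density(bundle: SyntheticTruth, image=None, subject=None,
                         scale: float = 1.0,
                         category: str | None = None) -> DensityMap:
    """Convenience alias for :meth:`SyntheticTruth.density`."""
    return bundle.density(image=image, subject=subject, scale=scale,
                          category=category)
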