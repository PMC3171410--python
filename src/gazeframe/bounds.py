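"""Reference-frame bounds for models of fixation selection.

A model's evaluation score is only interpretable relative to two
data-derived baselines:

* the **lower bound** — how well the image- and subject-independent
  spatial bias predicts held-out fixations.  Training draws exclude both
  the test subject and the test image, so the prediction uses no
  knowledge of either.  Any useful model must beat this.
* the **upper bound** — inter-subject consistency: how well the pooled
  fixations of other subjects on the *same* image predict a held-out
  subject.  Generic (subject-blind) models cannot beat this.

Both are estimated by cross-validation over a grid of training-set
sizes, following a fixed schedule of subject and image counts with
repeated random draws (explicitly balanced when only one or two donors
are drawn, so no donor is over-used).

On top of the frame, three subject-aware predictors are provided: the
subject-specific spatial bias, its PCA-cleaned version (the subject
bias re-expressed in the few dominant components of between-subject
bias variation), and the combined prediction that swaps the population
spatial bias inside an inter-subject FDM for the predicted subject's
own bias — the construction that can surpass the upper bound.

The module exposes plain functions plus a small model/results pair
(:class:`ReferenceFrame` / :class:`ReferenceFrameResults`) for the
common fit-everything-and-summarize workflow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DensityMap, FixationDataset, grid_shape
from .density import SmoothingSpec, coarse_grid, smooth_counts
from .entropy import BinnedSample, kl_corrected
from .exceptions import ConfigError, GeometryError
from .measures import EvaluationResult, _auc_value, sample_scores
from . import measures as _measures

__all__ = [
    "CVSchedule", "BoundsGrid", "PCABasis", "evaluate_prediction",
    "lower_bound", "upper_bound", "subject_bias_eval", "pca_basis",
    "pca_clean_bias", "eigen_weighted_bias", "combined_prediction",
    "ReferenceFrame", "ReferenceFrameResults", "DEFAULT_SCALE",
]

#: Working grid scale for bound computations: 64 x 48 cells on the
#: 1280 x 960 reference screen, fine enough for a 2-degree kernel.
DEFAULT_SCALE = 0.05


@dataclass(frozen=True)
class CVSchedule:
    """Cross-validation schedule for the bounds grid.

    Defaults are the full-study schedule (subject sizes 1..47, image
    sizes 1..63, 47 repetitions, 63 for the subject-specific bias);
    sizes exceeding what a dataset can support are marked missing in
    the resulting grid.
    """

    subject_sizes: tuple[int, ...] = (1, 2, 4, 7, 13, 25, 47)
    image_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 32, 63)
    reps: int = 47
    subject_reps: int = 63
    balanced_small: bool = True

    @classmethod
    def geometric(cls, n_subjects: int, n_images: int, reps: int = 47,
                  subject_reps: int = 63) -> "CVSchedule":
        """Powers-of-two sizes up to n-1 (the holdout), plus n-1 itself."""
        def sizes(n):
            out = []
            s = 1
            while s < n - 1:
                out.append(s)
                s *= 2
            out.append(n - 1)
            return tuple(out)
        return cls(sizes(n_subjects), sizes(n_images), reps=reps,
                   subject_reps=subject_reps)


@dataclass
class BoundsGrid:
    """Cross-validated mean scores indexed (subject size x image size)."""

    measure: str
    category: str
    subject_sizes: tuple[int, ...]
    image_sizes: tuple[int, ...]
    mean: np.ndarray          # (n_subject_sizes, n_image_sizes)
    sd: np.ndarray
    n_obs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=pd.Index(self.subject_sizes,
                                                      name="n_subjects"),
                            columns=pd.Index(self.image_sizes,
                                             name="n_images"))

    @property
    def max_cell(self) -> float:
        """Mean score at the largest feasible (subjects, images) cell."""
        finite = np.where(np.isfinite(self.mean))
        k = np.lexsort((finite[1], finite[0]))[-1]
        return float(self.mean[finite[0][k], finite[1][k]])


@dataclass
class PCABasis:
    """Mean map and top-k principal components of subject spatial biases.

    Components are orthonormal as flattened vectors, eigenvalues are the
    explained variances in nonincreasing order, and each component's
    sign is fixed so its largest-magnitude coefficient is positive.
    """

    mean_map: np.ndarray
    components: np.ndarray    # (k, n_cells)
    eigenvalues: np.ndarray
    shape: tuple[int, int]
    geometry: object
    scale: float

    @property
    def k(self) -> int:
        return self.components.shape[0]


# ---------------------------------------------------------------------------
# prediction scoring


def evaluate_prediction(prediction: DensityMap,
                        test_fixations: FixationDataset,
                        measure: str = "auc",
                        negatives_strategy: str = "all_pixels",
                        seed: int | None = None,
                        donor_fixations: FixationDataset | None = None,
                        kl_method: str = "jeffreys") -> EvaluationResult:
    """Score a density-map prediction against held-out fixations.

    Dispatches to the measures module, treating the prediction as the
    salience map.  For ``measure='kl'`` the coarse-grid protocol is
    used: test fixations are binned on the geometry-derived coarse grid
    (one bin per 2-degree disc area), the prediction is block-summed to
    that grid, and the sample-size-corrected KL divergence is returned
    (``kl_method``: ml, jeffreys or chao_shen — chao_shen needs test
    sets of at least a few dozen fixations).
    """
    if measure == "auc":
        sample = sample_scores(prediction, test_fixations,
                               negatives_strategy, donor_fixations, seed)
        return _measures.auc(sample)
    if measure == "nss":
        return _measures.nss(prediction, test_fixations)
    if measure == "kl":
        rows, cols = coarse_grid(prediction.geometry)
        prows, pcols = prediction.values.shape
        if prows % rows or pcols % cols:
            raise GeometryError(
                f"prediction grid {prediction.values.shape} does not "
                f"block-reduce to the coarse grid ({rows}, {cols})")
        q = prediction.values.reshape(rows, prows // rows, cols,
                                      pcols // cols).sum(axis=(1, 3))
        from .density import histogram2d

        counts = histogram2d(test_fixations, (rows, cols))
        est = kl_corrected(BinnedSample(counts), q / q.sum(),
                           method=kl_method)
        return EvaluationResult("kl", est.value, n_pos=est.n,
                                params={"method": kl_method,
                                        "grid": (rows, cols)})
    raise ConfigError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# cached per-trial histograms


class _TrialCache:
    """Per-(subject, image) count grids and fixation cells for one category."""

    def __init__(self, dataset: FixationDataset, scale: float):
        self.geometry = dataset.geometry
        self.scale = scale
        self.grid = grid_shape(dataset.geometry, scale)
        self.subjects = dataset.subjects
        self.images = dataset.images
        rows, cols = self.grid
        ns, ni = len(self.subjects), len(self.images)
        self.counts = np.zeros((ns, ni, rows, cols), dtype=np.uint16)
        self.cells: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        s_idx = {s: k for k, s in enumerate(self.subjects)}
        i_idx = {i: k for k, i in enumerate(self.images)}
        geom = dataset.geometry
        df = dataset.records
        col = np.clip((df["x"].to_numpy(float) * cols
                       // geom.width_px).astype(int), 0, cols - 1)
        row = np.clip((df["y"].to_numpy(float) * rows
                       // geom.height_px).astype(int), 0, rows - 1)
        si = df["subject"].map(s_idx).to_numpy()
        ii = df["image"].map(i_idx).to_numpy()
        np.add.at(self.counts, (si, ii, row, col), 1)
        order = np.lexsort((ii, si))
        for key, grp in itertools.groupby(order, key=lambda k: (si[k], ii[k])):
            idx = np.fromiter(grp, int)
            self.cells[key] = (row[idx], col[idx])

    def training_counts(self, subject_idx, image_idx) -> np.ndarray:
        return self.counts[np.ix_(subject_idx, image_idx)] \
            .sum(axis=(0, 1)).astype(float)


def _score_values(values: np.ndarray, cells, measure: str) -> float:
    """Fast scorer used inside the cross-validation loops."""
    row, col = cells
    pos = values[row, col]
    if measure == "auc":
        return _auc_value(pos, values.ravel())
    if measure == "nss":
        sd = values.std()
        return float(((pos - values.mean()) / sd).mean())
    raise ConfigError(f"measure {measure!r} not supported in grid loops; "
                      "use evaluate_prediction for KL")


def _draw(rng: np.random.Generator, donors: list, size: int, reps: int,
          balanced: bool) -> list[list]:
    """``reps`` training draws of ``size`` donors without replacement.

    For sizes of one or two (and ``balanced`` True) donors are consumed
    from reshuffled cycles so each donor appears equally often across
    repetitions; larger sizes use plain uniform draws, trusting the
    combinatorics for balance.
    """
    if size > len(donors):
        raise ValueError("size exceeds available donors")
    if balanced and size <= 2:
        draws, pool = [], []
        for _ in range(reps):
            take = []
            while len(take) < size:
                if not pool:
                    pool = list(donors)
                    rng.shuffle(pool)
                cand = pool.pop()
                if cand not in take:
                    take.append(cand)
            draws.append(take)
        return draws
    return [[donors[j] for j in rng.choice(len(donors), size=size,
                                           replace=False)]
            for _ in range(reps)]


# ---------------------------------------------------------------------------
# bounds


def _per_category(dataset: FixationDataset):
    for cat in dataset.categories:
        yield cat, dataset.select(category=cat)


def lower_bound(dataset: FixationDataset,
                schedule: CVSchedule | None = None,
                measure: str = "auc", seed: int | None = None,
                smoothing: SmoothingSpec = SmoothingSpec(),
                scale: float = DEFAULT_SCALE,
                progress=None,
                precomputed: dict | None = None) -> dict[str, BoundsGrid]:
    """Cross-validated spatial-bias grid, per category.

    For every (n_subjects, n_images) cell and every (test subject, test
    image) pair, the training set is a random draw of other subjects on
    other images; the FDM of the training fixations is scored against
    the test trial.  Cells that need more donors than the data holds
    are left missing.

    ``precomputed`` maps ``(category, n_subjects, n_images)`` to a
    ``(mean, sd, n)`` triple from an earlier run; those cells are
    reused instead of recomputed (checkpoint/resume support).
    """
    schedule = schedule or CVSchedule()
    precomputed = precomputed or {}
    out = {}
    for cat, sub in _per_category(dataset):
        cache = _TrialCache(sub, scale)
        subs, imgs = cache.subjects, cache.images
        ns, ni = len(subs), len(imgs)
        shape = (len(schedule.subject_sizes), len(schedule.image_sizes))
        mean = np.full(shape, np.nan)
        sd = np.full(shape, np.nan)
        n_obs = np.zeros(shape, dtype=int)
        for a, n_s in enumerate(schedule.subject_sizes):
            for b, n_i in enumerate(schedule.image_sizes):
                if n_s > ns - 1 or n_i > ni - 1:
                    continue
                if (cat, n_s, n_i) in precomputed:
                    mean[a, b], sd[a, b], n_obs[a, b] = \
                        precomputed[(cat, n_s, n_i)]
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed or 0, 11, a, b]))
                scores = []
                for ts in range(ns):
                    donors_s = [k for k in range(ns) if k != ts]
                    for ti in range(ni):
                        if (ts, ti) not in cache.cells:
                            continue
                        donors_i = [k for k in range(ni) if k != ti]
                        dr_s = _draw(rng, donors_s, n_s, schedule.reps,
                                     schedule.balanced_small)
                        dr_i = _draw(rng, donors_i, n_i, schedule.reps,
                                     schedule.balanced_small)
                        for rep in range(schedule.reps):
                            counts = cache.training_counts(dr_s[rep],
                                                           dr_i[rep])
                            if counts.sum() == 0:
                                continue
                            pred = smooth_counts(counts, cache.geometry,
                                                 smoothing, scale)
                            scores.append(_score_values(
                                pred.values, cache.cells[(ts, ti)], measure))
                if scores:
                    mean[a, b] = np.mean(scores)
                    sd[a, b] = np.std(scores, ddof=1) if len(scores) > 1 else 0.0
                    n_obs[a, b] = len(scores)
                if progress is not None:
                    progress(cat, n_s, n_i, mean[a, b], sd[a, b],
                             int(n_obs[a, b]))
        out[cat] = BoundsGrid(measure, cat, tuple(schedule.subject_sizes),
                              tuple(schedule.image_sizes), mean, sd, n_obs)
    return out


def upper_bound(dataset: FixationDataset,
                train_sizes=None, reps: int = 47,
                measure: str = "auc", seed: int | None = None,
                smoothing: SmoothingSpec = SmoothingSpec(),
                scale: float = DEFAULT_SCALE,
                balanced_small: bool = True) -> dict[str, pd.DataFrame]:
    """Inter-subject consistency curve vs. number of training subjects.

    Train and test share the image; the test subject never enters the
    training set.  Default training sizes step by one from 1 to the
    number of subjects minus one.
    """
    out = {}
    for cat, sub in _per_category(dataset):
        cache = _TrialCache(sub, scale)
        ns, ni = len(cache.subjects), len(cache.images)
        if ns < 2:
            raise ConfigError("upper bound needs at least 2 subjects")
        sizes = list(train_sizes) if train_sizes is not None \
            else list(range(1, ns))
        rows = []
        for a, n_s in enumerate(sizes):
            if n_s > ns - 1:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([seed or 0, 13, a]))
            scores = []
            for ts in range(ns):
                donors_s = [k for k in range(ns) if k != ts]
                for ti in range(ni):
                    if (ts, ti) not in cache.cells:
                        continue
                    dr_s = _draw(rng, donors_s, n_s, reps, balanced_small)
                    for rep in range(reps):
                        counts = cache.training_counts(dr_s[rep], [ti])
                        if counts.sum() == 0:
                            continue
                        pred = smooth_counts(counts, cache.geometry,
                                             smoothing, scale)
                        scores.append(_score_values(
                            pred.values, cache.cells[(ts, ti)], measure))
            rows.append({"n_train_subjects": n_s,
                         "mean": float(np.mean(scores)),
                         "sd": float(np.std(scores, ddof=1)),
                         "n": len(scores)})
        out[cat] = pd.DataFrame(rows)
    return out


def subject_bias_eval(dataset: FixationDataset,
                      image_sizes=None, reps: int = 63,
                      measure: str = "auc", seed: int | None = None,
                      smoothing: SmoothingSpec = SmoothingSpec(),
                      scale: float = DEFAULT_SCALE,
                      balanced_small: bool = True) -> dict[str, pd.DataFrame]:
    """Predictive power of the subject-specific spatial bias.

    Training and test share the subject but never the image; scores are
    reported per number of training images.
    """
    out = {}
    for cat, sub in _per_category(dataset):
        cache = _TrialCache(sub, scale)
        ns, ni = len(cache.subjects), len(cache.images)
        if ni < 2:
            raise ConfigError("subject bias needs at least 2 images")
        sizes = list(image_sizes) if image_sizes is not None \
            else [s for s in CVSchedule.geometric(ns, ni).image_sizes]
        rows = []
        for b, n_i in enumerate(sizes):
            if n_i > ni - 1:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([seed or 0, 17, b]))
            scores = []
            for ts in range(ns):
                for ti in range(ni):
                    if (ts, ti) not in cache.cells:
                        continue
                    donors_i = [k for k in range(ni) if k != ti]
                    dr_i = _draw(rng, donors_i, n_i, reps, balanced_small)
                    for rep in range(reps):
                        counts = cache.training_counts([ts], dr_i[rep])
                        if counts.sum() == 0:
                            continue
                        pred = smooth_counts(counts, cache.geometry,
                                             smoothing, scale)
                        scores.append(_score_values(
                            pred.values, cache.cells[(ts, ti)], measure))
            rows.append({"n_train_images": n_i,
                         "mean": float(np.mean(scores)),
                         "sd": float(np.std(scores, ddof=1)),
                         "n": len(scores)})
        out[cat] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# PCA cleaning of subject biases


def pca_basis(dataset: FixationDataset, training_subjects,
              training_images, k: int = 5,
              smoothing: SmoothingSpec = SmoothingSpec(),
              scale: float = DEFAULT_SCALE) -> PCABasis:
    """Principal components of the training subjects' spatial biases.

    Each training subject's smoothed bias map over the training images
    is flattened; maps are centered by their mean and decomposed by SVD.
    """
    from .density import spatial_bias

    training_subjects = list(training_subjects)
    if k > len(training_subjects) - 1:
        raise ValueError(f"k={k} exceeds the rank supported by "
                         f"{len(training_subjects)} training subjects")
    maps = []
    for s in training_subjects:
        m = spatial_bias(dataset, subjects=[s], images=training_images,
                         smoothing=smoothing, scale=scale)
        maps.append(m.values.ravel())
    B = np.asarray(maps)
    mean = B.mean(axis=0)
    centered = B - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:k]
    eigenvalues = svals[:k] ** 2 / (len(maps) - 1)
    # fix the sign indeterminacy for reproducibility
    for j in range(components.shape[0]):
        peak = np.argmax(np.abs(components[j]))
        if components[j, peak] < 0:
            components[j] = -components[j]
    shape = grid_shape(dataset.geometry, scale)
    return PCABasis(mean, components, eigenvalues, shape,
                    dataset.geometry, scale)


def pca_clean_bias(basis: PCABasis, subject_bias: DensityMap) -> DensityMap:
    """Re-express a (noisy) subject bias in the PCA basis.

    Least-squares weights of the centered bias on the components, then
    reconstruction from the mean map; negative cells are clipped to
    zero and the map renormalized to unit mass.
    """
    b = subject_bias.values.ravel()
    if b.size != basis.mean_map.size:
        raise GeometryError("subject bias shape does not match basis")
    w, *_ = np.linalg.lstsq(basis.components.T, b - basis.mean_map,
                            rcond=None)
    recon = basis.mean_map + basis.components.T @ w
    recon = np.clip(recon, 0.0, None).reshape(basis.shape)
    return DensityMap.from_values(recon, subject_bias.geometry,
                                  subject_bias.scale)


def eigen_weighted_bias(basis: PCABasis) -> DensityMap:
    """Subject-blind control: mean map plus eigenvalue-weighted components."""
    recon = basis.mean_map + basis.eigenvalues @ basis.components
    recon = np.clip(recon, 0.0, None).reshape(basis.shape)
    return DensityMap.from_values(recon, basis.geometry, basis.scale)


def combined_prediction(intersubject_fdm: DensityMap,
                        training_bias: DensityMap,
                        subject_bias: DensityMap,
                        floor: float | None = None) -> DensityMap:
    """Swap the population bias in an inter-subject FDM for a subject's own.

    The inter-subject FDM is divided point-wise by the training
    subjects' spatial bias (floored to avoid division by zero), leaving
    an image-specific component, which is then multiplied point-wise by
    the predicted subject's spatial bias and renormalized to unit mass.
    """
    shapes = {intersubject_fdm.values.shape, training_bias.values.shape,
              subject_bias.values.shape}
    if len(shapes) != 1:
        raise GeometryError(f"shape mismatch: {shapes}")
    if floor is None:
        floor = 1e-6 / intersubject_fdm.values.size
    if not floor > 0:
        raise ValueError("floor must be > 0")
    ratio = intersubject_fdm.values / np.maximum(training_bias.values, floor)
    return DensityMap.from_values(ratio * subject_bias.values,
                                  intersubject_fdm.geometry,
                                  intersubject_fdm.scale)


# ---------------------------------------------------------------------------
# model / results


class ReferenceFrame:
    """Reference-frame model of a fixation dataset.

    Fitting computes, per stimulus category, the cross-validated lower
    bound (spatial bias) over the schedule's (subjects x images) grid,
    the upper bound (inter-subject consistency) versus training-set
    size, and the subject-specific bias curve.

    Parameters
    ----------
    dataset : FixationDataset
    schedule : CVSchedule, optional
        Defaults to a geometric schedule fitted to the dataset size.
    measure : {'auc', 'nss'}
    smoothing : SmoothingSpec
    scale : float
        Working grid scale (cells per pixel).
    """

    def __init__(self, dataset: FixationDataset,
                 schedule: CVSchedule | None = None, measure: str = "auc",
                 smoothing: SmoothingSpec = SmoothingSpec(),
                 scale: float = DEFAULT_SCALE,
                 upper_train_sizes=None):
        self.dataset = dataset
        self.schedule = schedule or CVSchedule.geometric(
            len(dataset.subjects), len(dataset.images))
        self.measure = measure
        self.smoothing = smoothing
        self.scale = scale
        self.upper_train_sizes = upper_train_sizes

    def fit(self, seed: int | None = None,
            subject_specific: bool = True) -> "ReferenceFrameResults":
        lower = lower_bound(self.dataset, self.schedule, self.measure,
                            seed=seed, smoothing=self.smoothing,
                            scale=self.scale)
        upper = upper_bound(self.dataset,
                            train_sizes=self.upper_train_sizes,
                            reps=self.schedule.reps, measure=self.measure,
                            seed=seed, smoothing=self.smoothing,
                            scale=self.scale,
                            balanced_small=self.schedule.balanced_small)
        subj = None
        if subject_specific:
            subj = subject_bias_eval(
                self.dataset, image_sizes=self.schedule.image_sizes,
                reps=self.schedule.subject_reps, measure=self.measure,
                seed=seed, smoothing=self.smoothing, scale=self.scale,
                balanced_small=self.schedule.balanced_small)
        return ReferenceFrameResults(self, lower, upper, subj, seed)


@dataclass
class ReferenceFrameResults:
    """Fitted reference frame: grids, curves and a summary table."""

    model: ReferenceFrame
    lower: dict[str, BoundsGrid]
    upper: dict[str, pd.DataFrame]
    subject_specific: dict[str, pd.DataFrame] | None
    seed: int | None

    @property
    def categories(self) -> list[str]:
        return sorted(self.lower)

    def lower_bound_value(self, category: str) -> float:
        """Lower bound at the largest feasible training set."""
        return self.lower[category].max_cell

    def upper_bound_value(self, category: str) -> float:
        """Upper bound at the largest training-subject count."""
        return float(self.upper[category]["mean"].iloc[-1])

    def table(self, category: str) -> pd.DataFrame:
        """Reference-values layout: image counts as rows (descending),
        subject counts as columns, plus an image-specific row (the
        upper bound) and a subject-specific column when available."""
        grid = self.lower[category]
        body = grid.to_frame().T.iloc[::-1]  # rows = image sizes, descending
        up = self.upper[category].set_index("n_train_subjects")["mean"]
        top = pd.Series({n: up.get(n, np.nan) for n in grid.subject_sizes},
                        name="image_specific")
        body = pd.concat([top.to_frame().T, body])
        if self.subject_specific is not None:
            ss = self.subject_specific[category].set_index(
                "n_train_images")["mean"]
            body["subject_specific"] = [np.nan] + [
                ss.get(n, np.nan) for n in body.index[1:]]
        return body

    def summary(self) -> str:
        lines = [f"Reference frame ({self.model.measure.upper()}), "
                 f"seed={self.seed}"]
        for cat in self.categories:
            lines.append(f"\n== category: {cat} ==")
            lines.append(
                f"lower bound (max training set): "
                f"{self.lower_bound_value(cat):.3f}   "
                f"upper bound (max subjects): "
                f"{self.upper_bound_value(cat):.3f}")
            lines.append(self.table(cat).round(3).to_string())
        return "\n".join(lines)
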