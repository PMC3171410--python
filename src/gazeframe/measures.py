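"""Evaluation measures for salience maps against fixation data.

Three families of measures are implemented:

* central-tendency comparisons of salience at fixated vs. other
  locations — chance-adjusted salience, normalized scan-path salience
  (NSS), ratio of medians;
* classification measures treating the salience map as a classifier of
  fixated vs. non-fixated locations — the percentile measure, the area
  under the ROC curve (AUC) and a cross-validated naive-Bayes percent
  correct;
* distribution comparisons between the map (as a probability density)
  and an empirical fixation density — Kullback-Leibler divergence, its
  symmetric extension, and the Pearson correlation of the two maps.

The AUC here uses an efficient threshold scheme: only the unique
salience values at fixated locations act as thresholds, the step ROC is
integrated by lower sums, and segments where positives tie negatives
(or where the hit rate has not reached one) are integrated
trapezoidally.  This reduces to awarding, per positive, the fraction of
negatives strictly below it plus half the fraction tied with it, and is
identical to the Mann-Whitney U statistic and to trapezoidal
integration of the full ROC curve.

``theoretical_max_auc`` computes the best AUC any prediction can reach
for a given empirical fixation density: because every location has
finite probability of being fixated *and* of serving as a control, even
the self-prediction cannot separate the classes perfectly, so the bound
is below 1 for any non-degenerate density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DensityMap, SalienceMap, FixationDataset
from .exceptions import ConfigError, EmptyDatasetError, GeometryError

__all__ = [
    "ClassificationSample", "ROCCurve", "EvaluationResult",
    "sample_scores", "auc", "roc_curve", "nss", "chance_adjusted_salience",
    "ratio_of_medians", "percentile_measure", "naive_bayes_percent_correct",
    "kl_divergence", "symmetric_kl", "map_correlation",
    "theoretical_max_auc",
]

NEGATIVES_STRATEGIES = ("all_pixels", "nonfixated_pixels",
                        "other_image_fixations")


@dataclass
class ClassificationSample:
    """Salience values at fixated (positive) and control (negative) points."""

    positives: np.ndarray
    negatives: np.ndarray

    def __post_init__(self) -> None:
        self.positives = np.asarray(self.positives, float).ravel()
        self.negatives = np.asarray(self.negatives, float).ravel()
        if not (np.all(np.isfinite(self.positives))
                and np.all(np.isfinite(self.negatives))):
            raise ValueError("salience values must be finite")


@dataclass
class ROCCurve:
    """Full ROC curve: descending thresholds plus a terminal point."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    @property
    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.tpr, self.fpr))


@dataclass
class EvaluationResult:
    """A named scalar score with its provenance."""

    measure: str
    value: float
    n_pos: int = 0
    n_neg: int = 0
    params: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


def _positives(map_: SalienceMap, fixations: FixationDataset) -> np.ndarray:
    if len(fixations) == 0:
        raise EmptyDatasetError("no fixations to score")
    xy = fixations.xy()
    return np.asarray(map_.value_at(xy[:, 0], xy[:, 1]), float)


def sample_scores(map_: SalienceMap, fixations: FixationDataset,
                  negatives_strategy: str = "all_pixels",
                  donor_fixations: FixationDataset | None = None,
                  rng_seed: int | None = None) -> ClassificationSample:
    """Collect positive and negative salience values for classification.

    Positives are the map values at the fixated grid cells (nearest-cell
    lookup, no interpolation).  Negatives are, per strategy, all cell
    values, all values of cells that were never fixated, or the values
    at locations fixated on *other* images (``donor_fixations``).

    ``rng_seed`` is accepted for strategies that may subsample controls;
    the built-in strategies are deterministic and ignore it.
    """
    pos = _positives(map_, fixations)
    if negatives_strategy == "all_pixels":
        neg = map_.values.ravel()
    elif negatives_strategy == "nonfixated_pixels":
        xy = fixations.xy()
        row, col = map_.cell_of(xy[:, 0], xy[:, 1])
        mask = np.ones(map_.values.shape, dtype=bool)
        mask[row, col] = False
        neg = map_.values[mask]
    elif negatives_strategy == "other_image_fixations":
        if donor_fixations is None:
            raise ConfigError("other_image_fixations requires donor_fixations")
        neg = _positives(map_, donor_fixations)
    else:
        raise ConfigError(f"unknown negatives strategy {negatives_strategy!r}")
    return ClassificationSample(pos, neg)


def _auc_value(positives: np.ndarray, negatives: np.ndarray) -> float:
    """Efficient-threshold AUC.

    Thresholds are the unique positive values; between consecutive
    thresholds only the false-alarm rate moves, so lower-sum integration
    credits each positive with the fraction of negatives strictly below
    its value; segments where negatives tie the threshold (and the final
    segment when the hit rate is still short of one) are trapezoidal,
    which awards half credit per tied pair.
    """
    if positives.size == 0 or negatives.size == 0:
        raise EmptyDatasetError("AUC needs at least one positive and one negative")
    neg = np.sort(negatives)
    below = np.searchsorted(neg, positives, side="left")
    below_or_tied = np.searchsorted(neg, positives, side="right")
    credit = below + 0.5 * (below_or_tied - below)
    return float(credit.sum() / (positives.size * neg.size))


def auc(sample: ClassificationSample) -> EvaluationResult:
    """Area under the ROC curve; 0.5 is chance, 1 perfect."""
    value = _auc_value(sample.positives, sample.negatives)
    return EvaluationResult("auc", value, sample.positives.size,
                            sample.negatives.size)


def roc_curve(sample: ClassificationSample) -> ROCCurve:
    """The full ROC curve over all unique pooled score values.

    Points are (FPR(t), TPR(t)) for the classifier "fixated iff score
    >= t", preceded by (0, 0); the final point is (1, 1).
    """
    pos, neg = sample.positives, sample.negatives
    if pos.size == 0 or neg.size == 0:
        raise EmptyDatasetError("ROC needs at least one positive and one negative")
    thr = np.unique(np.concatenate([pos, neg]))[::-1]
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    tpr = 1.0 - np.searchsorted(pos_sorted, thr, side="left") / pos.size
    fpr = 1.0 - np.searchsorted(neg_sorted, thr, side="left") / neg.size
    thresholds = np.concatenate([[np.inf], thr])
    return ROCCurve(thresholds,
                    np.concatenate([[0.0], fpr]),
                    np.concatenate([[0.0], tpr]))


def nss(map_: SalienceMap, fixations: FixationDataset) -> EvaluationResult:
    """Normalized scan-path salience.

    Mean salience at fixated locations after normalizing the map to zero
    mean and unit (population) standard deviation.
    """
    values = map_.values
    sd = values.std()  # population SD over all cells
    if sd == 0:
        raise ZeroDivisionError("NSS undefined for a constant map")
    z = (values - values.mean()) / sd
    zmap = SalienceMap(z, map_.geometry, map_.scale)
    pos = _positives(zmap, fixations)
    return EvaluationResult("nss", float(pos.mean()), pos.size,
                            values.size)


def chance_adjusted_salience(map_: SalienceMap,
                             fixations: FixationDataset) -> EvaluationResult:
    """Mean salience at fixated locations minus the image mean."""
    pos = _positives(map_, fixations)
    value = float(pos.mean() - map_.values.mean())
    return EvaluationResult("cas", value, pos.size, map_.values.size)


def _disc_max(values: np.ndarray, row: np.ndarray, col: np.ndarray,
              ry: float, rx: float) -> np.ndarray:
    """Max of ``values`` within an ellipse of cell-radii (ry, rx), clipped."""
    rows, cols = values.shape
    iry, irx = int(np.floor(ry)), int(np.floor(rx))
    out = np.empty(len(row))
    for k, (r, c) in enumerate(zip(row, col)):
        r0, r1 = max(0, r - iry), min(rows, r + iry + 1)
        c0, c1 = max(0, c - irx), min(cols, c + irx + 1)
        dy = (np.arange(r0, r1) - r) / ry
        dx = (np.arange(c0, c1) - c) / rx
        mask = dy[:, None] ** 2 + dx[None, :] ** 2 <= 1.0
        out[k] = values[r0:r1, c0:c1][mask].max()
    return out


def ratio_of_medians(map_: SalienceMap, fixations: FixationDataset,
                     radius_deg: float = 5.6,
                     n_controls: int | None = None,
                     rng_seed: int | None = None) -> EvaluationResult:
    """Ratio of median disc-max salience at fixations vs. random controls.

    The score of a location is the maximum of the map within a circular
    area of ``radius_deg`` degrees around it (clipped at the borders).
    Controls are drawn uniformly over the image; ``n_controls`` defaults
    to the number of fixations.
    """
    if not radius_deg > 0:
        raise ValueError("radius_deg must be > 0")
    geom = map_.geometry
    rows, cols = map_.values.shape
    ry = max(geom.deg_to_px(radius_deg, "y") * rows / geom.height_px, 1e-9)
    rx = max(geom.deg_to_px(radius_deg, "x") * cols / geom.width_px, 1e-9)

    xy = fixations.xy()
    if len(xy) == 0:
        raise EmptyDatasetError("no fixations")
    frow, fcol = map_.cell_of(xy[:, 0], xy[:, 1])
    fix_scores = _disc_max(map_.values, frow, fcol, ry, rx)

    rng = np.random.default_rng(rng_seed)
    n_controls = len(xy) if n_controls is None else int(n_controls)
    crow = rng.integers(0, rows, n_controls)
    ccol = rng.integers(0, cols, n_controls)
    ctl_scores = _disc_max(map_.values, crow, ccol, ry, rx)

    ctl_median = float(np.median(ctl_scores))
    if ctl_median == 0:
        raise ZeroDivisionError("control median is zero; ratio undefined")
    value = float(np.median(fix_scores)) / ctl_median
    return EvaluationResult("rom", value, len(xy), n_controls,
                            params={"radius_deg": radius_deg})


def percentile_measure(map_: SalienceMap, fixations: FixationDataset,
                       percentile: float = 80.0) -> EvaluationResult:
    """Fraction of fixations landing in the top-(100-percentile)% area.

    With the default 80th percentile, the selected area covers 20% of
    the image, which is therefore the chance level of the measure.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    threshold = np.percentile(map_.values, percentile)
    pos = _positives(map_, fixations)
    value = float(np.mean(pos >= threshold))
    return EvaluationResult("percentile", value, pos.size,
                            map_.values.size,
                            params={"percentile": percentile})


def naive_bayes_percent_correct(sample: ClassificationSample,
                                n_bins: int = 10, k_folds: int = 10,
                                rng_seed: int | None = None) -> EvaluationResult:
    """Percent correct of a histogram naive-Bayes classifier.

    P(S|F) and P(S|not F) are estimated by equal-width binned histograms
    (Laplace-smoothed) on the training folds; a test point is classified
    as fixated iff P(S|F) > P(S|not F) (equal priors).  Stratified
    k-fold cross-validation: every point is in the test set exactly once.
    """
    from sklearn.model_selection import StratifiedKFold

    pos, neg = sample.positives, sample.negatives
    if pos.size < k_folds or neg.size < k_folds:
        raise ValueError("each class needs at least k_folds members")
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size, int), np.zeros(neg.size, int)])
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    bins = np.clip(np.digitize(scores, edges[1:-1]), 0, n_bins - 1)

    skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                          random_state=rng_seed)
    correct = 0
    for train, test in skf.split(scores.reshape(-1, 1), labels):
        hf = np.bincount(bins[train][labels[train] == 1], minlength=n_bins) + 1
        hn = np.bincount(bins[train][labels[train] == 0], minlength=n_bins) + 1
        lik_f = hf / hf.sum()
        lik_n = hn / hn.sum()
        pred = (lik_f[bins[test]] > lik_n[bins[test]]).astype(int)
        correct += int((pred == labels[test]).sum())
    value = correct / scores.size
    return EvaluationResult("naive_bayes", value, pos.size, neg.size,
                            params={"n_bins": n_bins, "k_folds": k_folds})


def _log(x: np.ndarray, log_base) -> np.ndarray:
    if log_base in ("e", None, np.e):
        return np.log(x)
    return np.log(x) / np.log(float(log_base))


def _floored(q: DensityMap, q_floor: float | None) -> np.ndarray:
    qv = q.values.ravel()
    if q_floor is None:
        q_floor = 1e-12 / qv.size  # 1e-12 of the uniform mass
    qv = np.maximum(qv, q_floor)
    return qv / qv.sum()


def kl_divergence(p: DensityMap, q: DensityMap, log_base="e",
                  q_floor: float | None = None) -> EvaluationResult:
    """Kullback-Leibler divergence sum_i p_i log(p_i / q_i).

    ``p`` is the true fixation density, ``q`` the model density.  Terms
    with ``p_i = 0`` contribute nothing; zeros in ``q`` are floored at
    ``q_floor`` (default 1e-12 of the uniform mass) and ``q``
    renormalized, because the raw measure is infinite whenever the model
    assigns zero to a fixated location.
    """
    if p.values.shape != q.values.shape:
        raise GeometryError(
            f"shape mismatch {p.values.shape} vs {q.values.shape}")
    pv = p.values.ravel()
    qv = _floored(q, q_floor)
    mask = pv > 0
    value = float(np.sum(pv[mask] * _log(pv[mask] / qv[mask], log_base)))
    return EvaluationResult("kl", value, params={"log_base": log_base})


def symmetric_kl(p: DensityMap, q: DensityMap, log_base="e",
                 q_floor: float | None = None) -> EvaluationResult:
    """Symmetric extension: KL(p, q) + KL(q, p)."""
    forward = kl_divergence(p, q, log_base, q_floor).value
    backward = kl_divergence(q, p, log_base, q_floor).value
    return EvaluationResult("skl", forward + backward,
                            params={"log_base": log_base})


def map_correlation(p: SalienceMap, q: SalienceMap) -> EvaluationResult:
    """Pearson correlation of cell values at matched locations."""
    if p.values.shape != q.values.shape:
        raise GeometryError(
            f"shape mismatch {p.values.shape} vs {q.values.shape}")
    a, b = p.values.ravel(), q.values.ravel()
    if a.std() == 0 or b.std() == 0:
        raise ZeroDivisionError("correlation undefined for a constant map")
    r = float(np.corrcoef(a, b)[0, 1])
    return EvaluationResult("correlation", r)


def theoretical_max_auc(p: DensityMap) -> EvaluationResult:
    """Upper bound on AUC for predicting fixations drawn from ``p``.

    Evaluates the self-prediction Q = P under a uniform control
    distribution over the N cells: positives occur at cell i with
    probability p_i, controls with probability 1/N, both scored p_i.
    The bound is the probability-weighted pairwise statistic

        sum_i sum_j p_i (1/N) [1(p_i > p_j) + 1/2 1(p_i = p_j)]

    which is 0.5 for the uniform density and strictly below 1 for every
    non-degenerate density.  The derivation assumes no spatial bias in
    the control distribution; this assumption is surfaced in ``params``.
    """
    pv = np.asarray(p.values, float).ravel()
    n_cells = pv.size
    ps = np.sort(pv)
    below = np.searchsorted(ps, pv, side="left")
    tied = np.searchsorted(ps, pv, side="right") - below
    value = float(np.sum(pv * (below + 0.5 * tied)) / n_cells)
    return EvaluationResult("max_auc", value, params={
        "n_cells": n_cells, "controls": "uniform (no spatial bias)"})
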