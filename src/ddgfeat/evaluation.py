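"""Class-aware evaluation of stability features and predictors.

Stability-variant datasets are strongly unbalanced towards destabilizing
variants (about 55/30/15 destabilizing/neutral/stabilizing), which biases
any pooled statistic.  This module provides:

* plain Pearson correlation and RMSE between experimental and predicted ddG,
* the stratified metric table (per class, total, and non-neutral),
* the balanced-resampling protocol: repeatedly draw equal-sized per-class
  subsets without replacement and average the statistic across draws,
* pairwise-class discrimination: AUC-ROC (rank-based, mid-rank ties) per
  class pair on balanced draws, with optional sign flips for features that
  anti-correlate with ddG, plus the two-sided Mann-Whitney test on the full
  class distributions.

The AUC here is exactly the Mann-Whitney U statistic normalized by n1*n2:
the probability that a random member of the positive class outranks a random
member of the negative class, ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .dataset_io import CLASS_ORDER, StabilityClass

logger = logging.getLogger(__name__)

#: class-pair labels in report order; within each pair the second-named
#: (higher-ddG) class is the positive label for the ROC
CLASS_PAIRS = [
    (StabilityClass.DESTABILIZING, StabilityClass.NEUTRAL),
    (StabilityClass.DESTABILIZING, StabilityClass.STABILIZING),
    (StabilityClass.NEUTRAL, StabilityClass.STABILIZING),
]

#: stratified-table row order
STRATA = ["Total", "Destabilizing", "Neutral", "Stabilizing", "Non-neutral"]


def _as_class_array(classes: Sequence) -> np.ndarray:
    return np.asarray(
        [c.value if isinstance(c, StabilityClass) else str(c) for c in classes]
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation coefficient.

    Raises on unequal lengths, fewer than two points, or zero variance in
    either argument (an undefined correlation is an error, never a silent 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("pearson needs at least two points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root mean square difference between two aligned vectors (kcal/mol)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("rmse of empty input")
    return float(np.sqrt(np.mean((x - y) ** 2)))


@dataclass
class MetricResult:
    """Pearson rho and RMSE on one stratum; rho is None when undefined (n < 2)."""

    pearson: float | None
    rmse: float
    n: int


def stratified_metrics(
    exp: Sequence[float], pred: Sequence[float], classes: Sequence
) -> pd.DataFrame:
    """Pearson/RMSE per class, on the whole set, and on the non-neutral subset.

    Rows follow the conventional report order Total / Destabilizing /
    Neutral / Stabilizing / Non-neutral.  Variants with missing predictions
    (NaN) are dropped pairwise before computing either metric.
    """
    exp = np.asarray(exp, dtype=float)
    pred = np.asarray(pred, dtype=float)
    cls = _as_class_array(classes)
    if not (len(exp) == len(pred) == len(cls)):
        raise ValueError("exp, pred and classes must be aligned")
    ok = np.isfinite(exp) & np.isfinite(pred)

    masks = {
        "Total": ok,
        "Destabilizing": ok & (cls == StabilityClass.DESTABILIZING.value),
        "Neutral": ok & (cls == StabilityClass.NEUTRAL.value),
        "Stabilizing": ok & (cls == StabilityClass.STABILIZING.value),
        "Non-neutral": ok & (cls != StabilityClass.NEUTRAL.value),
    }
    rows = []
    for stratum in STRATA:
        m = masks[stratum]
        n = int(m.sum())
        if n == 0:
            rows.append({"stratum": stratum, "pearson": np.nan, "rmse": np.nan, "n": 0})
            continue
        try:
            rho = pearson(exp[m], pred[m])
        except ValueError:
            logger.warning("pearson undefined on stratum %s (n=%d)", stratum, n)
            rho = np.nan
        rows.append(
            {"stratum": stratum, "pearson": rho, "rmse": rmse(exp[m], pred[m]), "n": n}
        )
    return pd.DataFrame(rows, columns=["stratum", "pearson", "rmse", "n"])


# ---------------------------------------------------------------------------
# Balanced resampling
# ---------------------------------------------------------------------------


@dataclass
class ResampleSpec:
    """Balanced-subsampling protocol parameters.

    ``per_class`` members of each class are drawn without replacement in
    each of ``n_subsets`` independent draws; with the conventional rule
    (half the smallest class of a 2461/1311/656 dataset) this is 328 per
    class, 984 per subset, repeated 100 times.
    """

    n_subsets: int = 100
    per_class: int = 328
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if self.per_class < 2:
            raise ValueError("per_class must be >= 2")

    def child_rngs(self) -> list[np.random.Generator]:
        """One independent, individually reproducible RNG per subset."""
        seq = np.random.SeedSequence(self.seed)
        return [np.random.default_rng(s) for s in seq.spawn(self.n_subsets)]


def half_smallest_class(classes: Sequence) -> int:
    """The conventional per-class subset size: half the smallest class."""
    cls = _as_class_array(classes)
    counts = [int((cls == c.value).sum()) for c in CLASS_ORDER]
    return min(counts) // 2


def balanced_subsample(
    classes: Sequence,
    per_class: int,
    rng: np.random.Generator,
    include: Sequence[StabilityClass] | None = None,
) -> np.ndarray:
    """Indices of a balanced subset: ``per_class`` per class, no replacement.

    ``include`` restricts the draw to a subset of classes (e.g. one pair for
    pairwise ROC analyses); default is all three.
    """
    cls = _as_class_array(classes)
    wanted = include if include is not None else CLASS_ORDER
    out = []
    for c in wanted:
        idx = np.flatnonzero(cls == c.value)
        if len(idx) < per_class:
            raise ValueError(
                f"class {c.value} has only {len(idx)} members, need {per_class}"
            )
        out.append(rng.choice(idx, size=per_class, replace=False))
    return np.concatenate(out)


@dataclass
class ResampleSummary:
    """Mean and spread of a statistic across balanced draws."""

    mean: float
    std: float
    values: np.ndarray = field(repr=False)

    @property
    def n_subsets(self) -> int:
        return len(self.values)


def repeated_balanced_correlation(
    feature: Sequence[float],
    ddg: Sequence[float],
    classes: Sequence,
    spec: ResampleSpec,
) -> ResampleSummary:
    """Mean +/- std Pearson correlation over repeated balanced subsets.

    Each subset draws ``spec.per_class`` variants per class without
    replacement and correlates the feature with ddG on the pooled balanced
    subset; subsets on which the correlation is undefined are skipped and
    logged.  NaN feature values are removed before drawing.
    """
    feature = np.asarray(feature, dtype=float)
    ddg = np.asarray(ddg, dtype=float)
    cls = _as_class_array(classes)
    ok = np.isfinite(feature) & np.isfinite(ddg)
    feature, ddg, cls = feature[ok], ddg[ok], cls[ok]

    values = []
    for rng in spec.child_rngs():
        idx = balanced_subsample(cls, spec.per_class, rng)
        try:
            values.append(pearson(feature[idx], ddg[idx]))
        except ValueError as exc:
            logger.warning("subset skipped: %s", exc)
    if not values:
        raise ValueError("no subset yielded a defined correlation")
    values = np.asarray(values)
    return ResampleSummary(mean=float(values.mean()), std=float(values.std(ddof=1)) if len(values) > 1 else 0.0, values=values)


# ---------------------------------------------------------------------------
# Discrimination: AUC-ROC and Mann-Whitney
# ---------------------------------------------------------------------------


def auc_roc(scores: Sequence[float], labels: Sequence) -> float:
    """Rank-based AUC with mid-rank tie handling (Mann-Whitney U / (n1*n2)).

    ``labels`` is a boolean/binary vector marking the positive class; both
    classes must be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("auc_roc needs both classes present")
    return float(roc_auc_score(labels, scores))


def mann_whitney_two_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value between two samples.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney needs two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    small = max(x.size, y.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


@dataclass
class ClassPairResult:
    """Discrimination of one class pair by one feature."""

    pair: str
    auc_mean: float
    auc_std: float
    mw_pvalue: float
    n_subsets: int


def pairwise_class_auc(
    values: Sequence[float],
    classes: Sequence,
    spec: ResampleSpec,
    flip: bool = False,
    mw_on_subsets: bool = False,
) -> list[ClassPairResult]:
    """Balanced AUC-ROC and Mann-Whitney p for each of the three class pairs.

    For every pair, ``spec.n_subsets`` balanced draws of ``spec.per_class``
    per class are scored; the positive label is the higher-ddG (more
    stabilizing) class of the pair, so a feature that increases with ddG
    scores above 0.5.  ``flip=True`` negates the scores first — the
    convention applied to features anti-correlated with ddG (conservation
    log-ratio, volume and hydrophobicity differences) so that all reported
    AUCs read "higher = more discriminative".  The Mann-Whitney p-value is
    computed on the full class distributions by default, or on one balanced
    draw per pair with ``mw_on_subsets``.
    """
    values = np.asarray(values, dtype=float)
    cls = _as_class_array(classes)
    ok = np.isfinite(values)
    values, cls = values[ok], cls[ok]
    scores = -values if flip else values

    results = []
    for lo, hi in CLASS_PAIRS:
        aucs = []
        first_idx = None
        for rng in spec.child_rngs():
            idx = balanced_subsample(cls, spec.per_class, rng, include=[lo, hi])
            if first_idx is None:
                first_idx = idx
            aucs.append(auc_roc(scores[idx], cls[idx] == hi.value))
        aucs = np.asarray(aucs)
        if mw_on_subsets:
            sub_cls, sub_sc = cls[first_idx], scores[first_idx]
            p = mann_whitney_two_sided(sub_sc[sub_cls == lo.value], sub_sc[sub_cls == hi.value])
        else:
            p = mann_whitney_two_sided(scores[cls == lo.value], scores[cls == hi.value])
        results.append(
            ClassPairResult(
                pair=f"{lo.value}-{hi.value}",
                auc_mean=float(aucs.mean()),
                auc_std=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
                mw_pvalue=p,
                n_subsets=len(aucs),
            )
        )
    return results


def feature_correlation_report(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    spec: ResampleSpec,
    ddg_col: str = "ddg_exp",
    class_col: str = "stability_class",
) -> pd.DataFrame:
    """Per-feature correlation table: total, balanced mean +/- std, per class.

    Columns follow the conventional layout Total / Total balanced /
    Destabilizing / Neutral / Stabilizing.
    """
    rows = []
    for name in feature_names:
        vals = table[name].to_numpy(dtype=float)
        ddg = table[ddg_col].to_numpy(dtype=float)
        cls = _as_class_array(table[class_col])
        ok = np.isfinite(vals) & np.isfinite(ddg)
        try:
            summary = repeated_balanced_correlation(vals[ok], ddg[ok], cls[ok], spec)
            bal_mean, bal_std = summary.mean, summary.std
        except ValueError as exc:
            logger.warning("balanced correlation undefined for %s: %s", name, exc)
            bal_mean = bal_std = np.nan
        try:
            total = pearson(vals[ok], ddg[ok])
        except ValueError:
            total = np.nan
        row = {
            "feature": name,
            "total": total,
            "total_balanced_mean": bal_mean,
            "total_balanced_std": bal_std,
        }
        for c in CLASS_ORDER:
            m = ok & (cls == c.value)
            try:
                row[c.value] = pearson(vals[m], ddg[m]) if m.sum() >= 2 else np.nan
            except ValueError:
                row[c.value] = np.nan
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["feature", "total", "total_balanced_mean", "total_balanced_std",
                 *[c.value for c in CLASS_ORDER]],
    )


def feature_auc_report(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    spec: ResampleSpec,
    flip_features: Sequence[str] = ("cons_log_ratio", "volume_diff", "hydrophobicity_diff"),
    ddg_col: str = "ddg_exp",
    class_col: str = "stability_class",
) -> pd.DataFrame:
    """Per-feature pairwise-class AUC and Mann-Whitney table.

    ``flip_features`` are scored with opposite sign (the anti-correlated
    features) so every reported AUC reads on the same monotone scale.
    """
    rows = []
    for name in feature_names:
        results = pairwise_class_auc(
            table[name].to_numpy(dtype=float),
            table[class_col],
            spec,
            flip=name in flip_features,
        )
        row: dict[str, object] = {"feature": name}
        for res in results:
            row[f"{res.pair}_auc_mean"] = res.auc_mean
            row[f"{res.pair}_auc_std"] = res.auc_std
            row[f"{res.pair}_pvalue"] = res.mw_pvalue
        rows.append(row)
    return pd.DataFrame(rows)
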