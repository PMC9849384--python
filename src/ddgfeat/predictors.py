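"""Untrained linear ddG scorer and the Random-Forest feature-ablation experiment.

The linear scorer combines four substitution components with fixed,
untrained weights, the accessibility acting as a burial modulator of the
structural-potential term:

    score_full       = 0.20*S_Bl + 0.29*S_Sk + 0.18*S_Hp + 0.33*S_BV*(1.1 - acc)
    score_reduced    = 0.29*S_Sk + 0.33*S_BV*(1.1 - acc)
    score_red_no_acc = 0.29*S_Sk + 0.33*S_BV

where S_Bl, S_Sk, S_Hp, S_BV are the substitution-matrix, Skolnick,
hydrophobicity and Bastolla-Vendruscolo components and acc the relative
accessibility in [0, 1].  The "reduced" variant drops the two
swap-symmetric-or-uninformative components (substitution matrix score and
hydrophobicity); "red-no-acc" additionally drops the accessibility
modulation.

The ablation experiment trains a Random-Forest regressor on repeated
balanced subsamples of a training pool and evaluates the per-variant mean
prediction (an ensemble over subsample models) on a fixed, key-disjoint
test set, for each feature subset.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .dataset_io import StabilityClass
from .evaluation import (
    ResampleSpec,
    balanced_subsample,
    half_smallest_class,
    stratified_metrics,
)
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["protein_id", "chain", "position", "wt_res", "mut_res"]


class FeatureSetSpec(str, enum.Enum):
    """Which components/features enter the predictor."""

    FULL = "full"
    REDUCED = "reduced"
    RED_NO_ACC = "red-no-acc"

    @property
    def feature_columns(self) -> list[str]:
        """Feature-table columns available to a trained model under this set."""
        cols = list(FEATURE_NAMES)
        if self in (FeatureSetSpec.REDUCED, FeatureSetSpec.RED_NO_ACC):
            cols = [c for c in cols if c not in ("blosum_score", "hydrophobicity_diff")]
        if self is FeatureSetSpec.RED_NO_ACC:
            cols = [c for c in cols if c != "accessibility"]
        return cols


@dataclass(frozen=True)
class DDGunWeights:
    """Fixed weights of the untrained linear scorer (overridable via config)."""

    w_bl: float = 0.20
    w_sk: float = 0.29
    w_hp: float = 0.18
    w_bv: float = 0.33
    acc_offset: float = 1.1


@dataclass
class DDGunComponents:
    """The component scores entering the linear scorer for one variant."""

    s_bl: float | None = None
    s_sk: float | None = None
    s_hp: float | None = None
    s_bv: float | None = None
    acc: float | None = None

    def __post_init__(self) -> None:
        if self.acc is not None and math.isfinite(self.acc):
            if not 0.0 <= self.acc <= 1.0:
                raise ValueError(f"acc {self.acc} outside [0, 1]")


#: which components each scorer variant requires
_REQUIRED: dict[FeatureSetSpec, tuple[str, ...]] = {
    FeatureSetSpec.FULL: ("s_bl", "s_sk", "s_hp", "s_bv", "acc"),
    FeatureSetSpec.REDUCED: ("s_sk", "s_bv", "acc"),
    FeatureSetSpec.RED_NO_ACC: ("s_sk", "s_bv"),
}


def ddgun_score(
    c: DDGunComponents,
    w: DDGunWeights = DDGunWeights(),
    variant: FeatureSetSpec = FeatureSetSpec.FULL,
) -> float:
    """Predicted ddG (kcal/mol) of the selected scorer variant.

    Missing required components raise a ``ValueError`` naming the component.
    """
    for name in _REQUIRED[variant]:
        val = getattr(c, name)
        if val is None or not math.isfinite(val):
            raise ValueError(f"component {name} missing or non-finite for {variant.value}")
    if variant is FeatureSetSpec.FULL:
        return (
            w.w_bl * c.s_bl + w.w_sk * c.s_sk + w.w_hp * c.s_hp
            + w.w_bv * c.s_bv * (w.acc_offset - c.acc)
        )
    if variant is FeatureSetSpec.REDUCED:
        return w.w_sk * c.s_sk + w.w_bv * c.s_bv * (w.acc_offset - c.acc)
    return w.w_sk * c.s_sk + w.w_bv * c.s_bv


#: default mapping from component name to feature-table column
DEFAULT_COMPONENT_MAP: dict[str, str] = {
    "s_bl": "blosum_score",
    "s_sk": "skolnick_diff",
    "s_hp": "hydrophobicity_diff",
    "s_bv": "bv_diff",
    "acc": "accessibility",
}


def score_dataset_ddgun(
    features: pd.DataFrame,
    variant: FeatureSetSpec = FeatureSetSpec.FULL,
    weights: DDGunWeights = DDGunWeights(),
    component_map: Mapping[str, str] = DEFAULT_COMPONENT_MAP,
) -> pd.Series:
    """Score every row of a feature table with the linear scorer.

    The component map is the adapter between component names and feature
    columns; variants whose required components are missing (NaN) get NaN
    predictions and are counted in the log.
    """
    preds = np.full(len(features), np.nan)
    n_missing = 0
    for i, (_, row) in enumerate(features.iterrows()):
        comps = DDGunComponents(
            **{name: float(row[col]) if pd.notna(row[col]) else None
               for name, col in component_map.items()}
        )
        try:
            preds[i] = ddgun_score(comps, weights, variant)
        except ValueError:
            n_missing += 1
    if n_missing:
        logger.info("%d variants without a %s score", n_missing, variant.value)
    return pd.Series(preds, index=features.index, name=f"ddgun_{variant.value}")


# ---------------------------------------------------------------------------
# Random-Forest ablation
# ---------------------------------------------------------------------------


@dataclass
class RegressorConfig:
    """Random-Forest ablation settings.

    ``per_class`` defaults to half the smallest class of the training pool,
    mirroring the balanced-resampling rule used for the correlation
    analyses.  Hyperparameters are library defaults unless overridden; they
    are serialized into the result metadata.
    """

    n_subsets: int = 100
    per_class: int | None = None
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)


def _leakage_guard(train: pd.DataFrame, test: pd.DataFrame) -> None:
    tkeys = set(map(tuple, train[KEY_COLUMNS].itertuples(index=False)))
    skeys = set(map(tuple, test[KEY_COLUMNS].itertuples(index=False)))
    shared = tkeys & skeys
    if shared:
        raise ValueError(
            f"train/test leakage: {len(shared)} shared variant keys, e.g. {sorted(shared)[:3]}"
        )


@dataclass
class AblationResult:
    """Results of one ablation run."""

    metrics: pd.DataFrame
    per_model_spread: pd.DataFrame
    predictions: pd.DataFrame
    metadata: dict


def run_rf_ablation(
    train: pd.DataFrame,
    test: pd.DataFrame,
    sets: Sequence[FeatureSetSpec] = tuple(FeatureSetSpec),
    cfg: RegressorConfig = RegressorConfig(),
) -> AblationResult:
    """Train balanced-subsample Random Forests per feature set; evaluate on test.

    For each feature set, ``cfg.n_subsets`` models are fitted, each on a
    balanced subsample of the training pool (``cfg.per_class`` per class,
    drawn without replacement).  Test-set metrics are computed on the
    per-variant mean prediction across models; the per-model spread of the
    total Pearson/RMSE is reported alongside.  Train and test must be
    disjoint on variant keys.
    """
    _leakage_guard(train, test)
    per_class = cfg.per_class or half_smallest_class(train["stability_class"])
    if per_class < 2:
        raise ValueError("training pool too small for balanced subsampling")
    spec = ResampleSpec(n_subsets=cfg.n_subsets, per_class=per_class, seed=cfg.seed)

    metric_frames, spread_rows = [], []
    pred_table = test[KEY_COLUMNS + ["ddg_exp", "stability_class"]].copy()
    test_exp = test["ddg_exp"].to_numpy(dtype=float)
    test_cls = test["stability_class"].to_list()

    for fset in sets:
        cols = fset.feature_columns
        train_ok = train.dropna(subset=cols + ["ddg_exp"])
        X_test = test[cols].to_numpy(dtype=float)
        classes = train_ok["stability_class"].to_list()
        all_preds = np.empty((cfg.n_subsets, len(test)))
        per_model_rho = []
        for m, rng in enumerate(spec.child_rngs()):
            idx = balanced_subsample(classes, per_class, rng)
            sub = train_ok.iloc[idx]
            model = RandomForestRegressor(
                random_state=int(rng.integers(2**31 - 1)), **cfg.hyperparameters
            )
            model.fit(sub[cols].to_numpy(dtype=float), sub["ddg_exp"].to_numpy(dtype=float))
            assert model.n_features_in_ == len(cols)
            all_preds[m] = model.predict(X_test)
            row = stratified_metrics(test_exp, all_preds[m], test_cls)
            per_model_rho.append(
                (row.loc[row.stratum == "Total", "pearson"].item(),
                 row.loc[row.stratum == "Total", "rmse"].item())
            )
        mean_pred = all_preds.mean(axis=0)
        pred_table[f"rf_{fset.value}"] = mean_pred
        frame = stratified_metrics(test_exp, mean_pred, test_cls)
        frame.insert(0, "feature_set", fset.value)
        frame.insert(0, "predictor", "RandomForest")
        metric_frames.append(frame)
        rhos = np.array([r for r, _ in per_model_rho])
        rmses = np.array([e for _, e in per_model_rho])
        spread_rows.append(
            {"feature_set": fset.value,
             "total_pearson_mean": rhos.mean(), "total_pearson_std": rhos.std(ddof=1),
             "total_rmse_mean": rmses.mean(), "total_rmse_std": rmses.std(ddof=1)}
        )
        logger.info("RF %s: ensemble total rho=%.3f", fset.value,
                    frame.loc[frame.stratum == "Total", "pearson"].item())

    metadata = {
        "model": "RandomForestRegressor",
        "hyperparameters": dict(cfg.hyperparameters),
        "n_subsets": cfg.n_subsets,
        "per_class": per_class,
        "seed": cfg.seed,
        "aggregation": "metrics on per-variant mean prediction",
    }
    return AblationResult(
        metrics=pd.concat(metric_frames, ignore_index=True),
        per_model_spread=pd.DataFrame(spread_rows),
        predictions=pred_table,
        metadata=metadata,
    )


def ablation_report(
    train: pd.DataFrame,
    test: pd.DataFrame,
    cfg: RegressorConfig = RegressorConfig(),
    weights: DDGunWeights = DDGunWeights(),
) -> tuple[pd.DataFrame, AblationResult]:
    """Six-row ablation table: linear scorer and RF, each in three variants.

    Rows carry Pearson/RMSE for the Total / Destabilizing / Neutral /
    Stabilizing / Non-neutral strata of the test set.
    """
    frames = []
    for fset in FeatureSetSpec:
        preds = score_dataset_ddgun(test, fset, weights)
        frame = stratified_metrics(
            test["ddg_exp"].to_numpy(dtype=float), preds.to_numpy(), test["stability_class"]
        )
        frame.insert(0, "feature_set", fset.value)
        frame.insert(0, "predictor", "DDGun3D")
        frames.append(frame)
    rf = run_rf_ablation(train, test, tuple(FeatureSetSpec), cfg)
    table = pd.concat(frames + [rf.metrics], ignore_index=True)
    return table, rf
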