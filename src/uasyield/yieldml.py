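"""Ensemble-tree grain-yield regression on the fused feature table.

The feature table has one row per plot and, in the default
configuration, exactly 60 feature columns: 48 radiometric (2 dates x
[canopy cover + 12 band statistics + 11 vegetation indices]) and 12
geometric (3 sources x [canopy volume, maximum height, and their
within-plot variation percentages]).  Two regressors are supported —
a bagged random forest and gradient-boosted trees — with fixed
hyperparameters (1000 trees, depth 5; boosting uses learning rate 0.06
and subsample 0.8) and a fixed random state throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from xgboost import XGBRegressor

from uasyield.canopy3d import RGB_FEATURE_NAMES, rgb_feature_columns
from uasyield.errors import (
    IntegrityError,
    NumericDomainError,
    ParameterError,
    SplitError,
)
from uasyield.triples import msi_feature_columns

ALGORITHMS = ("forest", "boost")


@dataclass
class ModelConfig:
    """Hyperparameters of the ensemble-tree regressors.

    Depth 5 is applied to both algorithms; the boosting library's own
    default would be 6, but the shallower setting is used uniformly to
    curb model complexity.
    """

    algorithm: str = "forest"
    n_trees: int = 1000
    max_depth: int = 5
    learning_rate: float = 0.06     # boosting only
    subsample: float = 0.8          # boosting only
    test_fraction: float = 0.15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"algorithm must be one of {ALGORITHMS}")
        if not 0 < self.test_fraction < 1:
            raise ParameterError("test_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")


@dataclass
class FitResult:
    """Fitted model with predictions, importances and headline metrics."""

    config: ModelConfig
    model: object
    feature_names: list[str]
    importance: pd.Series           # normalised, sums to 1
    pred_train: pd.Series
    pred_test: pd.Series
    act_train: pd.Series
    act_test: pd.Series
    acc_pct: float                  # signed, predicted-value denominator
    acc_abs_pct: float              # absolute-error variant
    mae_kg_ha: float


# ---------------------------------------------------------------------------
# table assembly and split
# ---------------------------------------------------------------------------

MSI_SOURCES = ("DAP61", "DAP70")
RGB_SOURCES = ("DAP61", "DAP70", "INC")


def feature_columns(
    msi_dates: tuple[str, ...] = MSI_SOURCES,
    rgb_sources: tuple[str, ...] = RGB_SOURCES,
) -> list[str]:
    """The default 60-column model feature schema."""
    cols = [f"{c}@{d}" for d in msi_dates for c in msi_feature_columns()]
    return cols + rgb_feature_columns(rgb_sources)


def assemble_feature_table(
    msi_by_date: dict[str, pd.DataFrame],
    rgb_feats: pd.DataFrame,
    yields: pd.DataFrame,
) -> pd.DataFrame:
    """Inner-join all per-plot feature sources with the yield target.

    ``msi_by_date`` maps a date tag to a frame of radiometric features
    keyed by ``plot_id``; ``rgb_feats`` is long-form with columns
    ``plot_id, source, CV_dm3, Hmax_cm, CVvar_pct, Hmaxvar_pct``;
    ``yields`` has ``plot_id, family, yield_kg_ha``.  Plots missing
    from any source are dropped (the caller may log them); duplicate
    plot ids are an integrity error.
    """
    for name, df in {"yields": yields, "rgb": rgb_feats, **msi_by_date}.items():
        key = ["plot_id", "source"] if name == "rgb" and "source" in df.columns else ["plot_id"]
        if df.duplicated(subset=key).any():
            raise IntegrityError(f"duplicate plot_id in {name} features")

    table = yields[["plot_id", "family", "yield_kg_ha"]].copy()
    for date, df in msi_by_date.items():
        renamed = df.set_index("plot_id").add_suffix(f"@{date}")
        table = table.join(renamed, on="plot_id", how="inner")
    if "source" in rgb_feats.columns:
        wide = rgb_feats.pivot(index="plot_id", columns="source", values=list(RGB_FEATURE_NAMES))
        wide.columns = [f"{feat}@{src}" for feat, src in wide.columns]
        table = table.join(wide, on="plot_id", how="inner")
    else:
        table = table.join(rgb_feats.set_index("plot_id"), on="plot_id", how="inner")
    table = table.dropna()
    return table.reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame, test_fraction: float = 0.15, seed: int = 42
) -> pd.DataFrame:
    """Random, reproducible train/test assignment.

    The test count is ``round(n * test_fraction)`` (round-half-even);
    840 plots at 15% give 714 train and 126 test.
    """
    n = len(table)
    if n == 0:
        raise SplitError("empty table")
    n_test = round(n * test_fraction)
    if test_fraction > 0 and n_test < 1:
        raise SplitError(f"test fraction {test_fraction} selects no plots of {n}")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    split = np.full(n, "train", dtype=object)
    split[idx[:n_test]] = "test"
    out = table.copy()
    out["split"] = split
    return out


# ---------------------------------------------------------------------------
# fitting and metrics
# ---------------------------------------------------------------------------


def _make_model(config: ModelConfig):
    if config.algorithm == "forest":
        return RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
    return XGBRegressor(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        subsample=config.subsample,
        random_state=config.seed,
        n_jobs=1,
        verbosity=0,
    )


def fit_model(
    config: ModelConfig,
    table: pd.DataFrame,
    features: list[str] | None = None,
    target: str = "yield_kg_ha",
) -> FitResult:
    """Fit one regressor on the train rows and score it on the test rows."""
    if "split" not in table.columns:
        raise ParameterError("assign the split before fitting (split_train_test)")
    features = features or [c for c in feature_columns() if c in table.columns]
    x = table[features].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise NumericDomainError("non-finite feature values")
    y = table[target].to_numpy(dtype=float)
    train = (table["split"] == "train").to_numpy()
    test = ~train

    model = _make_model(config)
    model.fit(x[train], y[train])
    imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    pred_train = model.predict(x[train])
    pred_test = model.predict(x[test])
    return FitResult(
        config=config,
        model=model,
        feature_names=list(features),
        importance=pd.Series(imp, index=features).sort_values(ascending=False),
        pred_train=pd.Series(pred_train, index=table.index[train]),
        pred_test=pd.Series(pred_test, index=table.index[test]),
        act_train=pd.Series(y[train], index=table.index[train]),
        act_test=pd.Series(y[test], index=table.index[test]),
        acc_pct=accuracy(pred_test, y[test]),
        acc_abs_pct=accuracy(pred_test, y[test], absolute=True),
        mae_kg_ha=float(np.mean(np.abs(pred_test - y[test]))),
    )


def accuracy(pred, act, absolute: bool = False) -> float:
    """Test-set accuracy: 100 minus the mean percent deviation.

    As defined, the deviation of each plot is ``(pred - act) / pred``
    (predicted-value denominator) and is *signed*, so errors of
    opposite sign cancel and the statistic is not bounded above by 100.
    ``absolute=True`` computes the absolute-deviation variant
    ``100 - mean(100 * |pred - act| / pred)``, which is bounded by 100
    and reduces to the signed form for one-sided errors.
    """
    pred = np.asarray(pred, dtype=float)
    act = np.asarray(act, dtype=float)
    if pred.shape != act.shape:
        raise ParameterError("pred and act must have the same length")
    if np.any(pred == 0):
        raise NumericDomainError("zero predicted value in accuracy denominator")
    dev = (pred - act) / pred
    if absolute:
        dev = np.abs(dev)
    return float(100.0 - 100.0 * dev.mean())


def feature_importance_report(
    fit: FitResult, cumulative: float = 0.71
) -> pd.DataFrame:
    """Features ranked by importance, flagging the head of the ranking.

    The minimal prefix whose cumulative importance reaches ``cumulative``
    is marked ``in_head`` — the subset one would plot when asking which
    features carry most of the model.
    """
    imp = fit.importance
    cum = imp.cumsum()
    head_len = int(np.searchsorted(cum.to_numpy(), cumulative) + 1)
    head_len = min(head_len, len(imp))
    return pd.DataFrame(
        {
            "feature": imp.index,
            "importance": imp.to_numpy(),
            "cumulative": cum.to_numpy(),
            "in_head": np.arange(len(imp)) < head_len,
        }
    )


# ---------------------------------------------------------------------------
# ablations
# ---------------------------------------------------------------------------


def default_subsets(columns: list[str]) -> dict[str, list[str]]:
    """The sensor and date ablation subsets of the 60-feature schema."""
    msi = [c for c in columns if not c.split("@")[0] in RGB_FEATURE_NAMES]
    rgb = [c for c in columns if c.split("@")[0] in RGB_FEATURE_NAMES]
    d61 = [c for c in columns if c.endswith("@DAP61")]
    d70 = [c for c in columns if c.endswith("@DAP70")]
    return {"RGB_only": rgb, "MSI_only": msi, "DAP61_only": d61, "DAP70_only": d70}


def ablation_study(
    table: pd.DataFrame,
    config: ModelConfig,
    subsets: dict[str, list[str]] | None = None,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Refit on feature subsets and report test MAE change vs the full model.

    Uses the split already present in ``table`` so every run sees the
    same plots.  ``features`` defines the full-model baseline (defaults
    to the standard 60-column schema).  Returns one row per subset with
    the MAE and its percent change relative to the full model.
    """
    all_feats = features or [c for c in feature_columns() if c in table.columns]
    subsets = subsets if subsets is not None else default_subsets(all_feats)
    if any(len(v) == 0 for v in subsets.values()):
        raise ParameterError("empty ablation subset")
    full = fit_model(config, table, features=all_feats)
    rows = [
        {"subset": "full", "n_features": len(all_feats), "mae_kg_ha": full.mae_kg_ha,
         "mae_change_pct": 0.0}
    ]
    for name, feats in subsets.items():
        fit = fit_model(config, table, features=feats)
        rows.append(
            {
                "subset": name,
                "n_features": len(feats),
                "mae_kg_ha": fit.mae_kg_ha,
                "mae_change_pct": 100.0 * (fit.mae_kg_ha - full.mae_kg_ha) / full.mae_kg_ha,
            }
        )
    return pd.DataFrame(rows)
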