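"""Gridded soil d15N prediction from point samples and covariates.

Point soil d15N measurements (natural, non-agricultural sites, 0-50 cm pooled
— depth shows no systematic effect in that range) are regressed on gridded
environmental covariates; missing ancillary values are gap-filled from the
gridded fields at the sample location.  The regressor family is pluggable: a
small feed-forward network by default, gradient-boosted trees as an
alternative.  Per-cell prediction uncertainty is the standard deviation of a
bootstrap ensemble of regressors refitted on resampled training sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .grid import GridField

__all__ = ["IsoscapeConfig", "IsoscapeModel", "gapfill_ancillary",
           "fit_isoscape", "predict_isoscape"]

DEFAULT_COVARIATES = ("MAT", "MAP", "WFPS", "bulk_density", "soil_N", "pH", "aridity")


@dataclass(frozen=True)
class IsoscapeConfig:
    covariates: tuple = DEFAULT_COVARIATES
    regressor: str = "mlp"          # "mlp" | "gbt"
    n_bootstrap: int = 50
    hidden_layers: tuple = (16, 8)
    max_iter: int = 500
    holdout_fraction: float = 0.2
    min_samples: int = 50
    seed: int = 0


def _make_regressor(config: IsoscapeConfig, seed: int):
    if config.regressor == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=config.hidden_layers,
                         max_iter=config.max_iter, random_state=seed),
        )
    if config.regressor == "gbt":
        return GradientBoostingRegressor(random_state=seed)
    raise ValueError(f"unknown regressor family {config.regressor!r}")


@dataclass
class IsoscapeModel:
    """Fitted regressor plus its bootstrap ensemble and diagnostics."""

    estimator: object
    ensemble: list
    covariates: tuple
    diagnostics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


def gapfill_ancillary(samples: pd.DataFrame, covariate_fields: dict) -> pd.DataFrame:
    """Fill missing ancillary values from the gridded fields at each sample.

    Adds a boolean ``filled_<name>`` column per covariate and an
    ``outside_grid`` flag; samples outside every grid are flagged and meant
    to be excluded by the caller (fit_isoscape drops them).
    """
    out = samples.copy()
    any_grid = next(iter(covariate_fields.values())).grid
    i, j, inside = any_grid.cell_index(out["lat"].to_numpy(), out["lon"].to_numpy())
    out["outside_grid"] = ~inside
    for name, fld in covariate_fields.items():
        if name not in out.columns:
            out[name] = np.nan
        vals = out[name].to_numpy(dtype=float)
        missing = ~np.isfinite(vals)
        fillable = missing & inside
        gridded = np.full(len(out), np.nan)
        gridded[inside] = np.where(fld.mask[i[inside], j[inside]],
                                   fld.values[i[inside], j[inside]], np.nan)
        vals[fillable] = gridded[fillable]
        out[name] = vals
        out[f"filled_{name}"] = fillable & np.isfinite(vals)
    return out


def fit_isoscape(samples: pd.DataFrame, config: IsoscapeConfig = IsoscapeConfig(),
                 target: str = "d15n") -> IsoscapeModel:
    """Fit the d15N regressor with hold-out diagnostics and a bootstrap ensemble."""
    cols = list(config.covariates)
    df = samples.dropna(subset=cols + [target])
    if "outside_grid" in df.columns:
        df = df[~df["outside_grid"]]
    if len(df) < config.min_samples:
        raise ValueError(f"need >= {config.min_samples} complete samples, "
                         f"got {len(df)}")
    for c in cols:
        if df[c].std(ddof=0) == 0:
            raise ValueError(f"covariate {c!r} has zero variance")
    X = df[cols].to_numpy(dtype=float)
    y = df[target].to_numpy(dtype=float)
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        X, y, test_size=config.holdout_fraction, random_state=config.seed)
    est = _make_regressor(config, config.seed)
    est.fit(X_tr, y_tr)
    pred = est.predict(X_ho)
    ss_res = float(np.sum((y_ho - pred) ** 2))
    ss_tot = float(np.sum((y_ho - y_ho.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan

    rng = np.random.default_rng(config.seed)
    ensemble = []
    for b in range(config.n_bootstrap):
        idx = rng.integers(0, len(X), size=len(X))
        member = _make_regressor(config, config.seed + 1 + b)
        member.fit(X[idx], y[idx])
        ensemble.append(member)
    return IsoscapeModel(estimator=est, ensemble=ensemble,
                         covariates=tuple(cols),
                         diagnostics={"r2_holdout": r2, "n_train": len(X_tr),
                                      "n_holdout": len(X_ho)})


def predict_isoscape(model: IsoscapeModel, covariate_fields: dict) -> GridField:
    """Per-cell mean prediction with bootstrap-ensemble SD as 1-sigma."""
    missing = [c for c in model.covariates if c not in covariate_fields]
    if missing:
        raise ValueError(f"missing covariate fields: {missing}")
    fields = [covariate_fields[c] for c in model.covariates]
    grid = fields[0].grid
    mask = np.logical_and.reduce([f.mask for f in fields])
    X = np.column_stack([f.values[mask] for f in fields])
    mean = np.full(grid.shape, np.nan)
    mean[mask] = model.predict(X)
    sigma = np.zeros(grid.shape)
    if len(model.ensemble) > 1:
        preds = np.stack([m.predict(X) for m in model.ensemble])
        sigma[mask] = preds.std(axis=0, ddof=0)
    return GridField(grid, mean, "permil", sigma=sigma, mask=mask)
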