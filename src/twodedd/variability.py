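"""Intrinsic spot variability: bootstrap fold quantiles and threshold model.

How large a fold change can appear between two groups of control replicates
by chance alone? Per spot, we resample two pseudo-groups with replacement
from the control replicates, record the orientation-free ratio of their
means (max/min, always >= 1), and take an upper quantile of the resulting
null fold distribution — the spot's intrinsic variability. A Gaussian
model of log quantile on log mean volume and gel position then smooths
these noisy per-spot estimates into spot-specific significance thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocessing import CONTROL, SpotTable

logger = logging.getLogger(__name__)

_PREDICTORS = ["const", "log_mean_volume", "x", "y"]


@dataclass
class BootstrapSettings:
    n_boot: int = 1000
    subgroup_sizes: tuple[int, int] = (7, 7)
    quantile: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if min(self.subgroup_sizes) < 2:
            raise ValueError("subgroup sizes must be >= 2")
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be strictly between 0 and 1")


def bootstrap_fold_quantile(control_volumes, settings: BootstrapSettings) -> float:
    """Upper quantile of the null fold distribution of one spot.

    Draws two pseudo-groups of sizes ``settings.subgroup_sizes`` with
    replacement from the control replicates, forms max(m1,m2)/min(m1,m2) of
    the pseudo-group means, repeats ``n_boot`` times and returns the
    ``quantile`` empirical quantile (linear/type-7 interpolation).
    Deterministic under the settings seed.
    """
    v = np.asarray(control_volumes, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 control replicates")
    if (v <= 0).any():
        raise ValueError("control volumes must be strictly positive")
    rng = np.random.default_rng(settings.seed)
    folds = _null_folds(v, settings, rng)
    return float(np.quantile(folds, settings.quantile))


def _null_folds(v: np.ndarray, settings: BootstrapSettings, rng) -> np.ndarray:
    s1, s2 = settings.subgroup_sizes
    m1 = v[rng.integers(0, v.size, size=(settings.n_boot, s1))].mean(axis=1)
    m2 = v[rng.integers(0, v.size, size=(settings.n_boot, s2))].mean(axis=1)
    return np.maximum(m1, m2) / np.minimum(m1, m2)


@dataclass
class VariabilityProfile:
    """Per-spot bootstrap quantiles plus the fitted threshold model.

    ``table`` is indexed by spot_id with columns q95, log_mean_volume, x,
    y, predicted_threshold. ``coefficients``/``stderr`` are indexed by
    const, log_mean_volume, x, y (zero for dropped terms when fitted
    intercept-only).
    """

    table: pd.DataFrame
    coefficients: pd.Series
    stderr: pd.Series
    residual_deviance: float
    n: int
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.table["q95"] < 1).any():
            raise ValueError("bootstrap quantiles must be >= 1")
        if (self.table["predicted_threshold"] < 1).any():
            raise ValueError("predicted thresholds must be >= 1")


def bootstrap_profile_table(table: SpotTable, settings: BootstrapSettings,
                            control_group: str = CONTROL) -> pd.DataFrame:
    """Per-spot (q95, log mean control volume, x, y) records for the GLM.

    Spots with a non-positive control volume carry no usable fold
    information and are excluded with a warning. Each spot gets its own RNG
    substream keyed by (seed, spot position), so results do not depend on
    which other spots are present.
    """
    vols = table.group_volumes(control_group).to_numpy()
    rows = []
    for i, spot in enumerate(table.spot_ids):
        v = vols[i]
        if (v <= 0).any():
            logger.warning("spot %s excluded: non-positive control volume", spot)
            continue
        rng = np.random.default_rng([settings.seed, i])
        q = float(np.quantile(_null_folds(v, settings, rng), settings.quantile))
        rows.append(
            {
                "spot_id": spot,
                "q95": q,
                "log_mean_volume": np.log(v.mean()),
                "x": table.spots.at[spot, "x"],
                "y": table.spots.at[spot, "y"],
            }
        )
    return pd.DataFrame(rows).set_index("spot_id")


def fit_threshold_glm(spots: pd.DataFrame, intercept_only: bool = False) -> VariabilityProfile:
    """Fit log(q95) ~ log mean volume + x + y (Gaussian) and predict thresholds.

    ``spots`` needs columns q95, log_mean_volume, x, y. Predicted
    thresholds are exp(fitted value) floored at 1. A rank-deficient design
    (e.g. constant volumes) raises unless ``intercept_only`` is set.
    """
    if len(spots) < 10:
        raise ValueError("need at least 10 spots to fit the threshold model")
    if (spots["q95"] < 1).any():
        raise ValueError("all q95 values must be >= 1")
    y = np.log(spots["q95"].to_numpy())
    if intercept_only:
        X = pd.DataFrame({"const": np.ones(len(spots))}, index=spots.index)
    else:
        X = sm.add_constant(spots[["log_mean_volume", "x", "y"]], has_constant="add")
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            raise ValueError(
                "rank-deficient design (constant predictor?); "
                "refit with intercept_only=True for a flat threshold"
            )
    # Gaussian identity-link GLM == OLS; OLS is robust to a degenerate
    # (constant) response, which a perfectly flat q95 field produces
    fit = sm.OLS(y, X).fit()
    coef = pd.Series(0.0, index=_PREDICTORS)
    se = pd.Series(np.nan, index=_PREDICTORS)
    coef[list(X.columns)] = fit.params
    se[list(X.columns)] = fit.bse
    thresholds = np.maximum(1.0, np.exp(np.asarray(fit.fittedvalues)))
    out = spots.copy()
    out["predicted_threshold"] = thresholds
    return VariabilityProfile(
        table=out,
        coefficients=coef,
        stderr=se,
        residual_deviance=float(fit.ssr),
        n=len(spots),
        diagnostics={"df_resid": float(fit.df_resid)},
    )


def predict_thresholds(profile: VariabilityProfile, spots: pd.DataFrame) -> pd.Series:
    """Thresholds max(1, exp(linear predictor)) for new spot records.

    ``spots`` needs columns log_mean_volume, x, y (index = spot_id).
    """
    c = profile.coefficients
    lp = (
        c["const"]
        + c["log_mean_volume"] * spots["log_mean_volume"]
        + c["x"] * spots["x"]
        + c["y"] * spots["y"]
    )
    return np.maximum(1.0, np.exp(lp)).rename("predicted_threshold")


def compute_variability_profile(
    table: SpotTable,
    settings: BootstrapSettings,
    control_group: str = CONTROL,
    intercept_only: bool = False,
) -> VariabilityProfile:
    """Bootstrap every spot, fit the threshold model, predict thresholds."""
    records = bootstrap_profile_table(table, settings, control_group)
    return fit_threshold_glm(records, intercept_only=intercept_only)
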