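"""Differential expression calls and pilot power analysis.

A spot is called differentially expressed only when two independent
criteria agree: its Welch test survives Benjamini–Hochberg FDR control at
``alpha``, *and* its orientation-free fold change exceeds the spot's
predicted intrinsic-variability threshold. Candidates are then optionally
re-checked against a reference (wild-type) line: same direction and a
one-tailed Welch p below alpha. Power utilities answer the pilot question
"how many replicates buy power 0.8 at fold 2 for most spots?" via the
noncentral t distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .preprocessing import CONTROL, KNOCKDOWN, WILDTYPE, SpotTable
from .variability import VariabilityProfile

logger = logging.getLogger(__name__)


# -- elementary statistics --------------------------------------------------


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


def welch_test(group_a, group_b, tails: str = "two") -> WelchResult:
    """Welch's unequal-variance t-test of mean(a) vs mean(b).

    ``tails="one"`` orients the alternative by the observed sign, i.e.
    halves the two-tailed p. When both groups are exactly constant the test
    is degenerate: equal constants give p = 1 by convention, different
    constants p = 0.
    """
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return WelchResult(float(t), float(a.size + b.size - 2), 0.0)
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2 * stats.t.sf(abs(t), df)
    if tails == "one":
        p /= 2
    return WelchResult(float(t), float(df), float(p))


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(control_mean: float, knockdown_mean: float) -> float:
    """Knockdown/control mean ratio; < 1 means down in the knockdown."""
    if control_mean <= 0 or knockdown_mean <= 0:
        raise ValueError("group means must be strictly positive")
    return knockdown_mean / control_mean


# -- selection --------------------------------------------------------------


@dataclass
class DEResult:
    """Per-spot fold changes, Welch/FDR statistics and selection flags."""

    table: pd.DataFrame
    alpha: float
    scale: str
    excluded: list[str] = field(default_factory=list)

    @property
    def selected_ids(self) -> pd.Index:
        return self.table.index[self.table["selected"]]

    @property
    def validated_ids(self) -> pd.Index:
        if "validated" not in self.table.columns:
            return pd.Index([])
        return self.table.index[self.table["validated"]]

    def summary(self) -> dict:
        t = self.table
        out = {
            "spots_tested": int(len(t)),
            "spots_excluded": len(self.excluded),
            "fdr_only": int(t["passes_fdr"].sum()),
            "selected": int(t["selected"].sum()),
            "up": int((t["selected"] & (t["direction"] == "up")).sum()),
            "down": int((t["selected"] & (t["direction"] == "down")).sum()),
        }
        if "validated" in t.columns:
            out["validated"] = int(t["validated"].sum())
        return out


def select_differential(
    table: SpotTable,
    profile: VariabilityProfile,
    alpha: float = 0.05,
    scale: str = "log",
    control_group: str = CONTROL,
    knockdown_group: str = KNOCKDOWN,
) -> DEResult:
    """Dual-criterion differential-expression calls for every testable spot.

    Fold change is the ratio of raw group mean volumes (knockdown/control);
    the Welch test runs on log volumes by default (``scale="raw"`` tests
    untransformed volumes). ``passes_fdr`` is BH-adjusted p <= alpha;
    ``passes_threshold`` requires max(fold, 1/fold) to strictly exceed the
    spot's predicted threshold (so a fold of exactly 1 can never pass,
    thresholds being floored at 1); ``selected`` requires both. Spots containing a non-positive
    volume in either tested group are excluded and listed in
    ``DEResult.excluded``.
    """
    if scale not in ("log", "raw"):
        raise ValueError("scale must be 'log' or 'raw'")
    if not table.normalized:
        logger.warning("selecting on a table not flagged as normalized")
    ctrl = table.group_volumes(control_group)
    kd = table.group_volumes(knockdown_group)

    ok = (ctrl.min(axis=1) > 0) & (kd.min(axis=1) > 0)
    excluded = list(table.spot_ids[~ok])
    for spot in excluded:
        logger.warning("spot %s excluded from testing: non-positive volume", spot)
    ids = table.spot_ids[ok]

    thr = profile.table["predicted_threshold"]
    missing = [s for s in ids if s not in thr.index]
    if missing:
        raise ValueError(f"no predicted threshold for spots: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))

    ca = ctrl.loc[ids].to_numpy()
    ka = kd.loc[ids].to_numpy()
    fold = ka.mean(axis=1) / ca.mean(axis=1)
    ta, ka_ = (np.log(ca), np.log(ka)) if scale == "log" else (ca, ka)

    rows = np.empty((len(ids), 3))
    for i in range(len(ids)):
        res = welch_test(ka_[i], ta[i], tails="two")
        rows[i] = (res.t, res.df, res.p)
    p_fdr = adjust_fdr(rows[:, 2])

    thr_v = thr.loc[ids].to_numpy()
    out = pd.DataFrame(
        {
            "fold": fold,
            "welch_t": rows[:, 0],
            "welch_df": rows[:, 1],
            "p_raw": rows[:, 2],
            "p_fdr": p_fdr,
            "threshold": thr_v,
            "passes_fdr": p_fdr <= alpha,
            "passes_threshold": np.maximum(fold, 1 / fold) > thr_v,
            "direction": np.where(fold > 1, "up", "down"),
        },
        index=ids,
    )
    out["selected"] = out["passes_fdr"] & out["passes_threshold"]
    return DEResult(table=out, alpha=alpha, scale=scale, excluded=excluded)


def validate_against_reference(
    de: DEResult,
    table: SpotTable,
    reference_group: str = WILDTYPE,
    knockdown_group: str = KNOCKDOWN,
    scale: str | None = None,
) -> DEResult:
    """Re-test selected spots against an independent reference line.

    A selected spot is validated when the knockdown-vs-reference fold goes
    the same way as the knockdown-vs-control fold and the one-tailed Welch
    p is <= the selection alpha. Selected spots without usable reference
    volumes are left unvalidated with a warning.
    """
    scale = scale or de.scale
    ref = table.group_volumes(reference_group)
    kd = table.group_volumes(knockdown_group)
    out = de.table.copy()
    out["validated"] = False
    out["p_reference"] = np.nan
    for spot in de.selected_ids:
        r = ref.loc[spot].to_numpy()
        k = kd.loc[spot].to_numpy()
        if (r <= 0).any() or (k <= 0).any():
            logger.warning("spot %s: no usable reference volumes; left unvalidated", spot)
            continue
        ref_fold = k.mean() / r.mean()
        same_direction = (ref_fold > 1) == (out.at[spot, "fold"] > 1)
        tk, tr = (np.log(k), np.log(r)) if scale == "log" else (k, r)
        res = welch_test(tk, tr, tails="one")
        out.at[spot, "p_reference"] = res.p
        out.at[spot, "validated"] = bool(same_direction and res.p <= de.alpha)
    return DEResult(table=out, alpha=de.alpha, scale=de.scale, excluded=list(de.excluded))


# -- power / sample size ----------------------------------------------------


@dataclass
class PowerSettings:
    alpha: float = 0.05
    target_power: float = 0.8
    folds: tuple[float, ...] = (2.0, 1.5)
    n_grid: tuple[int, ...] = tuple(range(2, 13))

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if any(f <= 1 for f in self.folds):
            raise ValueError("folds must exceed 1")
        if not self.n_grid:
            raise ValueError("n_grid must be non-empty")
        if min(self.n_grid) < 2:
            raise ValueError("n_grid values must be >= 2")


def _nct_lower_tail(tcrit, df, nc):
    """P(T < -tcrit) for noncentral t; scipy emits spurious NaN in this
    vanishing tail at large noncentrality, which we clamp to 0."""
    return np.nan_to_num(stats.nct.cdf(-tcrit, df, nc), nan=0.0)


@lru_cache(maxsize=64)
def _welch_quadrature(n: int, alpha: float, order: int = 80):
    """Precompute variance nodes/weights and critical values for exact Welch power.

    Per-group sample variances are chi2_{n-1}/(n-1)-distributed; integrate
    the conditional rejection probability over both with generalized
    Gauss-Laguerre quadrature.
    """
    k = (n - 1) / 2
    x, w = special.roots_genlaguerre(order, k - 1)
    w = w / special.gamma(k)
    s2 = 2 * x / (n - 1)
    sa, sb = np.meshgrid(s2, s2, indexing="ij")
    wa, wb = np.meshgrid(w, w, indexing="ij")
    pooled = (sa + sb) / 2
    df = (n - 1) * (sa + sb) ** 2 / (sa**2 + sb**2)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return np.sqrt(pooled), crit, wa * wb


def spot_power(
    log_sd: float, n_per_group: int, fold: float, alpha: float = 0.05, test: str = "student"
) -> float:
    """Power of a two-sided two-sample t-test on log volumes.

    Effect size d = log(fold)/log_sd, equal group size n. ``test="student"``
    is the classical noncentral-t power (df = 2n - 2, noncentrality
    d*sqrt(n/2)) as used for pilot sample-size planning; ``test="welch"``
    is the exact power of the Welch test under equal true variances,
    obtained by quadrature over both group variances — slightly below the
    classical value at small n because the Welch test is conservative
    there.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if log_sd <= 0:
        raise ValueError("log_sd must be > 0")
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if test not in ("student", "welch"):
        raise ValueError("test must be 'student' or 'welch'")
    d = abs(np.log(fold)) / log_sd
    nc = d * np.sqrt(n_per_group / 2)
    if test == "student":
        df = 2 * n_per_group - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        return float(stats.nct.sf(tcrit, df, nc) + _nct_lower_tail(tcrit, df, nc))
    sqrt_w, crit, weight = _welch_quadrature(n_per_group, alpha)
    reject = stats.norm.cdf(nc - crit * sqrt_w) + stats.norm.cdf(-nc - crit * sqrt_w)
    return float((reject * weight).sum())


@dataclass
class PowerProfile:
    """Fractions of spots reaching the target power over an (n, fold) grid."""

    table: pd.DataFrame  # columns: n, fold, fraction
    settings: PowerSettings
    recommended_n: dict[float, int | None] = field(default_factory=dict)

    def fraction(self, n: int, fold: float) -> float:
        t = self.table
        row = t[(t["n"] == n) & (t["fold"] == fold)]
        if not len(row):
            raise KeyError((n, fold))
        return float(row["fraction"].iloc[0])


def sample_size_profile(
    per_spot_log_sd,
    settings: PowerSettings,
    coverage_goal: float | None = None,
) -> PowerProfile:
    """For each (n, fold): fraction of spots whose power meets the target.

    With a ``coverage_goal``, also reports per fold the smallest n whose
    fraction reaches the goal (None when no n in the grid does).
    """
    sds = np.asarray(per_spot_log_sd, dtype=float)
    if sds.size == 0:
        raise ValueError("per_spot_log_sd must not be empty")
    if (sds <= 0).any():
        raise ValueError("per-spot log sds must be positive")
    rows = []
    for n in settings.n_grid:
        for fold in settings.folds:
            d = np.log(fold) / sds
            df = 2 * n - 2
            nc = d * np.sqrt(n / 2)
            tcrit = stats.t.ppf(1 - settings.alpha / 2, df)
            power = stats.nct.sf(tcrit, df, nc) + _nct_lower_tail(tcrit, df, nc)
            rows.append(
                {"n": n, "fold": fold, "fraction": float((power >= settings.target_power).mean())}
            )
    table = pd.DataFrame(rows)
    recommended: dict[float, int | None] = {}
    if coverage_goal is not None:
        for fold in settings.folds:
            sub = table[(table["fold"] == fold) & (table["fraction"] >= coverage_goal)]
            recommended[fold] = int(sub["n"].min()) if len(sub) else None
    return PowerProfile(table=table, settings=settings, recommended_n=recommended)
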