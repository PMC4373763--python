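"""Synthetic spot-volume tables and MS hit lists with known ground truth.

Volumes follow a log-normal law. The spread of log volume for spot *i* at
unit-square position (x, y) with log mean volume ``m`` is

    sd_i = cv_intercept * exp(cv_slope_logvolume * m
                              + cv_coeff_x * x + cv_coeff_y * y)

so on the log scale the relative SD trends log-linearly with abundance and
drifts smoothly across the gel — the structure the threshold model
downstream is designed to capture. Knockdown gels of spiked spots have
their log mean shifted by log(fold); a wild-type reference group, when
requested, shares the control means.

Every generator is deterministic under its seed: per-spot substreams are
derived from ``(seed, spot_index)`` counters, so any subset of spots is
reproducible independently of the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import CONTROL, KNOCKDOWN, WILDTYPE, SpotTable
from .deconvolution import SpotHitList


@dataclass
class SimulationConfig:
    n_spots: int = 2000
    n_replicates_per_group: int = 7
    groups: tuple[str, ...] = (CONTROL, KNOCKDOWN)
    log_volume_mean_range: tuple[float, float] = (4.0, 12.0)
    cv_intercept: float = 0.9
    cv_slope_logvolume: float = -0.15
    cv_coeff_x: float = 0.1
    cv_coeff_y: float = 0.1
    spiked_spots: tuple = ()
    gradient_label: str = "4-7"
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spots < 1:
            raise ValueError("n_spots must be >= 1")
        if self.n_replicates_per_group < 2:
            raise ValueError("n_replicates_per_group must be >= 2")
        if self.cv_intercept <= 0:
            raise ValueError("cv_intercept must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        lo, hi = self.log_volume_mean_range
        if not lo <= hi:
            raise ValueError("log_volume_mean_range must be (lo, hi) with lo <= hi")
        seen = set()
        for spike in self.spiked_spots:
            idx, fold = spike[0], spike[1]
            if not 0 <= idx < self.n_spots:
                raise ValueError(f"spiked spot index {idx} out of range")
            if idx in seen:
                raise ValueError(f"spiked spot index {idx} duplicated")
            seen.add(idx)
            if fold <= 0:
                raise ValueError(f"spiked fold must be > 0, got {fold}")
            if len(spike) > 2 and spike[2] not in ("up", "down"):
                raise ValueError(f"spike direction must be 'up' or 'down', got {spike[2]!r}")


@dataclass
class GroundTruth:
    """Per-spot generating parameters; non-spiked spots have true fold 1."""

    table: pd.DataFrame  # index spot_id: true_log_mean, true_fold, true_log_sd

    def __post_init__(self) -> None:
        if (self.table["true_fold"] <= 0).any():
            raise ValueError("true folds must be positive")

    @property
    def spiked_ids(self) -> pd.Index:
        return self.table.index[self.table["true_fold"] != 1.0]


def _effective_fold(spike) -> float:
    fold = float(spike[1])
    if len(spike) > 2 and spike[2] == "down" and fold > 1:
        fold = 1.0 / fold
    return fold


def log_sd_profile(config: SimulationConfig, log_mean, x, y):
    """Per-spot SD of log volume implied by the config's CV model."""
    return config.cv_intercept * np.exp(
        config.cv_slope_logvolume * np.asarray(log_mean)
        + config.cv_coeff_x * np.asarray(x)
        + config.cv_coeff_y * np.asarray(y)
    )


def generate_spot_table(config: SimulationConfig) -> tuple[SpotTable, GroundTruth]:
    """Draw a spots x gels volume table plus its generating ground truth."""
    n = config.n_spots
    fold_of = {s[0]: _effective_fold(s) for s in config.spiked_spots}

    gels: list[str] = []
    group_of_gel: dict[str, str] = {}
    for grp in config.groups:
        for r in range(1, config.n_replicates_per_group + 1):
            gel = f"{grp}_{r}"
            gels.append(gel)
            group_of_gel[gel] = grp

    lo, hi = config.log_volume_mean_range
    n_gels = len(gels)
    volumes = np.empty((n, n_gels))
    xs = np.empty(n)
    ys = np.empty(n)
    log_means = np.empty(n)
    sds = np.empty(n)
    folds = np.ones(n)

    kd_mask = np.array([group_of_gel[g] == KNOCKDOWN for g in gels])
    for i in range(n):
        rng = np.random.default_rng([config.seed, i])
        xs[i] = rng.uniform()
        ys[i] = rng.uniform()
        log_means[i] = rng.uniform(lo, hi)
        sds[i] = log_sd_profile(config, log_means[i], xs[i], ys[i])
        folds[i] = fold_of.get(i, 1.0)
        mu = np.where(kd_mask, log_means[i] + np.log(folds[i]), log_means[i])
        volumes[i] = np.exp(rng.normal(mu, sds[i]))
        if config.dropout_rate > 0:
            volumes[i] *= rng.uniform(size=n_gels) >= config.dropout_rate

    ids = pd.Index([f"s{i:05d}" for i in range(n)], name="spot_id")
    spots = pd.DataFrame({"x": xs, "y": ys, "gradient": config.gradient_label}, index=ids)
    vol_df = pd.DataFrame(volumes, index=ids, columns=gels)
    truth = GroundTruth(
        pd.DataFrame(
            {"true_log_mean": log_means, "true_fold": folds, "true_log_sd": sds},
            index=ids,
        )
    )
    return SpotTable(spots=spots, volumes=vol_df, group_of_gel=group_of_gel), truth


# -- MS hit tables ----------------------------------------------------------


def generate_hit_tables(
    spot_composition: list[tuple[str, int, float]],
    condition_effect: dict[str, float] | None,
    total_spectra: int,
    seed: int,
    spot_id: str = "spot",
    high_score_frac: float = 0.7,
) -> tuple[SpotHitList, SpotHitList]:
    """Simulate control/knockdown hit lists for one (possibly mixed) spot.

    ``spot_composition`` lists (accession, sequence length, molar share);
    shares must sum to 1. Spectra are allocated multinomially with
    probability proportional to share x length (longer proteins yield more
    spectra) times the per-protein ``condition_effect`` multiplier in the
    knockdown draw. Ion scores are a mixture: with probability
    ``high_score_frac`` uniform on (41, 80), else uniform on (5, 40), so
    generated hits usually — but not always — clear the confidence rule.
    """
    if not spot_composition:
        raise ValueError("spot_composition must not be empty")
    accs = [c[0] for c in spot_composition]
    lengths = np.array([c[1] for c in spot_composition], dtype=float)
    shares = np.array([c[2] for c in spot_composition], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("protein lengths must be positive")
    if not np.isclose(shares.sum(), 1.0):
        raise ValueError("shares must sum to 1")
    if total_spectra < 1:
        raise ValueError("total_spectra must be >= 1")
    effect = np.array([(condition_effect or {}).get(a, 1.0) for a in accs])

    rng = np.random.default_rng(seed)
    out = []
    for cond, weight in ((CONTROL, shares * lengths), (KNOCKDOWN, shares * lengths * effect)):
        counts = rng.multinomial(total_spectra, weight / weight.sum())
        entries = []
        for acc, length, c in zip(accs, lengths, counts):
            high = rng.uniform(size=c) < high_score_frac
            scores = np.where(high, rng.uniform(41, 80, size=c), rng.uniform(5, 40, size=c))
            uniq = int(rng.integers(1, c + 1)) if c > 0 else 0
            entries.append(
                {
                    "accession": acc,
                    "length": int(length),
                    "spectra": int(c),
                    "unique_peptides": uniq,
                    "ion_scores": [round(float(s), 2) for s in scores],
                }
            )
        out.append(SpotHitList(spot_id=spot_id, condition=cond, entries=pd.DataFrame(entries)))
    return out[0], out[1]
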