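"""Spot-volume tables: I/O, total-volume normalization and QC summaries.

The central object is :class:`SpotTable`, a spots x gels matrix of
(optionally normalized) volumes together with gel coordinates on the unit
square and a gel -> group assignment. Gel columns are named
``<group>_<replicate>`` so the grouping is recoverable from the CSV header
alone.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical group labels
CONTROL = "control"
KNOCKDOWN = "knockdown"
WILDTYPE = "wildtype"

_META_COLUMNS = ["spot_id", "x", "y", "gradient"]


class SpotTableError(ValueError):
    """Raised for malformed spot tables (parse or validation failures)."""


def _group_of(gel: str) -> str:
    if "_" not in gel:
        raise SpotTableError(
            f"gel column {gel!r} does not follow the <group>_<replicate> naming"
        )
    return gel.rsplit("_", 1)[0]


@dataclass
class SpotTable:
    """Spots x gels volume matrix with per-spot gel coordinates.

    Parameters
    ----------
    spots : pandas.DataFrame
        Indexed by ``spot_id``; columns ``x``, ``y`` (unit-square
        coordinates) and ``gradient`` (IPG label, e.g. ``"4-7"``).
    volumes : pandas.DataFrame
        Indexed by ``spot_id``; one column per gel, named
        ``<group>_<replicate>``. Non-negative.
    group_of_gel : dict
        Gel column name -> group label. Derived from column names when
        omitted.
    normalized : bool
        Whether gel columns have been scaled to a common total volume.
    """

    spots: pd.DataFrame
    volumes: pd.DataFrame
    group_of_gel: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.group_of_gel:
            self.group_of_gel = {g: _group_of(g) for g in self.volumes.columns}
        if self.spots.index.has_duplicates:
            dup = self.spots.index[self.spots.index.duplicated()][0]
            raise SpotTableError(f"duplicate spot_id {dup!r}")
        if not self.spots.index.equals(self.volumes.index):
            raise SpotTableError("spots and volumes indices differ")
        missing = [g for g in self.volumes.columns if g not in self.group_of_gel]
        if missing:
            raise SpotTableError(f"gels without group assignment: {missing}")
        vals = self.volumes.to_numpy()
        if np.isnan(vals).any():
            raise SpotTableError("volume matrix contains missing values")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise SpotTableError(
                f"negative volume at spot {self.volumes.index[r]!r}, "
                f"gel {self.volumes.columns[c]!r}"
            )

    # -- accessors ---------------------------------------------------------

    @property
    def spot_ids(self) -> pd.Index:
        return self.volumes.index

    @property
    def gels(self) -> list[str]:
        return list(self.volumes.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.volumes.columns:
            seen.setdefault(self.group_of_gel[g], None)
        return list(seen)

    def gels_in_group(self, group: str) -> list[str]:
        return [g for g in self.volumes.columns if self.group_of_gel[g] == group]

    def group_volumes(self, group: str) -> pd.DataFrame:
        """Volume sub-matrix (spots x replicate gels) for one group."""
        gels = self.gels_in_group(group)
        if not gels:
            raise SpotTableError(f"no gels in group {group!r}")
        return self.volumes[gels]

    def copy(self) -> "SpotTable":
        return replace(
            self,
            spots=self.spots.copy(),
            volumes=self.volumes.copy(),
            group_of_gel=dict(self.group_of_gel),
        )


@dataclass
class NormalizationReport:
    """Per-gel scale factors plus pre/post five-number log10 summaries."""

    scale_factors: pd.Series
    summary_pre: pd.DataFrame
    summary_post: pd.DataFrame
    flagged_gels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.scale_factors <= 0).any():
            raise SpotTableError("scale factors must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        out = self.summary_post.copy()
        out.insert(0, "scale_factor", self.scale_factors)
        out["flagged"] = out.index.isin(self.flagged_gels)
        return out


# -- CSV dialect ------------------------------------------------------------


def write_spot_table(table: SpotTable, path, header_comments: dict | None = None) -> None:
    """Write the tidy CSV dialect: ``#`` metadata lines, then the matrix."""
    meta = {"normalized": str(table.normalized).lower()}
    if header_comments:
        meta.update({k: str(v) for k, v in header_comments.items()})
    df = table.spots[["x", "y", "gradient"]].join(table.volumes)
    df.index.name = "spot_id"
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh)


def read_spot_table(path) -> SpotTable:
    """Read a spot-table CSV written by :func:`write_spot_table`.

    Raises :class:`SpotTableError` naming the offending row/column on
    malformed headers, duplicate spot ids or negative volumes.
    """
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, dtype={"spot_id": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise SpotTableError(f"missing required columns: {missing}")
    if df["spot_id"].duplicated().any():
        dup = df.loc[df["spot_id"].duplicated(), "spot_id"].iloc[0]
        raise SpotTableError(f"duplicate spot_id {dup!r}")
    df = df.set_index("spot_id")
    gel_cols = [c for c in df.columns if c not in ("x", "y", "gradient")]
    if not gel_cols:
        raise SpotTableError("no gel volume columns found")
    volumes = df[gel_cols].astype(float)
    bad = np.argwhere(volumes.to_numpy() < 0)
    if bad.size:
        r, c = bad[0]
        raise SpotTableError(
            f"negative volume at spot {volumes.index[r]!r}, gel {gel_cols[c]!r}"
        )
    return SpotTable(
        spots=df[["x", "y", "gradient"]].copy(),
        volumes=volumes,
        normalized=meta.get("normalized", "false") == "true",
    )


# -- normalization ----------------------------------------------------------


def _five_number(volumes: pd.DataFrame) -> pd.DataFrame:
    """Per-gel min/Q1/median/Q3/max of log10 volumes (positive entries only)."""
    rows = {}
    for gel in volumes.columns:
        v = volumes[gel].to_numpy()
        v = v[v > 0]
        lv = np.log10(v)
        rows[gel] = {
            "min": lv.min(),
            "q1": np.quantile(lv, 0.25),
            "median": np.quantile(lv, 0.5),
            "q3": np.quantile(lv, 0.75),
            "max": lv.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def normalize_total_volume(table: SpotTable) -> tuple[SpotTable, NormalizationReport]:
    """Scale each gel column so all column sums equal the mean pre-scale total.

    Idempotent: re-normalizing an already-normalized table yields unit
    factors. Within-gel spot proportions are preserved exactly.
    """
    totals = table.volumes.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise SpotTableError(f"gel {zero.index[0]!r} has zero total volume")
    target = totals.mean()
    factors = target / totals
    pre = _five_number(table.volumes)
    volumes = table.volumes * factors
    post = _five_number(volumes)
    out = replace(table, spots=table.spots.copy(), volumes=volumes, normalized=True)
    return out, NormalizationReport(scale_factors=factors, summary_pre=pre, summary_post=post)


def boxplot_summary(table: SpotTable, iqr_multiplier: float = 1.5) -> NormalizationReport:
    """Five-number summary of per-gel log10 volumes with outlier-gel flags.

    A gel is flagged when its median log10 volume deviates from the pooled
    median by more than ``iqr_multiplier`` times the pooled IQR — the
    programmatic stand-in for eyeballing box-plot agreement across gels.
    """
    if not table.normalized:
        raise SpotTableError("boxplot_summary expects a normalized table")
    summary = _five_number(table.volumes)
    pooled = table.volumes.to_numpy().ravel()
    pooled = np.log10(pooled[pooled > 0])
    grand_median = np.quantile(pooled, 0.5)
    grand_iqr = np.quantile(pooled, 0.75) - np.quantile(pooled, 0.25)
    dev = (summary["median"] - grand_median).abs()
    flagged = list(summary.index[dev > iqr_multiplier * grand_iqr])
    for gel in flagged:
        logger.warning("gel %s flagged: median deviates %.3f log10 units", gel, dev[gel])
    ones = pd.Series(1.0, index=table.volumes.columns)
    return NormalizationReport(
        scale_factors=ones, summary_pre=summary, summary_post=summary, flagged_gels=flagged
    )


def relative_expression(band_intensity: float, total_protein_stain: float) -> float:
    """Blot band intensity relative to the lane's total protein stain."""
    if band_intensity < 0:
        raise ValueError("band intensity must be non-negative")
    if not math.isfinite(total_protein_stain) or total_protein_stain <= 0:
        raise ValueError("total protein stain must be strictly positive")
    return band_intensity / total_protein_stain
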