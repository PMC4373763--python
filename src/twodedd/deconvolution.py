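"""Mixed-spot deconvolution from MS hit lists.

Spots cut from a gel frequently contain several comigrating proteins, so a
regulated spot volume does not by itself say *which* protein moved. This
module filters hit lists by the spectrum-score confidence rule, computes
length-normalized spectral abundance (NSAF) per protein within each spot,
and compares control vs knockdown abundance per protein to decide whether
the spot's regulation can be pinned on a protein (concordant), contradicts
it (discordant, blot needed) or cannot be resolved (single-sample, blot
needed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# verdict labels
CONCORDANT = "concordant_regulated"
DISCORDANT = "discordant_flag_wb"
SINGLE_SAMPLE = "single_sample_flag_wb"
UNCHANGED = "unchanged"

_ENTRY_COLUMNS = ["accession", "length", "spectra", "unique_peptides", "ion_scores"]


def confident_hit(ion_scores) -> bool:
    """Score rule: >=3 spectra scoring above 20, or >=2 scoring above 40."""
    scores = np.asarray(list(ion_scores), dtype=float)
    if scores.size == 0:
        return False
    if not np.isfinite(scores).all():
        raise ValueError("ion scores must be finite")
    return bool((scores > 20).sum() >= 3 or (scores > 40).sum() >= 2)


@dataclass
class SpotHitList:
    """Per-spot, per-condition protein identifications.

    ``entries`` columns: accession, length (residues), spectra (matched
    MS/MS count), unique_peptides, ion_scores (list of per-spectrum
    scores); ``nsaf`` column added by :func:`compute_nsaf`.
    """

    spot_id: str
    condition: str
    entries: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.entries) and self.entries["accession"].duplicated().any():
            dup = self.entries.loc[self.entries["accession"].duplicated(), "accession"].iloc[0]
            raise ValueError(f"duplicate accession {dup!r} in hit list")
        if len(self.entries) and (self.entries["length"] <= 0).any():
            raise ValueError("protein lengths must be positive")

    def filter_confident(self) -> "SpotHitList":
        if not len(self.entries):
            return self
        keep = self.entries["ion_scores"].map(confident_hit)
        return replace(self, entries=self.entries[keep].reset_index(drop=True))

    @property
    def accessions(self) -> set[str]:
        return set(self.entries["accession"]) if len(self.entries) else set()


def compute_nsaf(hits: SpotHitList) -> SpotHitList:
    """Attach NSAF: per-entry (spectra/length) normalized to sum to 1.

    Zero-spectra entries get NSAF 0; a list with no positive count carries
    no abundance information and is rejected.
    """
    if not len(hits.entries):
        raise ValueError(f"empty hit list for spot {hits.spot_id!r}")
    entries = hits.entries.copy()
    saf = entries["spectra"].to_numpy(dtype=float) / entries["length"].to_numpy(dtype=float)
    total = saf.sum()
    if total <= 0:
        raise ValueError(f"all-zero spectral counts in spot {hits.spot_id!r}")
    entries["nsaf"] = saf / total
    return replace(hits, entries=entries)


@dataclass
class SpotTriage:
    """Per-accession verdicts for one spot, given its gel regulation."""

    spot_id: str
    direction: str  # "up" or "down" on the gel
    verdicts: dict[str, str]
    details: pd.DataFrame = field(default_factory=pd.DataFrame)


def _nsaf_map(hits: SpotHitList, pseudocount: float) -> dict[str, float]:
    """accession -> NSAF, with zero counts replaced by a pseudocount."""
    e = hits.entries
    saf = e["spectra"].to_numpy(dtype=float)
    saf = np.where(saf == 0, pseudocount, saf) / e["length"].to_numpy(dtype=float)
    nsaf = saf / saf.sum()
    return dict(zip(e["accession"], nsaf))


def triage_spot(
    control_hits: SpotHitList,
    knockdown_hits: SpotHitList,
    spot_direction: str,
    min_ratio: float = 1.5,
    pseudocount: float = 0.5,
) -> SpotTriage:
    """Classify each confident protein of a spot against the gel direction.

    For accessions confident in both conditions the knockdown/control NSAF
    ratio is compared with ``min_ratio``: change in the spot's direction is
    ``concordant_regulated``, change in the opposite direction is
    ``discordant_flag_wb``, anything in between ``unchanged``. Accessions
    confident in only one condition cannot be ratioed; the major
    (highest-NSAF) such hit per condition is flagged for Western blot.
    """
    if spot_direction not in ("up", "down"):
        raise ValueError("spot_direction must be 'up' or 'down'")
    if min_ratio <= 1:
        raise ValueError("min_ratio must be > 1")
    if not len(control_hits.entries) and not len(knockdown_hits.entries):
        raise ValueError(f"both hit lists empty for spot {control_hits.spot_id!r}")

    ctrl_nsaf = _nsaf_map(control_hits, pseudocount) if len(control_hits.entries) else {}
    kd_nsaf = _nsaf_map(knockdown_hits, pseudocount) if len(knockdown_hits.entries) else {}
    shared = set(ctrl_nsaf) & set(kd_nsaf)

    verdicts: dict[str, str] = {}
    rows = []
    for acc in sorted(shared):
        ratio = kd_nsaf[acc] / ctrl_nsaf[acc]
        if (ratio >= min_ratio and spot_direction == "up") or (
            ratio <= 1 / min_ratio and spot_direction == "down"
        ):
            verdict = CONCORDANT
        elif ratio >= min_ratio or ratio <= 1 / min_ratio:
            verdict = DISCORDANT
        else:
            verdict = UNCHANGED
        verdicts[acc] = verdict
        rows.append({"accession": acc, "nsaf_ratio": ratio, "verdict": verdict})

    for nsaf_of in (ctrl_nsaf, kd_nsaf):
        only = {a: v for a, v in nsaf_of.items() if a not in shared}
        if only:
            major = max(only, key=only.get)
            for acc in only:
                verdicts[acc] = SINGLE_SAMPLE if acc == major else UNCHANGED
                rows.append(
                    {"accession": acc, "nsaf_ratio": np.nan, "verdict": verdicts[acc]}
                )

    return SpotTriage(
        spot_id=control_hits.spot_id,
        direction=spot_direction,
        verdicts=verdicts,
        details=pd.DataFrame(rows),
    )


def wb_worklist(triages: list[SpotTriage]) -> pd.DataFrame:
    """Collect every blot-flagged (spot, accession) pair with its reason."""
    rows = []
    for tri in triages:
        for acc, verdict in tri.verdicts.items():
            if verdict in (DISCORDANT, SINGLE_SAMPLE):
                rows.append({"spot_id": tri.spot_id, "accession": acc, "reason": verdict})
    df = pd.DataFrame(rows, columns=["spot_id", "accession", "reason"])
    return df.drop_duplicates(subset=["spot_id", "accession"]).reset_index(drop=True)


# -- TSV I/O ----------------------------------------------------------------


def write_hit_tables(hit_lists: list[SpotHitList], path) -> None:
    """TSV: spot_id, condition, accession, length, spectra, unique_peptides,
    ion_scores (semicolon-joined)."""
    rows = []
    for hl in hit_lists:
        for _, e in hl.entries.iterrows():
            rows.append(
                {
                    "spot_id": hl.spot_id,
                    "condition": hl.condition,
                    "accession": e["accession"],
                    "length": e["length"],
                    "spectra": e["spectra"],
                    "unique_peptides": e["unique_peptides"],
                    "ion_scores": ";".join(f"{s:g}" for s in e["ion_scores"]),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_hit_tables(path) -> list[SpotHitList]:
    df = pd.read_csv(path, sep="\t", dtype={"spot_id": str, "ion_scores": str})
    df["ion_scores"] = df["ion_scores"].fillna("")
    out = []
    for (spot, cond), grp in df.groupby(["spot_id", "condition"], sort=False):
        entries = grp[["accession", "length", "spectra", "unique_peptides"]].copy()
        entries["ion_scores"] = [
            [float(s) for s in row.split(";") if s] for row in grp["ion_scores"]
        ]
        out.append(
            SpotHitList(spot_id=spot, condition=cond, entries=entries.reset_index(drop=True))
        )
    return out
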