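"""End-to-end orchestration: simulate/load -> normalize -> thresholds ->
differential calls -> reference validation -> spot deconvolution.

One top-level seed fans out to deterministic stage seeds, so a whole run is
reproduced by a single number; every stage writes its output under the run
directory and the provenance record captures config, derived seeds and
library versions. Stage outputs are identical to running the corresponding
CLI subcommands by hand with the derived seeds (there is no hidden state).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .preprocessing import (
    CONTROL,
    KNOCKDOWN,
    WILDTYPE,
    SpotTable,
    boxplot_summary,
    normalize_total_volume,
    read_spot_table,
    write_spot_table,
)
from .simulate import SimulationConfig, generate_spot_table
from .variability import BootstrapSettings, compute_variability_profile
from .diffexpr import PowerSettings, sample_size_profile, select_differential, validate_against_reference
from .deconvolution import compute_nsaf, read_hit_tables, triage_spot, wb_worklist

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    spot_table: str | None = None
    simulate: SimulationConfig | None = None
    hit_table: str | None = None
    normalize_method: str = "total-volume"
    bootstrap: BootstrapSettings = field(default_factory=BootstrapSettings)
    power: PowerSettings | None = None
    alpha: float = 0.05
    scale: str = "log"
    reference_group: str | None = WILDTYPE
    min_ratio: float = 1.5
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.spot_table is None and self.simulate is None:
            raise ValueError("config needs either a spot_table path or a simulate section")
        for path in (self.spot_table, self.hit_table):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"input path does not exist: {path}")

    @classmethod
    def from_dict(cls, raw: dict, out_dir: str | None = None, seed: int | None = None) -> "RunConfig":
        raw = dict(raw)
        if out_dir is not None:
            raw["out_dir"] = out_dir
        if seed is not None:
            raw["seed"] = seed
        if isinstance(raw.get("simulate"), dict):
            sim = dict(raw["simulate"])
            if "spiked_spots" in sim:
                sim["spiked_spots"] = tuple(tuple(s) for s in sim["spiked_spots"])
            if "groups" in sim:
                sim["groups"] = tuple(sim["groups"])
            if "log_volume_mean_range" in sim:
                sim["log_volume_mean_range"] = tuple(sim["log_volume_mean_range"])
            raw["simulate"] = SimulationConfig(**sim)
        if isinstance(raw.get("bootstrap"), dict):
            b = dict(raw["bootstrap"])
            if "subgroup_sizes" in b:
                b["subgroup_sizes"] = tuple(b["subgroup_sizes"])
            raw["bootstrap"] = BootstrapSettings(**b)
        if isinstance(raw.get("power"), dict):
            p = dict(raw["power"])
            if "folds" in p:
                p["folds"] = tuple(p["folds"])
            if "n_grid" in p:
                p["n_grid"] = tuple(p["n_grid"])
            raw["power"] = PowerSettings(**p)
        return cls(**raw)

    def to_dict(self) -> dict:
        def conv(v):
            if dataclasses.is_dataclass(v):
                return dataclasses.asdict(v)
            return v

        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds from the single run seed."""
    state = np.random.SeedSequence(seed).generate_state(2, dtype=np.uint32)
    return {"simulate": int(state[0]), "bootstrap": int(state[1])}


def config_hash(config: RunConfig) -> str:
    """Hash of the analysis-relevant config (output location excluded)."""
    payload = config.to_dict()
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, header: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in header.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full differential-display run; returns the summary dict.

    On a stage failure, partial outputs are kept, a ``FAILED`` marker names
    the stage, and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(config.seed)
    header = {"config_hash": config_hash(config), "seed": config.seed}
    stage = "init"
    try:
        stage = "load"
        if config.spot_table is not None:
            table = read_spot_table(config.spot_table)
        else:
            sim = dataclasses.replace(config.simulate, seed=seeds["simulate"])
            table, truth = generate_spot_table(sim)
            _write_csv(truth.table, out / "ground_truth.csv", header)

        stage = "normalize"
        if config.normalize_method == "total-volume" and not table.normalized:
            table, report = normalize_total_volume(table)
            _write_csv(report.to_frame(), out / "normalization_report.csv", header)
        elif not table.normalized:
            table = dataclasses.replace(table, normalized=True)
        qc = boxplot_summary(table)
        for gel in qc.flagged_gels:
            logger.warning("QC flag: gel %s deviates from pooled distribution", gel)
        write_spot_table(table, out / "spots_normalized.csv", header)

        stage = "variability"
        boot = dataclasses.replace(config.bootstrap, seed=seeds["bootstrap"])
        profile = compute_variability_profile(table, boot)
        _write_csv(profile.table, out / "variability_profile.csv", header)
        (out / "threshold_coefficients.json").write_text(
            json.dumps(
                {
                    "coefficients": profile.coefficients.to_dict(),
                    "stderr": {k: None if pd.isna(v) else v for k, v in profile.stderr.items()},
                    "residual_deviance": profile.residual_deviance,
                    "n": profile.n,
                },
                indent=2,
            )
        )

        stage = "detest"
        de = select_differential(table, profile, alpha=config.alpha, scale=config.scale)
        if config.reference_group and config.reference_group in table.groups:
            stage = "validate"
            de = validate_against_reference(de, table, reference_group=config.reference_group)
        _write_csv(de.table, out / "de_results.csv", header)

        if config.power is not None:
            stage = "power"
            ctrl = table.group_volumes(CONTROL)
            usable = ctrl[(ctrl > 0).all(axis=1)]
            sds = np.log(usable.to_numpy()).std(axis=1, ddof=1)
            prof = sample_size_profile(sds[sds > 0], config.power)
            _write_csv(prof.table.set_index("n"), out / "power_profile.csv", header)

        summary = de.summary()
        summary["n_spots"] = len(table.spot_ids)

        if config.hit_table is not None:
            stage = "deconvolve"
            hits = {(h.spot_id, h.condition): h for h in read_hit_tables(config.hit_table)}
            spot_ids = sorted({k[0] for k in hits})
            triages = []
            directions = de.table["direction"]
            for sid in spot_ids:
                if sid not in directions.index:
                    logger.warning("hit table spot %s absent from DE results; skipped", sid)
                    continue
                ctrl_h = hits.get((sid, CONTROL))
                kd_h = hits.get((sid, KNOCKDOWN))
                if ctrl_h is None or kd_h is None:
                    logger.warning("spot %s lacks one condition's hit list; skipped", sid)
                    continue
                ctrl_h = compute_nsaf(ctrl_h.filter_confident())
                kd_h = compute_nsaf(kd_h.filter_confident())
                triages.append(
                    triage_spot(ctrl_h, kd_h, directions[sid], config.min_ratio, config.pseudocount)
                )
            rows = []
            for tri in triages:
                for acc, verdict in tri.verdicts.items():
                    rows.append(
                        {"spot_id": tri.spot_id, "direction": tri.direction,
                         "accession": acc, "verdict": verdict}
                    )
            _write_csv(pd.DataFrame(rows).set_index("spot_id") if rows else pd.DataFrame(),
                       out / "triage.csv", header)
            worklist = wb_worklist(triages)
            worklist.to_csv(out / "wb_worklist.csv", index=False)
            summary["wb_worklist"] = len(worklist)

        stage = "summary"
        provenance = {
            "config": config.to_dict(),
            "config_hash": header["config_hash"],
            "seed": config.seed,
            "stage_seeds": seeds,
            "versions": {
                "twodedd": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        return summary
    except Exception as exc:  # noqa: BLE001 - marker file then re-raise with stage
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise PipelineError(stage, exc) from exc
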