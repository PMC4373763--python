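import numpy as np
import pandas as pd
import pytest

from twodedd import (
    BootstrapSettings,
    SimulationConfig,
    SpotTable,
    generate_spot_table,
    normalize_total_volume,
)


@pytest.fixture
def small_config():
    return SimulationConfig(
        n_spots=60,
        n_replicates_per_group=7,
        groups=("control", "knockdown", "wildtype"),
        spiked_spots=((0, 2.0), (1, 2.0, "down")),
        cv_intercept=0.6,
        cv_slope_logvolume=-0.1,
        seed=11,
    )


@pytest.fixture
def small_table(small_config):
    table, truth = generate_spot_table(small_config)
    table, _ = normalize_total_volume(table)
    return table, truth


@pytest.fixture
def boot_settings():
    return BootstrapSettings(n_boot=300, subgroup_sizes=(7, 7), quantile=0.95, seed=5)


def make_table(volumes: np.ndarray, groups: list[str], gradient: str = "4-7",
               normalized: bool = False, rng=None) -> SpotTable:
    """Build a SpotTable from a raw (spots x gels) array and per-gel groups."""
    n = volumes.shape[0]
    rng = rng or np.random.default_rng(0)
    counts: dict[str, int] = {}
    gels = []
    for g in groups:
        counts[g] = counts.get(g, 0) + 1
        gels.append(f"{g}_{counts[g]}")
    ids = pd.Index([f"s{i}" for i in range(n)], name="spot_id")
    spots = pd.DataFrame(
        {"x": rng.uniform(size=n), "y": rng.uniform(size=n), "gradient": gradient}, index=ids
    )
    return SpotTable(
        spots=spots,
        volumes=pd.DataFrame(volumes, index=ids, columns=gels),
        normalized=normalized,
    )
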