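"""Shared fixtures: hand-built sighting tables and small simulated studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from socionet.synthetic import PopulationScenario, simulate


def make_records(rows: list[tuple]) -> pd.DataFrame:
    """Build a records frame from (occasion, group, individual[, subarea]) rows."""
    out = []
    for row in rows:
        occ, grp, ind = row[:3]
        sub = row[3] if len(row) > 3 else "SOUTH"
        x = row[4] if len(row) > 4 else 0.0
        y = row[5] if len(row) > 5 else 0.0
        out.append(
            {
                "occasion_id": occ,
                "group_id": grp,
                "individual_id": ind,
                "subarea": sub,
                "x": x,
                "y": y,
            }
        )
    return pd.DataFrame(out)


def day(i: int) -> str:
    """ISO date i days into a nominal study starting 2006-01-01."""
    return (pd.Timestamp("2006-01-01") + pd.Timedelta(int(i), "D")).date().isoformat()


@pytest.fixture(scope="session")
def small_scenario() -> PopulationScenario:
    """Three planted units, strong assortativity, modest survey effort."""
    return PopulationScenario(
        n_individuals=30,
        unit_sizes=(15, 8, 7),
        unit_area_prefs=(
            {"ESTUARY": 0.6, "SOUTH": 0.3, "NORTH": 0.3},
            {"ESTUARY": 0.0, "SOUTH": 0.7, "NORTH": 0.1},
            {"ESTUARY": 0.0, "SOUTH": 0.1, "NORTH": 0.7},
        ),
        unit_centroids=((0.0, 3000.0), (-6000.0, -3000.0), (6000.0, -1000.0)),
        lambda_in=6.0,
        lambda_out=0.6,
        new_group_weight=0.8,
        availability=0.6,
        n_years=5,
        n_occasions=150,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_study(small_scenario):
    return simulate(small_scenario, seed=0)


def null_scenario(n: int = 15, occasions: int = 40, seed: int = 0) -> PopulationScenario:
    """Exchangeable individuals: no units, no gregariousness, no seasonality."""
    return PopulationScenario(
        n_individuals=n,
        unit_sizes=(n,),
        unit_area_prefs=({"ESTUARY": 0.6, "SOUTH": 0.6, "NORTH": 0.6},),
        unit_centroids=((0.0, 0.0),),
        lambda_in=1.0,
        lambda_out=1.0,
        greg_sigma=0.0,
        new_group_weight=1.0,
        availability=1.0,
        n_years=2,
        n_occasions=occasions,
        p_identify=1.0,
        p_transition=0.0,
        field_noise=0.0,
        seed=seed,
    )
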