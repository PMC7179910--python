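"""Shared fixtures: one small synthetic cohort reused across the suite."""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # reference_ephemeris oracle

from dielmove import covariates, ephemeris, synthetic, trajectory

SITE = synthetic.DEFAULT_SITE


@pytest.fixture(scope="session")
def small_cohort() -> synthetic.SyntheticDataset:
    """Four individuals over 35 days (covers a full lunation), mixed
    schedules, default noise."""
    inds = [
        synthetic.IndividualSpec("O1", synthetic.OCELOT_PROFILE,
                                 synthetic.CollarSchedule("continuous")),
        synthetic.IndividualSpec("O2", synthetic.OCELOT_PROFILE,
                                 synthetic.CollarSchedule("lunar_window",
                                                          window_hours=24)),
        synthetic.IndividualSpec("B1", synthetic.BOBCAT_PROFILE,
                                 synthetic.CollarSchedule("continuous")),
        synthetic.IndividualSpec("B2", synthetic.BOBCAT_PROFILE,
                                 synthetic.CollarSchedule("lunar_window",
                                                          window_hours=72)),
    ]
    cfg = synthetic.CohortConfig(individuals=inds, start="2016-05-01",
                                 n_days=35)
    return synthetic.simulate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def true_velocity_table(small_cohort) -> pd.DataFrame:
    return trajectory.true_velocity(small_cohort.gps)


@pytest.fixture(scope="session")
def analysis_table(small_cohort, true_velocity_table) -> pd.DataFrame:
    """Categorized analysis rows from the GPS-derived stream of the shared
    cohort (no accelerometer fusion; fusion has its own fixtures)."""
    lon, lat = SITE
    rec = ephemeris.attribute_ephemeris(true_velocity_table, lon, lat)
    rec = covariates.attach_tmax(rec, small_cohort.weather)
    rec = covariates.standardize_velocity(rec)
    rec = covariates.categorize(rec)
    return rec.rename(columns={"species": "Species"})
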