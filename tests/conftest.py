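import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from phenoflor import FloralCalendar

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_calendar(grid, n_weeks=None, **labels) -> FloralCalendar:
    grid = np.asarray(grid, dtype=np.int64)
    defaults = dict(
        department="Caldas", semester="1st", accession="CX2197", size_class="SS"
    )
    defaults.update(labels)
    return FloralCalendar(
        n_weeks=n_weeks or grid.shape[1],
        plant_ids=tuple(f"P{i + 1:02d}" for i in range(grid.shape[0])),
        counts=grid,
        **defaults,
    )


@pytest.fixture
def calendar_factory():
    return make_calendar


@pytest.fixture
def census_csv(tmp_path):
    """A tiny long-format census CSV writer returning the path."""

    def write(rows, header="department,semester,accession,size_class,plant_id,week,count"):
        path = tmp_path / "census.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return write


def random_small_grid(rng, max_plants=4, max_weeks=6, max_count=3):
    """A calendar grid from the small-calendar space used for oracle checks."""
    n_p = rng.integers(2, max_plants + 1)
    n_w = rng.integers(3, max_weeks + 1)
    return rng.integers(0, max_count + 1, size=(n_p, n_w))
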