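import pandas as pd
import pytest

from etiqh.synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_roster,
    simulate_responses,
)
from etiqh.types import IndicatorSpec, catalog_frame


def make_responses(rows):
    """Build a responses frame from (facility, year, indicator, answer) tuples."""
    return pd.DataFrame(rows, columns=["facility", "year", "indicator", "answer"])


@pytest.fixture(scope="session")
def six_qd_catalog():
    """One binary indicator per quality dimension, all weight 1."""
    return catalog_frame(
        IndicatorSpec(id=f"{s}_001", section=s, weight=1)
        for s in ("QD1", "QD2", "QD3A", "QD4", "QD5", "QD6")
    )


@pytest.fixture(scope="session")
def default_dataset():
    """A full default-sized synthetic dataset, shared across tests."""
    cfg = SyntheticConfig()
    catalog = generate_catalog(cfg, 11)
    roster = generate_roster(cfg, 12)
    responses, truth = simulate_responses(catalog, roster, cfg, 13)
    return cfg, catalog, roster, responses, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for fast unit tests."""
    cfg = SyntheticConfig(
        n_councils=4,
        facilities_per_council=6,
        section_sizes={s: 3 for s in (
            "QD1", "QD2", "QD3A", "QD3B", "QD3C", "QD3D", "QD4", "QD5", "QD6"
        )},
    )
    catalog = generate_catalog(cfg, 21)
    roster = generate_roster(cfg, 22)
    responses, truth = simulate_responses(catalog, roster, cfg, 23)
    return cfg, catalog, roster, responses, truth
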