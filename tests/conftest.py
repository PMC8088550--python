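from pathlib import Path

import pandas as pd
import pytest

from pertpool import ThreePointElicitation

REPO_ROOT = Path(__file__).resolve().parent.parent


@pytest.fixture(scope="session")
def published_table() -> pd.DataFrame:
    """Published per-question summary table (n, mean, median, HDI, bandwidth)."""
    return pd.read_csv(REPO_ROOT / "data" / "published_scenario_summaries.csv")


@pytest.fixture
def worked_example() -> ThreePointElicitation:
    """The worked survey example: lowest 40%, most likely 50%, highest 80%."""
    return ThreePointElicitation(40.0, 50.0, 80.0)
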