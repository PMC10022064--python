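import numpy as np
import pytest

import ebsmr
from ebsmr import synthetic


@pytest.fixture(scope="session")
def small_panel():
    """A compact synthetic panel shared by read-only tests."""
    cfg = ebsmr.default_config(n_municipalities=80, n_prefectures=5, seed=42)
    panel, edges, rates, truth = ebsmr.generate_panel(cfg)
    return {"config": cfg, "panel": panel, "edges": edges, "rates": rates,
            "truth": truth,
            "resources": synthetic.resource_table_from_panel(panel)}


@pytest.fixture(scope="session")
def small_ebsmr(small_panel):
    table = ebsmr.compute_ebsmr_table(small_panel["panel"], small_panel["rates"])
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)
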