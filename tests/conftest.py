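import numpy as np
import pytest

from isosentinel.synthetic import ScenarioSpec, simulate_all


@pytest.fixture(scope="session")
def default_dataset():
    """Default-scale synthetic study (57+1 sources, 101 beetles, 62 turnover)."""
    return simulate_all(ScenarioSpec(seed=101))


@pytest.fixture(scope="session")
def small_dataset():
    """Reduced scenario for fast end-to-end pipeline tests."""
    spec = ScenarioSpec(
        n_sources=12, n_voucher_sites=6, n_vouchers=30, n_pdx_beetles=24,
        turnover_counts=(6, 6, 6, 6, 6, 6),
        time_mu_by_year={2010: np.log(30.0), 2013: np.log(6.0)},
        seed=7,
    )
    return simulate_all(spec)
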