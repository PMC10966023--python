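import pytest

from lpi_cea import BASE_SCENARIO, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_scenario():
    return BASE_SCENARIO


@pytest.fixture(scope="session")
def zeroed_params(params):
    """All clinical transitions switched off: the cohort never leaves PACS."""
    return params.replace(
        p_pacs_pac_lpi=0.0, p_pacs_pac_obs=0.0,
        p_pac_pacg_lpi=0.0, p_pac_pacg_obs=0.0,
        p_pacg_uniblind=0.0, p_uni_biblind=0.0,
        p_pacs_aacc_obs=0.0, p_aacc_pacs_lpiopen=0.0,
        p_pacg_trab_40_49=0.0, p_pacg_trab_50_59=0.0,
    )


def annuity_due(rate: float, horizon: int) -> float:
    """Closed-form sum_{t=0}^{horizon-1} (1+r)^-t."""
    if rate == 0.0:
        return float(horizon)
    v = 1.0 / (1.0 + rate)
    return (1.0 - v**horizon) / (1.0 - v)
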