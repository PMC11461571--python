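import pytest

import aircheck as ac


@pytest.fixture(scope="session")
def default_cfg():
    return ac.default_config()


@pytest.fixture(scope="session")
def campaign(default_cfg):
    """One deterministic synthetic campaign (records, truth)."""
    return ac.generate_campaign(default_cfg, seed=7)


@pytest.fixture(scope="session")
def campaign_records(campaign):
    return campaign[0]


@pytest.fixture()
def campaign_file(campaign_records, tmp_path):
    path = tmp_path / "campaign.csv"
    ac.write_campaign(campaign_records, path)
    return path
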