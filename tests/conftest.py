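import pytest

import tetrahap.synthetic_data as syn


@pytest.fixture(scope="session")
def preset_config():
    return syn.SimConfig.preset("panel-2012", seed=11)


@pytest.fixture(scope="session")
def preset_panel(preset_config):
    return syn.generate_haplotypes(preset_config)


@pytest.fixture(scope="session")
def small_panel():
    """Five-haplotype panel: small enough for exhaustive-oracle comparisons."""
    cfg = syn.SimConfig(
        seed=23,
        n_haplotypes=5,
        amplicon_lengths=(300, 280),
        target_pi=0.02,
        frequencies={"P": 0.35, "Q": 0.25, "R": 0.2, "S": 0.15, "T": 0.05},
    )
    return syn.generate_haplotypes(cfg)
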