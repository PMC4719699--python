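import pytest

from dmrscan import SimulationConfig, generate_cohort, generate_manifest


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 4,000 probes, 12 planted DMRs, 34+34 samples."""
    return SimulationConfig(
        n_probes=4000,
        chromosome_length=4_000_000,
        n_planted_dmrs=12,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    manifest = generate_manifest(small_config)
    beta, detp, sheet, truth = generate_cohort(manifest, small_config)
    return {
        "config": small_config,
        "manifest": manifest,
        "beta": beta,
        "detp": detp,
        "sheet": sheet,
        "truth": truth,
    }
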