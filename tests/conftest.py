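import matplotlib

matplotlib.use("Agg")

import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from isletmorph import GeneratorConfig, generate_donor, config_for_target_beta_pct
from isletmorph.pipeline import run_synthetic_pipeline
from isletmorph.synth import donor_islet_table


@pytest.fixture(scope="session")
def table_donor():
    """Default-scale synthetic donor, fast analytic table mode."""
    donor = generate_donor(GeneratorConfig(seed=1))
    return donor, donor_islet_table(donor)


@pytest.fixture(scope="session")
def rendered_run():
    """Small rendered donor pushed through segmentation end to end."""
    cfg = config_for_target_beta_pct(
        0.7, n_blocks=4, section_size_px=(1536, 1536), seed=7
    )
    report, donor = run_synthetic_pipeline(cfg, table_only=False)
    return report, donor
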