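import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from gbmrs.synthdata import DiseaseSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def demo_config() -> SimulationConfig:
    """A small cohort exercising every simulated structure."""
    return SimulationConfig(
        n_samples=1200,
        n_snps=300,
        n_biomarkers=4,
        n_causal_per_biomarker=15,
        heritability_h2=0.5,
        shared_env_var=0.15,
        n_sibling_pairs=80,
        sex_offset=0.4,
        age_slope=0.02,
        repeat_noise_sd=0.3,
        disease_specs=[
            DiseaseSpec(
                "metabolic",
                {"bm01": 1.0, "bm02": 0.6},
                direct_genetic_weight=0.3,
                noise_var=0.5,
                prevalence=0.15,
            )
        ],
        seed=11,
    )


@pytest.fixture(scope="session")
def demo_cohort(demo_config):
    return simulate_cohort(demo_config)
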