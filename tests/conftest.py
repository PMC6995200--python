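import numpy as np
import pytest

from paleoploidy.pipeline import demo_config, run_pipeline
from paleoploidy.simulate import carrot_like_config, simulate_history


@pytest.fixture(scope="session")
def noloss_clade():
    """Small clade with no fractionation: 3 copies in the reference/outgroup,
    12 in the twice-duplicated target."""
    cfg = carrot_like_config(
        seed=11, n_ancestral_genes=120, n_chromosomes=1,
        ech_sd=0.04, beta_sd=0.04, alpha_sd=0.04, speciation_sd=0.03,
        ech_retention=(1.0, 1.0, 1.0), beta_retention=(1.0, 1.0), alpha_retention=(1.0, 1.0),
    )
    return simulate_history(cfg)


@pytest.fixture(scope="session")
def sharp_clade():
    """Well-separated clade (small Ks spreads) with moderate fractionation,
    used for orthology/event-table recovery checks."""
    cfg = carrot_like_config(
        seed=5, n_ancestral_genes=300, n_chromosomes=1,
        ech_sd=0.05, beta_sd=0.05, alpha_sd=0.04, speciation_sd=0.04,
    )
    return simulate_history(cfg)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full pipeline execution on the bundled demo configuration."""
    outdir = tmp_path_factory.mktemp("demo_pipeline")
    report = run_pipeline(demo_config(seed=17), outdir)
    return report, outdir
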