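import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def two_module_study():
    """17-sample study with two planted 50-gene modules and no noise genes."""
    from ppx.synthetic_data import ModuleSpec, StudySpec, make_study

    spec = StudySpec(
        n_cases=12,
        n_controls=5,
        n_genes=100,
        module_specs=(
            ModuleSpec(size=50, within_correlation=0.8, trait_link="MAP", direction="up"),
            ModuleSpec(size=50, within_correlation=0.8, trait_link="BW", direction="down"),
        ),
        seed=11,
    )
    return make_study(spec)


@pytest.fixture(scope="session")
def de_recovery_study():
    """Study with 30 planted 2-fold DE genes among 500 genes."""
    from ppx.synthetic_data import StudySpec, make_study

    spec = StudySpec(
        n_cases=12,
        n_controls=5,
        n_genes=500,
        module_specs=(),
        noise_sd=0.2,
        n_de_genes=30,
        de_log2fc=1.0,
        seed=7,
    )
    return make_study(spec)
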