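import numpy as np
import pandas as pd
import pytest

from sexregulome.diffacc import DesignSpec, filter_low_accessibility, normalize_log_cpm
from sexregulome.synth import SimConfig, simulate_abc_inputs, simulate_study

STANDARD_COVARIATES = ("sex", "diagnosis", "region", "frip", "gc_content")


@pytest.fixture(scope="session")
def sex_design():
    return DesignSpec(fixed_covariates=STANDARD_COVARIATES, contrast="sex",
                      grouping="individual")


@pytest.fixture(scope="session")
def planted_study():
    """Mid-size study with planted sex/SCZ effects, CRD blocks and TRD groups."""
    cfg = SimConfig(
        n_individuals=80, n_ocrs_autosome=150, n_ocrs_X=40, n_ocrs_Y=6,
        sex_effect_log2fc=1.0, scz_effect_log2fc=0.6,
        sex_scz_effect_correlation=0.6,
        crd_blocks=(("chr1", 8, 0.75), ("chr2", 6, 0.75), ("chr3", 7, 0.75),
                    ("chrX", 6, 0.75), ("chr4", 6, 0.75), ("chr5", 6, 0.75)),
        trd_groups=(((0, 1), 0.5), ((3, 4), 0.5)),
        sex_effect_block_ids=(0, 1, 3, 4), seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def planted_logcpm(planted_study):
    retained = filter_low_accessibility(planted_study.counts, 1.0, 0.25)
    return normalize_log_cpm(planted_study.counts.loc[retained])


@pytest.fixture(scope="session")
def null_study():
    """No planted effects, one region per individual (independent samples)."""
    cfg = SimConfig(n_individuals=100, regions=("ACC",), n_ocrs_autosome=500,
                    n_ocrs_X=0, n_ocrs_Y=0, seed=21)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def abc_inputs():
    return simulate_abc_inputs(SimConfig(seed=4))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
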