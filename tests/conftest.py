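import numpy as np
import pytest

import carriermod as cm


@pytest.fixture(scope="session")
def breast_curve():
    return cm.default_breast_incidence()


@pytest.fixture(scope="session")
def ovarian_curve():
    return cm.default_ovarian_incidence()


@pytest.fixture(scope="session")
def flat_curve():
    """Constant 1%/year hazard on the standard grid."""
    ages = np.arange(18, 81)
    return cm.IncidenceCurve("breast", ages, np.full(len(ages), 0.01))


@pytest.fixture()
def small_cohort(breast_curve):
    """A deterministic 200-carrier ascertained cohort with one causal SNP."""
    cfg = cm.SimConfig(
        n_families=260,
        sibship_size_distribution=(1.0,),
        maf=(0.3,),
        true_log_hr_bc=(np.log(1.4),),
        seed=42,
        missing_rate=0.0,
        ascertainment="proband_affected",
    )
    records, geno, truth = cm.simulate_cohort(cfg)
    return records[:200], geno.subset_samples([r.sample_id for r in records[:200]]), truth
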