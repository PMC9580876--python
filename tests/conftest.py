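import numpy as np
import pytest

from ctdnamrd.calling import NoiseProfile
from ctdnamrd.cohort import CohortConfig
from ctdnamrd.ddpcr import DdpcrAssay, MergedSample
from ctdnamrd.io import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def assay():
    return DdpcrAssay(assay_id="A01", target_label="KRAS_G12V")


@pytest.fixture
def quiet_assay():
    """Assay with zero chemistry noise (mutant droplets only from template)."""
    return DdpcrAssay(assay_id="A00", target_label="clean", fp_rate_per_ge=0.0)


def make_blank(ge, fp, assay_id="A01", n_droplets=17000, sample_id="blank"):
    """Count-level blank sample with a consistent wild-type channel."""
    k_wt = min(int(round(n_droplets * (1 - np.exp(-ge / n_droplets)))),
               n_droplets - 1)
    return MergedSample(sample_id=sample_id, assay_id=assay_id,
                        n_droplets_total=n_droplets, k_mutant_total=fp,
                        k_wildtype_total=k_wt, ge_screened=ge)


def make_sample(k_mutant, ge=12000.0, assay_id="A01", n_droplets=34000,
                plasma_ml=8.0, fraction=0.9, sample_id="S1"):
    k_wt = min(int(round(n_droplets * (1 - np.exp(-ge / n_droplets)))),
               n_droplets - 1)
    return MergedSample(sample_id=sample_id, assay_id=assay_id,
                        n_droplets_total=n_droplets, k_mutant_total=k_mutant,
                        k_wildtype_total=k_wt, ge_screened=ge,
                        plasma_ml=plasma_ml,
                        fraction_eluate_analyzed=fraction)


def simulate_profile(rate, rng, n_blanks=94, ge_median=10000.0,
                     ge_sigma=0.5, assay_id="A01"):
    """Blank panel with Poisson false positives at a known rate."""
    blanks = []
    for i in range(n_blanks):
        ge = float(ge_median * np.exp(ge_sigma * rng.standard_normal()))
        blanks.append((ge, int(rng.poisson(rate * ge))))
    return NoiseProfile(assay_id=assay_id, blanks=tuple(blanks))


@pytest.fixture
def tiny_cohort_config():
    """Small cohort for fast end-to-end runs."""
    return CohortConfig(n_patients=20)


@pytest.fixture
def tiny_run_config(tiny_cohort_config):
    return RunConfig(cohort=tiny_cohort_config, n_assays=2)
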