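import numpy as np
import pytest

from nmropls.cohortsim import CohortConfig, MetaboliteSpec, default_metabolites, simulate_cohort
from nmropls.preproc import bin_cohort, reference_to_lactate, total_sum_normalize


def noiseless_config(seed: int = 0) -> CohortConfig:
    return CohortConfig(noise_sd=0.0, shift_jitter_sd=0.0, amplitude_cv=0.0, seed=seed)


def null_metabolites():
    """Default panel with every group effect removed."""
    return tuple(
        MetaboliteSpec(
            s.name, s.multiplets, s.base_amplitude, {g: 1.0 for g in s.group_multipliers}
        )
        for s in default_metabolites()
    )


def preprocess(spectra):
    referenced = [reference_to_lactate(s) for s in spectra]
    return total_sum_normalize(bin_cohort(referenced))


@pytest.fixture(scope="session")
def default_cohort():
    """One default four-group cohort (n=7, realistic noise), preprocessed."""
    cfg = CohortConfig(seed=11)
    spectra, design, truth = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "spectra": spectra,
        "design": design,
        "truth": truth,
        "norm": preprocess(spectra),
    }


@pytest.fixture(scope="session")
def noiseless_cohort():
    cfg = noiseless_config(seed=4)
    spectra, design, truth = simulate_cohort(cfg)
    return {
        "cfg": cfg,
        "spectra": spectra,
        "design": design,
        "truth": truth,
        "norm": preprocess(spectra),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
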