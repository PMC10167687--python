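import numpy as np
import pytest

import secdiff as sd


@pytest.fixture
def calibration():
    return sd.FractionCalibration(slope=-0.05, intercept=3.0)


@pytest.fixture
def gaussian():
    def make(apex, sigma=2.0, height=1000.0, n=49):
        x = np.arange(1, n + 1, dtype=float)
        return height * np.exp(-0.5 * ((x - apex) / sigma) ** 2)
    return make


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy two-condition cohort used by several module tests."""
    config, shifted = sd.amf_shift_cohort(
        n_proteins=12, n_shifted=3, shift=0.4, noise_cv=0.08, seed=11,
    )
    return sd.simulate(config), shifted


def make_traceset(arrays, protein_of=None, sample_ids=None):
    """Assemble a PeptideTraceSet from {peptide_id: (n_samples, n_fractions)}."""
    pep_ids = list(arrays)
    data = np.stack([np.atleast_2d(np.asarray(arrays[p], dtype=float))
                     for p in pep_ids])
    protein_of = protein_of or {}
    prot_ids = [protein_of.get(p, "PROT1") for p in pep_ids]
    n_samp = data.shape[1]
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n_samp)]
    return sd.PeptideTraceSet(data, pep_ids, prot_ids, sample_ids)
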