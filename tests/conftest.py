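import numpy as np
import pytest

from oligoadapt import StopSchedule, TraitModel


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


@pytest.fixture
def three_locus_model():
    """New-mutation-only scenario: 3 loci, trait adapts from 0 toward 3 gamma.

    theta_bg = 2 Ne mu (d - 1) = 1 with Ne = 1000.
    """
    ne = 1000
    return TraitModel(
        L=3,
        gamma=1.0,
        Ne=ne,
        mu=1.0 / (2 * ne * 2),
        sigma_before=100.0 / ne,
        zopt0=0.0,
        zopt_new=3.0,
    )


@pytest.fixture
def midrange_model():
    """10-locus trait with the ancestral optimum mid-range (d = L/2)."""
    ne = 1000
    return TraitModel(
        L=10,
        gamma=1.0,
        Ne=ne,
        mu=1.0 / (2 * ne * 4),  # theta_bg = 1 with d - 1 = 4
        sigma_before=100.0 / ne,
        zopt0=5.0,
        zopt_new=8.0,
    )


@pytest.fixture
def single_stop():
    return StopSchedule(cz_values=(1.0,), max_generations=500_000)
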