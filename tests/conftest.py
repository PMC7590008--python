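import numpy as np
import pytest

import itcdissolve as itc


@pytest.fixture(scope="session")
def small_schedule() -> itc.InjectionSchedule:
    """Six low-concentration injections with compressed spacing (fast kinetics)."""
    return itc.InjectionSchedule(
        c_inj_mM=30.0, spacing_s=600.0, n_injections=6, null_injection=(2.0, 4.0)
    )


@pytest.fixture(scope="session")
def small_sim(small_schedule):
    """Noiseless, drift-free simulation of the small schedule."""
    return itc.simulate_experiment(small_schedule)


@pytest.fixture(scope="session")
def experiment_a_sim():
    """Noiseless simulation of the full 27-injection titration into solvent."""
    return itc.simulate_experiment(itc.EXPERIMENT_A)


@pytest.fixture(scope="session")
def experiment_a_fit(experiment_a_sim):
    trace, truth = experiment_a_sim
    table, results = itc.fit_series(trace, itc.EXPERIMENT_A)
    return table, results, truth


@pytest.fixture(scope="session")
def noise_sd_2pct(small_sim) -> float:
    """Noise level equal to 2% of the largest peak amplitude of the small sim."""
    trace, _ = small_sim
    return 0.02 * float(np.abs(trace.values).max())


@pytest.fixture
def kinetics_default() -> itc.DissolutionKinetics:
    return itc.DissolutionKinetics(
        A_uJ_per_mM=-2044.0,
        k_per_s=1.0 / 30.0,
        alpha=3.0,
        f_agg=1.0 - 5.0 / 30.0,
        delta_c0_mM=30.0 * 10.0 / 1460.0,
    )
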