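import numpy as np
import pytest

from nanokin import Condition, ErosionScenario, TurbidityCurve

# Published parameter sets used as generating truths throughout the suite
# (enzyme, substrate, temperature): (K_A mL/mg, k_tau 1/min)
TRUTHS = {
    ("Tcur1278", "PCL", 49): (41.1, 122.2e-3),
    ("Tcur0390", "PCL", 49): (96.0, 108.3e-3),
    ("Tcur1278", "PET", 50): (44.4, 4.1e-3),
    ("Tcur0390", "PET", 50): (172.7, 7.0e-3),
    ("Tcur1278", "PET", 55): (24.3, 11.0e-3),
    ("Tcur1278", "PET", 60): (46.9, 11.8e-3),
}
MM_TRUTHS = {  # K_m uM, k_cat 1/s
    "Tcur1278": (88.8, 2.3),
    "Tcur0390": (83.1, 12.4),
}


@pytest.fixture
def rng():
    return np.random.default_rng(20140603)


@pytest.fixture
def pet_scenario_noisefree():
    """PET/50 degC assay at the published parameters, zero noise."""
    K_A, k_tau = TRUTHS[("Tcur1278", "PET", 50)]
    return ErosionScenario(k_tau=k_tau, K_A=K_A, noise_rel=0.0, n_replicates=1, seed=5)


def make_curve(times, turbidity, enzyme_conc=0.02, substrate="PET", temperature=50.0,
               replicate=0):
    return TurbidityCurve(
        times=np.asarray(times, float),
        turbidity=np.asarray(turbidity, float),
        condition=Condition(enzyme_conc=enzyme_conc, substrate=substrate,
                            temperature=temperature, replicate=replicate),
    )
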