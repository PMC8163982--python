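import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from gpcrbias import (SimTruth, NoiseModel, PlateDesign, simulate_panel,
                      simulate_experiment)


@pytest.fixture
def one_phase_truth():
    """Glucagon-like G-protein recruitment truth (pEC50 6.7, k 0.17/min)."""
    return SimTruth(ligand_name="GCG", pathway="mini-Gs", pec50=6.7,
                    emax_frac=1.0, kinetic_model="one_phase", k=0.17)


@pytest.fixture
def rise_fall_truth():
    """Arrestin-like rise-and-fall truth (recruit then dissociate)."""
    return SimTruth(ligand_name="GCG", pathway="barr2", pec50=6.1,
                    emax_frac=1.0, kinetic_model="rise_and_fall",
                    k1=0.05, k2=0.89)


@pytest.fixture
def noiseless_panel(one_phase_truth):
    """One assay, no noise, linear drift only (worst-case for correction)."""
    design = PlateDesign.around_pec50(6.7, n_replicate_assays=1,
                                      technical_replicates=1)
    noise = NoiseModel.noiseless(drift_slope=-0.002)
    return simulate_panel([one_phase_truth], design, noise)


@pytest.fixture
def noisy_panels(one_phase_truth):
    design = PlateDesign.around_pec50(6.7, n_replicate_assays=4)
    noise = NoiseModel(cv_multiplicative=0.05, seed=1234)
    return simulate_experiment([one_phase_truth], design, noise)
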