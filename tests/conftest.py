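import numpy as np
import pytest
import threadpoolctl

# single-threaded linear algebra keeps floating-point reductions, and hence
# seeded pipelines, bit-reproducible across runs
_BLAS_LIMIT = threadpoolctl.threadpool_limits(limits=1)

from fretfold.simulate import (
    ConstantLaw,
    HillLaw,
    KineticScheme,
    Photophysics,
    StateModel,
)


@pytest.fixture
def two_state_model() -> StateModel:
    """U / F_LB apparent efficiencies as in the low-Mg titrations."""
    return StateModel(("U", "F_LB"), (0.32, 0.69), (0.05, 0.05))


@pytest.fixture
def three_state_model() -> StateModel:
    return StateModel(("U", "F_LF", "F_LB"), (0.32, 0.60, 0.69),
                      (0.05, 0.05, 0.05))


@pytest.fixture
def docking_law() -> HillLaw:
    """Ligand-activated U->F_LB docking rate (0.5 mM Mg2+ conditions)."""
    return HillLaw(k_max=1.22, K_D=310.0, n=3.1)


@pytest.fixture
def two_state_scheme(docking_law) -> KineticScheme:
    return KineticScheme(
        states=("U", "F_LB"),
        base_rates=np.zeros((2, 2)),
        ligand_laws={("U", "F_LB"): docking_law,
                     ("F_LB", "U"): ConstantLaw(0.18)},
        condition={"mg_mM": 0.5, "lysine_uM": 300.0},
    )


@pytest.fixture
def noiseless_photophysics() -> Photophysics:
    return Photophysics(noise_sd=0.0, bleach_lifetime=None)
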