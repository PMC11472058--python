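import numpy as np
import pytest

from capassays import binding, synthetic


@pytest.fixture(scope="session")
def reference_params() -> binding.BindingModelParams:
    """Ground-truth model for the reference cap-1 trinucleotide (K_D 42.1 nM)."""
    return binding.BindingModelParams(
        k_as=1000.0 / 42.1, p_act=0.1, f0=1000.0, delta_phi=9000.0, phi_free=10.0)


@pytest.fixture(scope="session")
def reference_protocol() -> binding.TitrationProtocol:
    """Study titration protocol: 1 ul aliquots into 1.4 ml of 0.1 uM protein."""
    aliquots, stocks = synthetic.escalating_stocks(42.1)
    return binding.TitrationProtocol(aliquot_volumes=aliquots, stock_concs=stocks)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
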