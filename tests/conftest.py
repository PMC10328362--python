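import numpy as np
import pytest

import linaprs as lp


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small learnable cohort shared by read-only tests."""
    cfg = lp.SimConfig(n_subjects=200, n_snps=20, n_traits=2, n_causal_per_trait=4,
                       shared_fraction=0.5, heritability=0.5, prevalences=0.3, seed=11)
    geno, eff, phen = lp.simulate_cohort(cfg)
    return cfg, geno, eff, phen


@pytest.fixture()
def tiny_model():
    cfg = lp.MTLModelConfig(n_snps=20, n_traits=2, hidden_sizes=(8, 6, 4))
    return lp.init_model(cfg, seed=3)


def make_constant_attention(model, a0):
    """Pin the final attention layer to the constant map A = a0."""
    last = model.net.layers[-1]
    last.W[...] = 0.0
    last.b[...] = a0
    return model


@pytest.fixture()
def constant_attention_model():
    cfg = lp.MTLModelConfig(n_snps=4, n_traits=2, hidden_sizes=(5, 4, 3))
    model = lp.init_model(cfg, seed=9)
    a0 = np.array([0.5, -1.0, 2.0, 0.25])
    return make_constant_attention(model, a0), a0
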