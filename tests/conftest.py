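import numpy as np
import pytest

from sfcopoly import initial_conformation, make_model


@pytest.fixture(scope="session")
def s_attract_small():
    """N=8, b=4 chain in the S-attract-stronger solvent."""
    return make_model("S-attract-stronger", N=8, b=4, eps_st=-1.0)


@pytest.fixture(scope="session")
def phantom_allS6():
    """Phantom all-S hexamer: 4 eligible angles, no contacts."""
    return make_model("non-selective", N=6, pattern="SSSSSS", phantom=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_valid_conformation(model, seed, n_tries=5000):
    """Grow a self-avoiding chain bond-by-bond (rejection per bead)."""
    from sfcopoly.model import Conformation, random_bond_vector, validate

    rng = np.random.default_rng(seed)
    for _ in range(50):
        x = np.zeros((model.N, 3))
        ok = True
        for i in range(1, model.N):
            for _ in range(n_tries):
                cand = x[i - 1] + random_bond_vector(rng, model.l_min, model.l_max)
                d2 = np.sum((x[: max(i - 1, 0)] - cand) ** 2, axis=1)
                if model.phantom or d2.size == 0 or d2.min() >= model.sigma**2:
                    x[i] = cand
                    break
            else:
                ok = False
                break
        if ok:
            conf = Conformation(x)
            assert validate(conf, model)
            return conf
    raise RuntimeError("failed to grow a valid conformation")
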