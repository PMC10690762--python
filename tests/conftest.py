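import numpy as np
import pytest

from ndes import NDESParameters

# Fitted parameters of the six reexamination periods (inputs, not targets).
TABLE2 = {
    "1989-1994": NDESParameters(0.7220, 35.8226, -2.8635, 3.5865, -6.9519, -4.4867),
    "1994-1999": NDESParameters(1.0682, 20.4263, -2.7597, 2.7024, -5.7101, -3.8109),
    "1999-2004": NDESParameters(0.8203, 32.2185, -2.3495, 3.1429, -5.6925, -3.3400),
    "2004-2009": NDESParameters(1.3904, 42.8872, -3.1068, 2.5992, -5.8867, -3.1080),
    "2009-2014": NDESParameters(1.1641, 32.1222, -2.9822, 2.8834, -5.4936, -2.9301),
    "2014-2019": NDESParameters(1.5110, 33.1472, -3.3836, 2.8001, -5.5520, -2.8888),
}

# Periods with a globally unique equilibrium (verified by dense-grid
# iteration); the two earlier maps each have three stable equilibria.
UNIQUE_LIMIT_PERIODS = ("1999-2004", "2004-2009", "2009-2014", "2014-2019")
MULTI_LIMIT_PERIODS = ("1989-1994", "1994-1999")

# Published limit of the 2014-2019 model (pine, fir, broadleaf).
LIMIT_2014_2019 = (0.0408, 0.0642, 0.8950)


@pytest.fixture(scope="session")
def t2019() -> NDESParameters:
    return TABLE2["2014-2019"]


@pytest.fixture(scope="session")
def noiseless_pairs():
    """200 exact-mode pairs generated from the default ground truth."""
    from ndes import SyntheticConfig, generate_plot_pairs

    cfg = SyntheticConfig(n_plots=200, noise_concentration=None, seed=11)
    return generate_plot_pairs(cfg)


@pytest.fixture(scope="session")
def noisy_fit():
    """A fitted model on one seeded noisy dataset (n=500, kappa=200)."""
    from ndes import SyntheticConfig, fit_ndes, generate_plot_pairs

    cfg = SyntheticConfig(n_plots=500, noise_concentration=200.0, seed=7)
    pairs = generate_plot_pairs(cfg)
    return pairs, fit_ndes(pairs)


def random_simplex(rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.ones(3))
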