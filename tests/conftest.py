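"""Shared fixtures: a baseline economy and random valid parameter draws."""

import numpy as np
import pytest

from poctecon import EconomicParameters, uniform_uncertainty


@pytest.fixture
def params():
    """Baseline economy: B=10, l=2, p_a=0.7, r=0.3 (p=1), a_bar=0.4."""
    return EconomicParameters(B=10.0, l=2.0, p_a=0.7, r=0.3, a_bar=0.4)


@pytest.fixture
def uniform_dist(params):
    return uniform_uncertainty(params.b_max)


def draw_params(rng: np.random.Generator) -> EconomicParameters:
    """Random economy satisfying all maintained assumptions."""
    while True:
        a_bar = float(rng.uniform(0.1, 0.9))
        p_a = float(rng.uniform(0.1, 1.5))
        r = float(rng.uniform(0.0, 0.5))
        p = p_a + r
        l = float(rng.uniform(0.0, 3.0))
        B = p + l + float(rng.uniform(0.1, 10.0))
        if B + l > 2 * p + 1e-6:
            return EconomicParameters(B=B, l=l, p_a=p_a, r=r, a_bar=a_bar)


def draw_fee(rng: np.random.Generator, params: EconomicParameters,
             frac_max: float = 0.95) -> float:
    """Random per-test fee strictly inside the feasibility region."""
    return float(rng.uniform(0.0, frac_max * params.max_test_fee))
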