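import numpy as np
import pytest

import miequiv as mq

LITERACY_SYNTAX = """\
AlphabetKnowledge =~ Letter_Name + Letter_Sound
PhonologicalAwareness =~ Blending + Elision
Spelling =~ Real_Words + Pseudo_Words
"""

SIMPLE_SYNTAX = "A =~ x1 + x2\nB =~ x3 + x4\nC =~ x5 + x6\n"


@pytest.fixture(scope="session")
def literacy_model():
    """Three factors, six indicators, two indicators per factor."""
    return mq.parse_model(LITERACY_SYNTAX)


@pytest.fixture(scope="session")
def simple_model():
    """Same dimensions as literacy_model with generic names."""
    return mq.parse_model(SIMPLE_SYNTAX)


@pytest.fixture(scope="session")
def small_model():
    """Two factors, four indicators (fast fits)."""
    return mq.parse_model("A =~ x1 + x2\nB =~ x3 + x4\n")


@pytest.fixture
def invariant_design(simple_model):
    return mq.default_design(simple_model, ns=(150, 180), seed=11)


@pytest.fixture
def invariant_moments(invariant_design):
    return mq.generate(invariant_design, "moments")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_psd(rng, k, scale=1.0):
    a = rng.standard_normal((k, k + 2))
    return scale * (a @ a.T) / (k + 2) + 0.1 * np.eye(k)


def random_paramset(rng, model, m, tau_nonzero=False):
    """Random valid ParamSet honoring the model's pattern and markers."""
    p, k = model.n_variables, model.n_factors
    pattern = model.loading_pattern()
    markers = model.marker_indices()
    gamma, lam, phi, psi, tau = [], [], [], [], []
    for _ in range(m):
        L = np.zeros((p, k))
        for c in range(k):
            for r in range(p):
                if pattern[r, c]:
                    L[r, c] = 1.0 if r == markers[c] else rng.uniform(0.4, 1.2)
        gamma.append(rng.normal(0, 1, p))
        lam.append(L)
        phi.append(random_psd(rng, k))
        psi.append(rng.uniform(0.3, 1.0, p))
        tau.append(rng.normal(0, 0.5, k) if tau_nonzero else np.zeros(k))
    return mq.mgsem.ParamSet(gamma, lam, phi, psi, tau)
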