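import numpy as np
import pytest

from myoanfis import FuzzyRule, GaussianMF, SugenoFIS


def make_random_fis(rng, n_inputs, n_rules, order="first"):
    """Random, well-conditioned FIS for oracle-equivalence checks."""
    rules = []
    for _ in range(n_rules):
        premises = [
            GaussianMF(center=float(rng.uniform(-1, 1)), sigma=float(rng.uniform(0.2, 2.0)))
            for _ in range(n_inputs)
        ]
        n_cons = n_inputs + 1 if order == "first" else 1
        rules.append(FuzzyRule(premises=premises, consequent=rng.normal(size=n_cons)))
    return SugenoFIS(rules=rules, order=order)


def naive_forward_pass(fis, x):
    """Straight-line loop evaluation of the five-layer forward pass.

    Independent of the vectorized implementation: explicit loops over rules
    and inputs, explicit normalization and weighted sum.
    """
    x = np.asarray(x, dtype=float).ravel()
    strengths = []
    for rule in fis.rules:
        w = 1.0
        for j, mf in enumerate(rule.premises):
            w *= float(np.exp(-((x[j] - mf.center) ** 2) / (2.0 * mf.sigma**2)))
        strengths.append(w)
    total = sum(strengths)
    out = 0.0
    for rule, w in zip(fis.rules, strengths):
        if fis.order == "zero":
            f = float(rule.consequent[0])
        else:
            f = float(sum(p * xi for p, xi in zip(rule.consequent[:-1], x)) + rule.consequent[-1])
        out += (w / total) * f
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
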