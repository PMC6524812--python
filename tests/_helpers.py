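"""Shared test utilities."""

import numpy as np

from leksim.estimators import gamma_shape_rate


def simulate_growth_counts(seed, n_sites, n_years, lambda_bar, sigma_lambda,
                           p=None, n1_range=(20, 60)):
    """Counts simulated from the estimators' own generative model.

    Without ``p``: Poisson max-count data for the state-space model.
    With ``p``: two-occasion Binomial counts for the N-mixture model.
    """
    gen = np.random.default_rng(seed)
    r, beta = gamma_shape_rate(lambda_bar, sigma_lambda)
    lam = gen.gamma(r, 1.0 / beta, size=(n_sites, n_years - 1))
    n = np.empty((n_sites, n_years))
    n[:, 0] = gen.uniform(*n1_range, n_sites)
    for t in range(1, n_years):
        n[:, t] = n[:, t - 1] * lam[:, t - 1]
    if p is None:
        return gen.poisson(n)
    x = gen.poisson(n)
    return gen.binomial(x[:, :, None], p, size=(n_sites, n_years, 2))
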