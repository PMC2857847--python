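"""Shared test harnesses (not oracles: these drive the package's own ops)."""

import numpy as np

from bayesgs.model import Method, ModelState
from bayesgs.samplers import rj_update_AB, sample_indicator_C, sample_mu


def run_indicator_chain(y, X, prior, n_iter, burn_in, seed, s2e):
    """Mini chain over (mu, indicators, effects) with sigma2_e held fixed.

    Uses the production op functions; holding the residual variance at
    its true value lets exhaustive enumeration serve as an exact oracle
    for the inclusion probabilities.
    """
    rng = np.random.default_rng(seed)
    n, p = X.shape
    Xt = np.ascontiguousarray(X.T)
    xtx = np.einsum("ij,ij->i", Xt, Xt)
    st = ModelState(
        mu=float(np.mean(y)), beta=np.zeros(p),
        sigma2_beta=np.full(p, prior.fixed_effect_variance),
        gamma=np.ones(p, dtype=np.int64),
        u=np.zeros(n), sigma2_u=1.0, sigma2_e=s2e, residual=None,
    )
    st.residual = y - st.mu
    gam_samples = []
    for it in range(1, n_iter + 1):
        sample_mu(st, rng)
        for j in range(p):
            if prior.method is Method.C:
                sample_indicator_C(j, st, prior, Xt, xtx, rng)
            else:
                rj_update_AB(j, st, prior, Xt, xtx, rng)
        if it > burn_in:
            gam_samples.append(st.gamma.copy())
    gam_samples = np.asarray(gam_samples)
    return {"inclusion": gam_samples.mean(axis=0), "gamma_samples": gam_samples}
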