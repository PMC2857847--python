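"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the relationship
matrix is obtained by exhaustive enumeration of allele transmissions,
and mixture-model inclusion probabilities by direct summation over the
model space with Gaussian marginal likelihoods.
"""

import itertools

import numpy as np

UNKNOWN = -1


def relationship_by_gene_enumeration(sire, dam):
    """Exact A matrix by enumerating every possible allele transmission.

    Each founder carries two uniquely labelled genes; each non-founder
    draws one of its sire's two genes and one of its dam's two (4
    possibilities per non-founder).  Over all 4^k equally likely
    configurations, a_ij = 1/2 * sum over the four gene pairs of
    P(identical by descent).  Only feasible for small pedigrees.
    """
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    n = sire.size
    nonf = [i for i in range(n) if sire[i] != UNKNOWN]
    k = len(nonf)
    M = 4**k
    ids = np.zeros((n, 2, M), dtype=np.int32)
    next_gene = 0
    c = np.arange(M)
    choice = {}
    for m, i in enumerate(nonf):
        bits = (c // 4**m) % 4
        choice[i] = (bits % 2, bits // 2)  # sire-gene pick, dam-gene pick
    for i in range(n):
        if sire[i] == UNKNOWN:
            ids[i, 0, :] = next_gene
            ids[i, 1, :] = next_gene + 1
            next_gene += 2
        else:
            sp, dp = choice[i]
            ids[i, 0, :] = np.where(sp == 0, ids[sire[i], 0, :], ids[sire[i], 1, :])
            ids[i, 1, :] = np.where(dp == 0, ids[dam[i], 0, :], ids[dam[i], 1, :])
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            tot = 0.0
            for a, b in itertools.product(range(2), repeat=2):
                tot += np.mean(ids[i, a, :] == ids[j, b, :])
            A[i, j] = A[j, i] = 0.5 * tot
    return A


def random_small_pedigree(rng, n_max=10, max_nonfounders=7):
    """Random topologically ordered pedigree for oracle comparison."""
    n = int(rng.integers(4, n_max + 1))
    n_found = max(2, n - max_nonfounders)
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    for i in range(n_found, n):
        s, d = rng.choice(i, size=2, replace=False)
        sire[i], dam[i] = s, d
    return sire, dam


def _flat_mu_log_marginal(y, V):
    """log p(y | V) with the mean integrated against a flat prior.

    y ~ N(1 mu, V), improper flat mu; constant terms in y-dimension are
    kept so that differences across V are meaningful.
    """
    n = y.size
    Vi = np.linalg.inv(V)
    one = np.ones(n)
    a = one @ Vi @ one
    sign, logdet = np.linalg.slogdet(V)
    assert sign > 0
    quad = y @ Vi @ y - (one @ Vi @ y) ** 2 / a
    return -0.5 * (logdet + np.log(a) + quad)


def mixture_inclusion_by_enumeration(y, X, sigma2_large, sigma2_small, sigma2_e, pi):
    """Posterior inclusion probabilities by summing over all indicator configs.

    ``sigma2_small`` = 0 gives the point-mass (in/out) mixture of the
    reversible-jump hybrid; a positive value gives the SSVS two-component
    mixture.  The overall mean carries a flat prior, matching the chain.
    """
    n, p = X.shape
    log_post = {}
    for config in itertools.product([0, 1], repeat=p):
        V = sigma2_e * np.eye(n)
        for j, g in enumerate(config):
            s2 = sigma2_large if g else sigma2_small
            if s2 > 0:
                V += s2 * np.outer(X[:, j], X[:, j])
        n_in = sum(config)
        log_prior = n_in * np.log(pi) + (p - n_in) * np.log1p(-pi)
        log_post[config] = log_prior + _flat_mu_log_marginal(y, V)
    mx = max(log_post.values())
    weights = {cfg: np.exp(lp - mx) for cfg, lp in log_post.items()}
    Z = sum(weights.values())
    incl = np.zeros(p)
    for cfg, w in weights.items():
        for j, g in enumerate(cfg):
            if g:
                incl[j] += w
    return incl / Z


def batch_se(samples, n_batches=20):
    """Batch-means standard error of the mean of an autocorrelated chain."""
    samples = np.asarray(samples, dtype=float)
    m = samples.size // n_batches
    means = samples[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)
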