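"""Gibbs / Metropolis-Hastings engines for the four whole-genome methods.

Every full-conditional update is exposed as a standalone function so it
can be validated against its closed form on toy problems; ``run_chain``
drives them.  For speed the per-iteration SNP sweep inside ``run_chain``
inlines the same arithmetic with pre-drawn random variates; an
equivalence test guarantees the two paths produce identical draws.

Update order per iteration (deterministic by default, random-scan as an
option): mu -> SNP effects (with their variances / indicators per
method) -> polygenic u -> sigma2_u -> sigma2_e.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .model import (
    VARIANCE_FLOOR,
    ChainConfig,
    Method,
    ModelState,
    PosteriorSummary,
    PriorSpec,
    scaled_inv_chi2_rvs,
)

logger = logging.getLogger(__name__)

RESIDUAL_CHECK_EVERY = 1000
RESIDUAL_TOL = 1e-6


class ChainDivergedError(RuntimeError):
    """Raised when a variance or residual overflows during sampling."""


# ---------------------------------------------------------------------------
# single-parameter full conditionals


def snp_effect_conditional(xtr: float, xtx: float, sigma2_beta: float, sigma2_e: float):
    """Mean and variance of beta_j | rest.

    ``xtr`` is x_j' r_j with r_j the residual after adding SNP j's old
    contribution back; the conditional is N(xtr / C, sigma2_e / C) with
    C = x_j'x_j + sigma2_e / sigma2_beta (ridge-shrunken least squares).
    """
    C = xtx + sigma2_e / sigma2_beta
    return xtr / C, sigma2_e / C


def sample_mu(state: ModelState, rng: np.random.Generator) -> float:
    """Draw the overall mean from N(mean(r + mu_old), sigma2_e / n)."""
    n = state.residual.size
    r_plus = state.residual + state.mu
    new_mu = r_plus.mean() + rng.standard_normal() * math.sqrt(state.sigma2_e / n)
    state.residual = r_plus - new_mu
    state.mu = new_mu
    return new_mu


def sample_snp_effect(j: int, state: ModelState, Xt: np.ndarray, xtx: np.ndarray,
                      rng: np.random.Generator) -> float:
    """Gibbs draw of beta_j from its normal full conditional.

    Monomorphic columns (x_j'x_j == 0) get beta_j = 0.  The residual
    cache is updated in place.
    """
    xj = Xt[j]
    if xtx[j] <= 0.0:
        if state.beta[j] != 0.0:
            state.residual += xj * state.beta[j]
            state.beta[j] = 0.0
        return 0.0
    xtr = float(xj @ state.residual) + xtx[j] * state.beta[j]
    mean, var = snp_effect_conditional(xtr, xtx[j], state.sigma2_beta[j], state.sigma2_e)
    new = mean + rng.standard_normal() * math.sqrt(var)
    state.residual += xj * (state.beta[j] - new)
    state.beta[j] = new
    return new


def sample_snp_variance_A(beta_j: float, prior: PriorSpec, rng: np.random.Generator) -> float:
    """Per-SNP variance draw: (nu S + beta_j^2) / chi2_{nu+1}."""
    draw = (prior.nu * prior.S + beta_j**2) / rng.chisquare(prior.nu + 1.0)
    return max(draw, VARIANCE_FLOOR)


def sample_common_variance_BLUP(beta: np.ndarray, prior: PriorSpec,
                                rng: np.random.Generator) -> float:
    """Common SNP variance: (nu S + sum beta^2) / chi2_{nu+p}."""
    p = beta.size
    draw = (prior.nu * prior.S + float(beta @ beta)) / rng.chisquare(prior.nu + p)
    return max(draw, VARIANCE_FLOOR)


def sample_variance_flat(quadratic_form: float, n_terms: int, rng: np.random.Generator,
                         dof_offset: int = -2) -> float:
    """Variance draw under the flat chi^-2(-2, 0) prior.

    Posterior is the quadratic form over chi2 with n_terms + dof_offset
    degrees of freedom (the flat prior contributes -2 df and zero scale).
    A zero quadratic form degenerates to zero and is caught by the
    variance floor.
    """
    df = n_terms + dof_offset
    if df <= 0:
        raise ValueError(f"need more than {-dof_offset} observations, got {n_terms}")
    draw = quadratic_form / rng.chisquare(df)
    return max(draw, VARIANCE_FLOOR)


def sample_polygenic(state: ModelState, eigA: tuple[np.ndarray, np.ndarray],
                     rng: np.random.Generator) -> float:
    """Block draw of u from its multivariate-normal full conditional.

    ``eigA`` is the (eigenvalues, eigenvectors) factorisation of A over
    the phenotyped animals, computed once per run.  In the eigenbasis
    the conditional precision 1/sigma2_e + 1/(sigma2_u lambda_i) is
    diagonal, so the block update costs two matrix-vector products.
    Returns the quadratic form u' A^-1 u needed by the sigma2_u update.
    """
    lam, Q = eigA
    r_plus = state.residual + state.u
    b = Q.T @ r_plus
    v = np.zeros_like(b)
    ok = lam > 1e-12
    prec = 1.0 / state.sigma2_e + 1.0 / (state.sigma2_u * lam[ok])
    var = 1.0 / prec
    v[ok] = b[ok] / state.sigma2_e * var + rng.standard_normal(ok.sum()) * np.sqrt(var)
    state.u = Q @ v
    state.residual = r_plus - state.u
    return float(np.sum(v[ok] ** 2 / lam[ok]))


def _log_marginal_gain(s: float, xtx: float, sigma2: float, sigma2_e: float) -> float:
    """log p(r | beta_j ~ N(0, sigma2)) - log p(r | beta_j = 0).

    ``s`` is x_j' r_j (SNP j's contribution added back).  Obtained from
    the rank-one covariance sigma2 x x' + sigma2_e I via
    Sherman-Morrison.
    """
    if sigma2 <= 0.0:
        return 0.0
    t = xtx * sigma2
    return -0.5 * math.log1p(t / sigma2_e) + 0.5 * s * s * sigma2 / (sigma2_e * (sigma2_e + t))


def rj_update_AB(j: int, state: ModelState, prior: PriorSpec, Xt: np.ndarray,
                 xtx: np.ndarray, rng: np.random.Generator) -> bool:
    """Reversible-jump move set for SNP j of the Bayes A/B hybrid.

    SNP j's effect is first integrated out (its contribution added back
    to the residual), then ``rj_repeats`` independence Metropolis-
    Hastings moves are made on (in/out, sigma2_beta_j) with the prior as
    proposal — out with probability 1 - pi, otherwise a fresh
    scaled-inv-chi2 variance — so the acceptance ratio reduces to the
    marginal-likelihood ratio.  Finally beta_j is redrawn from its full
    conditional under the surviving model (exactly zero if out).

    Returns the final in/out state.
    """
    xj = Xt[j]
    if xtx[j] <= 0.0:
        if state.beta[j] != 0.0:
            state.residual += xj * state.beta[j]
        state.beta[j] = 0.0
        state.gamma[j] = 0
        return False
    s = float(xj @ state.residual) + xtx[j] * state.beta[j]

    cur_in = bool(state.gamma[j])
    cur_sigma2 = float(state.sigma2_beta[j]) if cur_in else 0.0
    cur_logml = _log_marginal_gain(s, xtx[j], cur_sigma2, state.sigma2_e)
    for _ in range(prior.rj_repeats):
        if rng.random() < prior.pi:
            if prior.fixed_effect_variance is not None:
                prop_sigma2 = prior.fixed_effect_variance
            else:
                prop_sigma2 = float(scaled_inv_chi2_rvs(prior.nu, prior.S, rng))
        else:
            prop_sigma2 = 0.0
        prop_logml = _log_marginal_gain(s, xtx[j], prop_sigma2, state.sigma2_e)
        if math.log(rng.random()) < prop_logml - cur_logml:
            cur_sigma2, cur_logml = prop_sigma2, prop_logml

    new_in = cur_sigma2 > 0.0
    state.gamma[j] = int(new_in)
    if new_in:
        state.sigma2_beta[j] = cur_sigma2
        mean, var = snp_effect_conditional(s, xtx[j], cur_sigma2, state.sigma2_e)
        new_beta = mean + rng.standard_normal() * math.sqrt(var)
    else:
        state.sigma2_beta[j] = max(prior.nu * prior.S / (prior.nu - 2.0), VARIANCE_FLOOR)
        new_beta = 0.0
    state.residual += xj * (state.beta[j] - new_beta)
    state.beta[j] = new_beta
    return new_in


def sample_indicator_C(j: int, state: ModelState, prior: PriorSpec, Xt: np.ndarray,
                       xtx: np.ndarray, rng: np.random.Generator) -> int:
    """SSVS indicator and effect draw for SNP j.

    With beta_j integrated out, gamma_j | rest is Bernoulli with odds
    pi L(large) / ((1 - pi) L(small)), where the two components are the
    SNP's variance sigma2_beta_j and c * sigma2_beta_j.  beta_j is then
    drawn from its full conditional under the selected component.
    """
    xj = Xt[j]
    if xtx[j] <= 0.0:
        if state.beta[j] != 0.0:
            state.residual += xj * state.beta[j]
        state.beta[j] = 0.0
        return int(state.gamma[j])
    s = float(xj @ state.residual) + xtx[j] * state.beta[j]
    large = float(state.sigma2_beta[j])
    small = prior.small_variance_ratio * large
    log_odds = (
        math.log(prior.pi) - math.log1p(-prior.pi)
        + _log_marginal_gain(s, xtx[j], large, state.sigma2_e)
        - _log_marginal_gain(s, xtx[j], small, state.sigma2_e)
    ) if prior.pi < 1.0 else math.inf
    p_in = 1.0 / (1.0 + math.exp(-log_odds)) if log_odds < 700 else 1.0
    gamma_j = int(rng.random() < p_in)
    state.gamma[j] = gamma_j
    sigma2_eff = large if gamma_j else small
    mean, var = snp_effect_conditional(s, xtx[j], sigma2_eff, state.sigma2_e)
    new_beta = mean + rng.standard_normal() * math.sqrt(var)
    state.residual += xj * (state.beta[j] - new_beta)
    state.beta[j] = new_beta
    return gamma_j


# ---------------------------------------------------------------------------
# chain driver


def _init_state(y: np.ndarray, p: int, prior: PriorSpec,
                rng: np.random.Generator) -> ModelState:
    var_y = float(np.var(y))
    if prior.fixed_effect_variance is not None:
        s2b = prior.fixed_effect_variance
    else:
        s2b = prior.nu * prior.S / (prior.nu - 2.0)  # prior mean
    # mixture methods start their indicator at a prior draw (all effects are
    # zero initially, so this only sets which SNPs the first sweeps touch);
    # pi = 1 keeps everything in deterministically so the Bayes A reduction
    # shares the A sampler's random stream exactly
    if prior.method in (Method.AB, Method.C) and prior.pi < 1.0:
        gamma0 = (rng.random(p) < prior.pi).astype(np.int64)
    else:
        gamma0 = np.ones(p, dtype=np.int64)
    state = ModelState(
        mu=float(np.mean(y)),
        beta=np.zeros(p),
        sigma2_beta=np.full(p, max(s2b, VARIANCE_FLOOR)),
        gamma=gamma0,
        u=np.zeros(y.size),
        sigma2_u=max(0.2 * var_y, VARIANCE_FLOOR),
        sigma2_e=max(0.5 * var_y, VARIANCE_FLOOR),
        residual=None,  # type: ignore[arg-type]
    )
    state.residual = y - state.mu
    return state


def _sweep_blup(state, prior, Xt, xtx, z, rng):
    beta, r = state.beta, state.residual
    s2e = state.sigma2_e
    s2b = state.sigma2_beta[0]
    for j in range(Xt.shape[0]):
        if xtx[j] <= 0.0:
            continue
        xj = Xt[j]
        xtr = xj @ r + xtx[j] * beta[j]
        C = xtx[j] + s2e / s2b
        new = xtr / C + z[j] * math.sqrt(s2e / C)
        r += xj * (beta[j] - new)
        beta[j] = new
    if prior.fixed_effect_variance is None:
        state.sigma2_beta[:] = sample_common_variance_BLUP(beta, prior, rng)


def _sweep_bayesA(state, prior, Xt, xtx, z, chi, active=None):
    """Bayes A sweep: per-SNP variance draw, then effect draw.

    ``chi`` holds pre-drawn chi2_{nu+1} variates, ``z`` standard
    normals.  ``active`` restricts the sweep (hybrid's "in" SNPs).
    """
    beta, r = state.beta, state.residual
    s2b = state.sigma2_beta
    s2e = state.sigma2_e
    nuS = prior.nu * prior.S
    fixed = prior.fixed_effect_variance
    cols = range(Xt.shape[0]) if active is None else active
    for j in cols:
        if xtx[j] <= 0.0:
            continue
        if fixed is None:
            s2b[j] = max((nuS + beta[j] ** 2) / chi[j], VARIANCE_FLOOR)
        xj = Xt[j]
        xtr = xj @ r + xtx[j] * beta[j]
        C = xtx[j] + s2e / s2b[j]
        new = xtr / C + z[j] * math.sqrt(s2e / C)
        r += xj * (beta[j] - new)
        beta[j] = new


def _sweep_bayesC(state, prior, Xt, xtx, z, chi, unif):
    beta, r = state.beta, state.residual
    s2b, gamma = state.sigma2_beta, state.gamma
    s2e = state.sigma2_e
    nuS = prior.nu * prior.S
    c = prior.small_variance_ratio
    fixed = prior.fixed_effect_variance
    log_prior_odds = math.log(prior.pi) - math.log1p(-prior.pi) if prior.pi < 1.0 else math.inf
    for j in range(Xt.shape[0]):
        if xtx[j] <= 0.0:
            continue
        if fixed is None:
            m_j = 1.0 if gamma[j] else c
            s2b[j] = max((nuS + beta[j] ** 2 / m_j) / chi[j], VARIANCE_FLOOR)
        xj = Xt[j]
        s = xj @ r + xtx[j] * beta[j]
        large = s2b[j]
        small = c * large
        log_odds = (
            log_prior_odds
            + _log_marginal_gain(s, xtx[j], large, s2e)
            - _log_marginal_gain(s, xtx[j], small, s2e)
        )
        p_in = 1.0 if log_odds > 700 else 1.0 / (1.0 + math.exp(-log_odds))
        gamma[j] = int(unif[j] < p_in)
        sig = large if gamma[j] else small
        C = xtx[j] + s2e / sig
        new = s / C + z[j] * math.sqrt(s2e / C)
        r += xj * (beta[j] - new)
        beta[j] = new


def run_chain(
    y: np.ndarray,
    X: np.ndarray,
    prior: PriorSpec,
    chain: ChainConfig,
    A: np.ndarray | tuple[np.ndarray, np.ndarray] | None = None,
    timepoint: float | None = None,
    log_every: int = 1000,
) -> PosteriorSummary:
    """Run one MCMC chain and return posterior means.

    Parameters
    ----------
    y : phenotype vector of the training animals (no missing values).
    X : n x p genotype design matrix, raw 0/1/2 codes (centered here if
        the prior requests it).
    A : additive relationship matrix over the training animals, or a
        precomputed ``(eigenvalues, eigenvectors)`` pair; required when
        the prior includes the polygenic term.
    """
    y = np.ascontiguousarray(np.asarray(y, dtype=np.float64))
    if np.any(~np.isfinite(y)):
        raise ValueError("training phenotypes contain missing values")
    X = np.asarray(X, dtype=np.float64)
    n, p = X.shape
    if y.size != n:
        raise ValueError("phenotype / genotype row mismatch")
    if prior.center_genotypes:
        X = X - X.mean(axis=0)
    Xt = np.ascontiguousarray(X.T)
    xtx = np.einsum("ij,ij->i", Xt, Xt)

    use_u = prior.include_polygenic and A is not None
    eigA = None
    if use_u:
        if isinstance(A, tuple):
            eigA = A
        else:
            A = np.asarray(A, dtype=np.float64)
            if A.shape != (n, n):
                raise ValueError("A must be n x n over the training animals")
            lam, Q = np.linalg.eigh(A)
            if lam.min() < -1e-8:
                raise ValueError(
                    "relationship matrix is not positive semidefinite; "
                    "check the pedigree for ordering errors"
                )
            eigA = (np.clip(lam, 0.0, None), Q)
        n_u = int(np.sum(eigA[0] > 1e-12))

    rng = np.random.default_rng(chain.seed)
    state = _init_state(y, p, prior, rng)
    method = prior.method

    n_rec = 0
    acc = {
        "mu": 0.0, "beta": np.zeros(p), "u": np.zeros(n),
        "sigma2_u": 0.0, "sigma2_e": 0.0, "gamma": np.zeros(p),
    }
    stored: dict[str, list] = {"mu": [], "sigma2_e": [], "sigma2_u": [], "n_active": []}
    store_beta: list[np.ndarray] = []

    nu1 = prior.nu + 1.0
    for it in range(1, chain.n_iter + 1):
        sample_mu(state, rng)

        order = rng.permutation(p) if prior.random_scan else None
        if order is not None:
            Xt_it, xtx_it = Xt[order], xtx[order]
        else:
            Xt_it, xtx_it = Xt, xtx
        sv = _view(state, order)
        # pre-drawn variates for the inlined sweeps (one per SNP, in sweep order)
        z = rng.standard_normal(p)
        if method is Method.BLUP:
            _sweep_blup(sv, prior, Xt_it, xtx_it, z, rng)
        elif method is Method.A:
            chi = rng.chisquare(nu1, p)
            _sweep_bayesA(sv, prior, Xt_it, xtx_it, z, chi)
        elif method is Method.AB:
            if prior.pi < 1.0 and it % prior.k == 0:
                for j in range(p):
                    rj_update_AB(j, sv, prior, Xt_it, xtx_it, rng)
            else:
                chi = rng.chisquare(nu1, p)
                active = np.flatnonzero(sv.gamma == 1)
                _sweep_bayesA(sv, prior, Xt_it, xtx_it, z, chi, active=active)
        elif method is Method.C:
            chi = rng.chisquare(nu1, p)
            unif = rng.random(p)
            _sweep_bayesC(sv, prior, Xt_it, xtx_it, z, chi, unif)
        _unview(state, sv, order)

        if use_u:
            quad = sample_polygenic(state, eigA, rng)
            state.sigma2_u = sample_variance_flat(quad, n_u, rng)
        state.sigma2_e = sample_variance_flat(float(state.residual @ state.residual), n, rng)

        if it % RESIDUAL_CHECK_EVERY == 0:
            Zu = state.u if use_u else None
            drift = state.refresh_residual(y, X, Zu)
            if not math.isfinite(drift) or drift > RESIDUAL_TOL:
                raise ChainDivergedError(
                    f"residual cache drifted by {drift:.3g} at iteration {it}"
                )
            if not (math.isfinite(state.sigma2_e) and math.isfinite(state.sigma2_u)):
                raise ChainDivergedError(f"variance overflow at iteration {it}")
        if log_every and it % log_every == 0:
            logger.debug(
                "%s iter %d: s2e=%.4g s2u=%.4g active=%d",
                method.value, it, state.sigma2_e, state.sigma2_u, int(state.gamma.sum()),
            )

        if it > chain.burn_in and (it - chain.burn_in - 1) % chain.thin == 0:
            n_rec += 1
            acc["mu"] += state.mu
            acc["beta"] += state.beta
            acc["u"] += state.u
            acc["sigma2_u"] += state.sigma2_u
            acc["sigma2_e"] += state.sigma2_e
            acc["gamma"] += state.gamma
            stored["mu"].append(state.mu)
            stored["sigma2_e"].append(state.sigma2_e)
            stored["sigma2_u"].append(state.sigma2_u)
            stored["n_active"].append(int(state.gamma.sum()))
            if chain.store_samples:
                store_beta.append(state.beta.copy())

    inclusion = acc["gamma"] / n_rec
    if method in (Method.BLUP, Method.A):
        inclusion = np.ones(p)
    samples = {k: np.asarray(v) for k, v in stored.items()}
    if chain.store_samples:
        samples["beta"] = np.asarray(store_beta)
    return PosteriorSummary(
        method=method,
        mu=acc["mu"] / n_rec,
        beta=acc["beta"] / n_rec,
        u=acc["u"] / n_rec,
        sigma2_u=acc["sigma2_u"] / n_rec,
        sigma2_e=acc["sigma2_e"] / n_rec,
        inclusion_prob=inclusion,
        n_samples=n_rec,
        timepoint=timepoint,
        samples=samples,
    )


def _view(state: ModelState, order: np.ndarray | None) -> ModelState:
    """Permuted view of the SNP-indexed state arrays for random-scan."""
    if order is None:
        return state
    view = ModelState(
        mu=state.mu, beta=state.beta[order], sigma2_beta=state.sigma2_beta[order],
        gamma=state.gamma[order], u=state.u, sigma2_u=state.sigma2_u,
        sigma2_e=state.sigma2_e, residual=state.residual,
    )
    return view


def _unview(state: ModelState, view: ModelState, order: np.ndarray | None) -> None:
    if order is None or view is state:
        return
    state.beta[order] = view.beta
    state.sigma2_beta[order] = view.sigma2_beta
    state.gamma[order] = view.gamma
    state.residual = view.residual
    state.mu = view.mu
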