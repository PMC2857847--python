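"""Model state, prior specifications and the scaled inverse-chi-square.

The linear model fitted to each time point's records is

    y = 1 mu + sum_j X_j beta_j + Z u + e,

with X_j the 0/1/2 genotype codes at SNP j, u ~ N(0, A sigma2_u) the
pedigree polygenic term and e ~ N(0, I sigma2_e).  The four methods
differ only in the prior placed on the SNP effects:

* Bayes BLUP — all beta_j share one normal variance (infinitesimal model);
* Bayes A    — each beta_j has its own scaled-inv-chi2 variance (marginal t);
* Bayes A/B  — mixture: beta_j = 0 with probability 1 - pi, otherwise as
  Bayes A; in/out moves by reversible jump every k Gibbs iterations;
* Bayes C    — SSVS: an indicator gamma_j ~ Bernoulli(pi) switches beta_j's
  variance between a "large" and a "near-zero" (ratio c) component.

Variance scalars sigma2_u and sigma2_e carry flat chi^-2(-2, 0) priors.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

VARIANCE_FLOOR = 1e-10


class Method(str, enum.Enum):
    BLUP = "blup"
    A = "bayesA"
    AB = "bayesAB"
    C = "bayesC"

    @classmethod
    def parse(cls, value) -> "Method":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower().replace("/", "").replace("-", "").replace("_", "")
        aliases = {
            "blup": cls.BLUP, "bayesblup": cls.BLUP,
            "a": cls.A, "bayesa": cls.A,
            "ab": cls.AB, "bayesab": cls.AB, "hybrid": cls.AB, "bayesb": cls.AB,
            "c": cls.C, "bayesc": cls.C, "ssvs": cls.C,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValueError(f"unknown method {value!r}") from None


def scaled_inv_chi2_rvs(df: float, scale: float, rng: np.random.Generator, size=None):
    """Draw from ScaledInvChi2(df, scale): X = df * scale / chi2_df.

    Mean is df * scale / (df - 2) for df > 2.  This is the scale
    parameterisation (Gelman et al.); the conjugate posterior for a
    normal variance with prior ScaledInvChi2(nu, S) and one observation
    beta is ScaledInvChi2(nu + 1, (nu S + beta^2) / (nu + 1)), i.e. the
    draw (nu S + beta^2) / chi2_{nu+1}.
    """
    if df <= 0 or scale < 0:
        raise ValueError("df must be > 0 and scale >= 0")
    return df * scale / rng.chisquare(df, size=size)


def scaled_inv_chi2_mean(df: float, scale: float) -> float:
    if df <= 2:
        raise ValueError("mean undefined for df <= 2")
    return df * scale / (df - 2.0)


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters and mixture/algorithm settings for one fit.

    nu and S are the scaled-inv-chi2 degrees of freedom and scale for the
    SNP-effect variances (see :func:`compute_hyperparameters`); pi is the
    prior proportion of SNPs in the nonzero / large-variance component;
    c is the near-zero:large variance ratio of Bayes C; k is the number
    of Gibbs iterations between reversible-jump sweeps of the hybrid and
    m the number of jump proposals per SNP per sweep.
    """

    method: Method = Method.A
    nu: float = 4.012
    S: float = 1.0
    pi: float = 0.05
    small_variance_ratio: float = 0.01
    k: int = 10
    rj_repeats: int = 5
    include_polygenic: bool = True
    center_genotypes: bool = False
    fixed_effect_variance: float | None = None
    random_scan: bool = False

    def __post_init__(self):
        object.__setattr__(self, "method", Method.parse(self.method))
        if not 0.0 < self.pi <= 1.0:
            raise ValueError("pi must lie in (0, 1]")
        if self.nu <= 2.0:
            raise ValueError("nu must exceed 2 (prior mean undefined otherwise)")
        if self.S <= 0.0:
            raise ValueError("S must be positive")
        if not 0.0 < self.small_variance_ratio <= 1.0:
            # 1.0 collapses the two components; useful as a degenerate check
            raise ValueError("small_variance_ratio must lie in (0, 1]")
        if self.k < 1 or self.rj_repeats < 1:
            raise ValueError("k and rj_repeats must be >= 1")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run-length settings; defaults follow the study protocol."""

    n_iter: int = 30_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    store_samples: bool = False

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelState:
    """Current values of all unknowns plus the residual cache.

    ``residual`` always equals y - 1 mu - X beta - Z u; the samplers
    maintain it incrementally and :meth:`refresh_residual` recomputes it
    from scratch as a consistency check.
    """

    mu: float
    beta: np.ndarray
    sigma2_beta: np.ndarray  # per-SNP (A/AB/C); BLUP keeps all entries equal
    gamma: np.ndarray  # {0,1}; inclusion (C) or in/out (AB); all-ones for BLUP/A
    u: np.ndarray
    sigma2_u: float
    sigma2_e: float
    residual: np.ndarray

    def refresh_residual(self, y: np.ndarray, X: np.ndarray, Zu: np.ndarray | None = None):
        fitted = self.mu + X @ self.beta
        if Zu is not None:
            fitted = fitted + Zu
        new = y - fitted
        drift = float(np.max(np.abs(new - self.residual))) if self.residual is not None else np.inf
        self.residual = new
        return drift


@dataclass
class PosteriorSummary:
    """Posterior means over post-burn-in (thinned) samples of one chain."""

    method: Method
    mu: float
    beta: np.ndarray
    u: np.ndarray
    sigma2_u: float
    sigma2_e: float
    inclusion_prob: np.ndarray
    n_samples: int
    timepoint: float | None = None
    samples: dict[str, np.ndarray] | None = None


def compute_hyperparameters(
    assumed_genetic_variance: float,
    p: int,
    expected_nonzero_fraction: float = 1.0,
    nu: float = 4.012,
    mean_2pq: float | None = None,
    genotypes: np.ndarray | None = None,
) -> float:
    """Scale S of the SNP-variance prior from an assumed genetic variance.

    The per-SNP prior variance is the assumed additive variance divided
    by the expected number of nonzero SNPs times the mean heterozygosity
    scaling of the marker set:

        sigma~^2 = V_g / (p * f * mean(2 p_j q_j)),

    then S = sigma~^2 (nu - 2) / nu so that the prior mean of
    ScaledInvChi2(nu, S) equals sigma~^2.

    ``mean_2pq`` may be given directly or computed from a genotype
    matrix; it defaults to 1.0 (no scaling) when neither is supplied.
    """
    if assumed_genetic_variance <= 0 or p <= 0 or expected_nonzero_fraction <= 0:
        raise ValueError("inputs must be positive")
    if nu <= 2:
        raise ValueError("nu must exceed 2: the prior mean is undefined otherwise")
    if mean_2pq is None:
        if genotypes is not None:
            freq = genotypes.astype(float).mean(axis=0) / 2.0
            mean_2pq = float(np.mean(2.0 * freq * (1.0 - freq)))
        else:
            mean_2pq = 1.0
    sigma_tilde2 = assumed_genetic_variance / (p * expected_nonzero_fraction * mean_2pq)
    return sigma_tilde2 * (nu - 2.0) / nu
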