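"""Synthetic QTL-MAS-style dataset generator with known ground truth.

Emulates the structure of the community-simulated genomic-selection
benchmark this package targets: a pedigreed population genotyped at a few
hundred SNPs, a finite set of QTL in which the largest explains ~10.5% of
the genetic variance, phenotypes recorded at three time points on the
linear part of a growth curve, and a final generation of 50 full-sib
families left unphenotyped for validation.  Because the data are
simulated, true breeding values (TBV) are known at every time point,
including the extrapolation target t = 600.

Randomness is organised as one root seed; each stage (pedigree,
genotypes, QTL effects, phenotypes) draws from an independent child
stream spawned from ``numpy.random.SeedSequence(seed)``, in that fixed
order, so a dataset is bit-reproducible from its config.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedigree import UNKNOWN, Pedigree


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults reproduce the study conditions: 435 SNPs, 21 QTL, largest
    QTL explaining 10.5% of genetic variance, heritability 0.5 per time
    point, phenotypes at days 265/397/530, ~1000 phenotyped (training)
    animals and 50 unphenotyped full-sib validation families of 20.
    """

    n_founders: int = 200
    n_generations: int = 4
    family_size: int = 20
    n_validation_families: int = 50
    n_snp: int = 435
    n_qtl: int = 21
    max_qtl_variance_share: float = 0.105
    heritability: float = 0.5
    time_points: tuple[float, ...] = (265.0, 397.0, 530.0)
    seed: int = 0

    # QTL architecture: "typed" places the QTL on typed SNP columns;
    # "tagged" makes them untyped causal loci, each completely linked to
    # n_tags_per_qtl typed SNPs whose founder alleles copy the causal
    # allele with error tag_allele_error (a dense-map LD emulation)
    qtl_mode: str = "typed"
    n_tags_per_qtl: int = 3
    tag_allele_error: float = 0.1

    # free "flavour" parameters of the growth trait, trait units (kg-like)
    base_mean: float = 20.0
    mean_growth_per_day: float = 0.04
    genetic_sd: float = 3.0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigurationError("need at least two founders")
        if self.n_generations < 0 or self.family_size < 1:
            raise ConfigurationError("n_generations >= 0 and family_size >= 1 required")
        if self.n_validation_families < 0:
            raise ConfigurationError("n_validation_families must be >= 0")
        if not 0 < self.n_qtl <= self.n_snp:
            raise ConfigurationError("require 0 < n_qtl <= n_snp")
        if not 0.0 < self.max_qtl_variance_share < 1.0:
            raise ConfigurationError("max_qtl_variance_share must lie in (0, 1)")
        if self.n_qtl == 1 and self.max_qtl_variance_share < 1.0:
            raise ConfigurationError(
                "a single QTL necessarily explains all genetic variance; "
                "max_qtl_variance_share < 1 is unsatisfiable with n_qtl = 1"
            )
        if not 0.0 < self.heritability < 1.0:
            raise ConfigurationError("heritability must lie in (0, 1)")
        tp = np.asarray(self.time_points, dtype=float)
        if tp.size < 2 or np.any(np.diff(tp) <= 0):
            raise ConfigurationError("time_points must be strictly increasing, length >= 2")
        if self.qtl_mode not in ("typed", "tagged"):
            raise ConfigurationError("qtl_mode must be 'typed' or 'tagged'")
        if self.qtl_mode == "tagged":
            if self.n_tags_per_qtl < 1 or self.n_tags_per_qtl * self.n_qtl > self.n_snp:
                raise ConfigurationError("need 1 <= n_tags_per_qtl with n_qtl * n_tags_per_qtl <= n_snp")
            if not 0.0 <= self.tag_allele_error < 1.0:
                raise ConfigurationError("tag_allele_error must lie in [0, 1)")

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.time_points, dtype=float)


@dataclass
class TruthSet:
    """Ground truth of a simulated dataset.

    ``qtl_effects_per_timepoint`` has one row per QTL and one column per
    evaluated time point (the phenotyped points plus the extrapolation
    target).  ``true_breeding_values`` is animals x time points on the
    same column grid.  By construction each QTL effect is linear in time,
    so every animal's TBV at the phenotyped points lies exactly on a line
    and the extrapolation-target truth is that same line's value.
    """

    qtl_indices: np.ndarray
    qtl_effects_per_timepoint: np.ndarray
    true_breeding_values: np.ndarray
    eval_timepoints: np.ndarray
    # tagged (LD) mode only: untyped causal genotypes and the typed
    # columns tagging each QTL; qtl_indices then holds the first tag
    causal_genotypes: np.ndarray | None = None
    tag_indices: np.ndarray | None = None

    def tbv_at(self, timepoint: float) -> np.ndarray:
        (col,) = np.where(np.isclose(self.eval_timepoints, timepoint))
        if col.size != 1:
            raise KeyError(f"no TBV column for time point {timepoint}")
        return self.true_breeding_values[:, col[0]]


@dataclass
class Dataset:
    """A complete simulated dataset: inputs plus ground truth."""

    config: SimulationConfig
    pedigree: Pedigree
    genotypes: np.ndarray  # n_animals x n_snp, int8 codes 0/1/2
    phenotypes: np.ndarray  # n_animals x n_timepoints, NaN for validation animals
    mu_per_timepoint: np.ndarray
    residual_var_per_timepoint: np.ndarray
    truth: TruthSet

    @property
    def training_mask(self) -> np.ndarray:
        return self.pedigree.phenotyped

    @property
    def validation_mask(self) -> np.ndarray:
        return ~self.pedigree.phenotyped


EXTRAPOLATION_TIMEPOINT = 600.0


def _spawn_streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("pedigree", "genotypes", "effects", "phenotypes")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def make_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Build the generational pedigree.

    Generation 0 holds ``n_founders`` base animals with unknown parents.
    Each of the ``n_generations`` training generations has the same size
    as the founder generation, every offspring receiving two distinct
    randomly drawn parents from the previous generation.  A final
    unphenotyped generation of ``n_validation_families`` full-sib
    families of ``family_size`` is appended (parents drawn from the last
    training generation), mirroring the validation design of the target
    study.
    """
    config.validate()
    if rng is None:
        rng = _spawn_streams(config.seed)["pedigree"]

    sire: list[int] = [UNKNOWN] * config.n_founders
    dam: list[int] = [UNKNOWN] * config.n_founders
    gen: list[int] = [0] * config.n_founders
    fam: list[int] = [-1] * config.n_founders

    prev = np.arange(config.n_founders)
    for g in range(1, config.n_generations + 1):
        cur = []
        for _ in range(config.n_founders):
            s, d = rng.choice(prev, size=2, replace=False)
            cur.append(len(sire))
            sire.append(int(s))
            dam.append(int(d))
            gen.append(g)
            fam.append(-1)
        prev = np.asarray(cur)

    n_train = len(sire)
    if config.n_validation_families > 0:
        if prev.size < 2:
            raise ConfigurationError("validation families need >= 2 candidate parents")
        g = config.n_generations + 1
        for f in range(config.n_validation_families):
            s, d = rng.choice(prev, size=2, replace=False)
            for _ in range(config.family_size):
                sire.append(int(s))
                dam.append(int(d))
                gen.append(g)
                fam.append(f)

    phenotyped = np.arange(len(sire)) < n_train
    return Pedigree(
        np.asarray(sire), np.asarray(dam),
        generation=np.asarray(gen), phenotyped=phenotyped, family=np.asarray(fam),
    )


def simulate_genotypes(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None,
    founder_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Gene-drop genotypes through the pedigree, loci unlinked.

    Founder allele frequencies are drawn per locus from Uniform(0.05,
    0.95) and founder codes from Binomial(2, f).  Each offspring receives
    one allele from each parent; because loci are transmitted
    independently, the allele a parent passes at a locus is Bernoulli
    with probability code/2, which is the exact Mendelian law without
    tracking phase.
    """
    config.validate()
    if rng is None:
        rng = _spawn_streams(config.seed)["genotypes"]
    p = config.n_snp
    if founder_freqs is None:
        founder_freqs = rng.uniform(0.05, 0.95, size=p)
    founder_freqs = np.asarray(founder_freqs, dtype=float)

    n = pedigree.n_animals
    G = np.zeros((n, p), dtype=np.int8)
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            G[i] = rng.binomial(2, founder_freqs)
        else:
            a1 = rng.random(p) < G[s] / 2.0
            a2 = rng.random(p) < G[d] / 2.0
            G[i] = a1.astype(np.int8) + a2.astype(np.int8)
    return G


def simulate_genotypes_tagged(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotypes for the tagged (LD-emulation) architecture.

    Each of the ``n_qtl`` causal loci is untyped; ``n_tags_per_qtl``
    typed SNP columns per QTL are completely linked duplicates of the
    causal locus whose founder alleles copy the causal allele with
    probability 1 - tag_allele_error (otherwise an independent draw at
    the causal frequency).  Complete linkage is realised by a
    phase-aware gene drop: a single descent tree of founder-gene labels
    per QTL cluster, with causal and tag alleles assigned by
    per-founder-gene lookup.  Tags are therefore Mendelian-consistent
    loci whose association with the causal locus never decays.

    Returns (typed genotypes n x p, causal genotypes n x n_qtl,
    tag column indices n_qtl x n_tags_per_qtl).
    """
    config.validate()
    if rng is None:
        rng = _spawn_streams(config.seed)["genotypes"]
    G = simulate_genotypes(pedigree, config, rng)  # background typed SNPs
    n, nq, m = pedigree.n_animals, config.n_qtl, config.n_tags_per_qtl
    eps = config.tag_allele_error
    freqs = rng.uniform(0.2, 0.8, size=nq)  # causal frequencies away from fixation

    # descent tree of founder-gene labels, one per QTL cluster
    gene = np.zeros((n, 2, nq), dtype=np.int32)
    cluster = np.arange(nq)
    k = 0
    for i in range(n):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if s == UNKNOWN or d == UNKNOWN:
            gene[i, 0, :] = 2 * k
            gene[i, 1, :] = 2 * k + 1
            k += 1
        else:
            gene[i, 0, :] = gene[s][rng.integers(0, 2, size=nq), cluster]
            gene[i, 1, :] = gene[d][rng.integers(0, 2, size=nq), cluster]
    n_genes = 2 * k

    causal_map = (rng.random((n_genes, nq)) < freqs).astype(np.int8)
    causal = (causal_map[gene[:, 0, :], cluster[None, :]]
              + causal_map[gene[:, 1, :], cluster[None, :]])

    tag_cols = np.sort(rng.choice(config.n_snp, size=nq * m, replace=False)).reshape(nq, m)
    for t in range(m):
        err = rng.random((n_genes, nq)) < eps
        fresh = (rng.random((n_genes, nq)) < freqs).astype(np.int8)
        tag_map = np.where(err, fresh, causal_map)
        tagG = (tag_map[gene[:, 0, :], cluster[None, :]]
                + tag_map[gene[:, 1, :], cluster[None, :]])
        G[:, tag_cols[:, t]] = tagG
    return G, causal, tag_cols


def _qtl_variance_shares(G_qtl: np.ndarray, effects: np.ndarray) -> np.ndarray:
    """Realized per-QTL, per-timepoint genetic-variance shares.

    share[j, t] = var(x_j * beta_j(t)) / var(sum_k x_k * beta_k(t)),
    variances taken over the simulated animals.
    """
    col_var = G_qtl.astype(float).var(axis=0)
    tbv = G_qtl.astype(float) @ effects
    total = tbv.var(axis=0)
    per_qtl = col_var[:, None] * effects**2
    return per_qtl / total[None, :]


def assign_qtl_effects(
    genotypes: np.ndarray, config: SimulationConfig, rng: np.random.Generator | None = None,
    causal_genotypes: np.ndarray | None = None,
) -> TruthSet:
    """Choose QTL columns and per-time-point additive effects.

    Effects are linear in time with QTL-specific slopes, so each animal's
    total additive value is linear in time.  Per-QTL variance
    contributions are drawn from an exponential profile (a few large, a
    long tail of small QTL) and then iteratively rescaled so that the
    realized share of genetic variance explained by the largest QTL — the
    maximum over QTL and phenotyped time points — equals
    ``max_qtl_variance_share`` within +-0.01.
    """
    config.validate()
    if rng is None:
        rng = _spawn_streams(config.seed)["effects"]
    n_qtl, p = config.n_qtl, config.n_snp
    if causal_genotypes is not None:
        # tagged mode: the causal loci are given, one column per QTL
        if causal_genotypes.shape[1] != n_qtl:
            raise ConfigurationError("causal genotype matrix width does not match n_qtl")
        qtl = np.arange(n_qtl)
        G_qtl = causal_genotypes.astype(float)
        if np.any(G_qtl.var(axis=0) <= 0):
            raise ConfigurationError("monomorphic causal locus; re-seed the generator")
    else:
        if genotypes.shape[1] != p:
            raise ConfigurationError("genotype matrix width does not match n_snp")
        # QTL columns: sample without replacement among polymorphic SNPs
        col_var = genotypes.astype(float).var(axis=0)
        polymorphic = np.where(col_var > 0)[0]
        if polymorphic.size < n_qtl:
            raise ConfigurationError("not enough polymorphic SNPs to place the QTL")
        qtl = np.sort(rng.choice(polymorphic, size=n_qtl, replace=False))
        G_qtl = genotypes[:, qtl].astype(float)
    vq = G_qtl.var(axis=0)

    # target variance shares: exponential profile, largest pinned at the cap
    raw = rng.exponential(size=n_qtl)
    shares = raw / raw.sum()
    cap = config.max_qtl_variance_share
    if n_qtl > 1:
        if cap * n_qtl <= 1.0:
            raise ConfigurationError("max_qtl_variance_share too small: cap * n_qtl must exceed 1")
        for _ in range(200):
            # clamp everything above the cap, renormalize the rest
            over = shares > cap + 1e-12
            if over.any():
                shares[over] = cap
                rest = ~over
                shares[rest] *= (1.0 - cap * over.sum()) / shares[rest].sum()
                continue
            if np.isclose(shares.max(), cap, atol=1e-9):
                break
            # all below the cap: pin the current largest exactly at it
            j = int(np.argmax(shares))
            other = np.arange(n_qtl) != j
            shares[other] *= (1.0 - cap) / shares[other].sum()
            shares[j] = cap
    base_var = config.genetic_sd**2
    signs = rng.choice([-1.0, 1.0], size=n_qtl)
    beta_mid = signs * np.sqrt(shares * base_var / vq)

    # linear time profile per QTL around the middle phenotyped time point
    tp = config.timepoints
    t_mid = tp[len(tp) // 2]
    t_span = tp[-1] - tp[0]
    slopes = np.clip(rng.normal(0.3, 0.15, size=n_qtl), -0.2, 0.8)
    eval_tp = np.append(tp, EXTRAPOLATION_TIMEPOINT)
    profile = 1.0 + slopes[:, None] * (eval_tp[None, :] - t_mid) / t_span
    profile = np.maximum(profile, 0.05)  # keep effects from flipping sign over the window
    effects = beta_mid[:, None] * profile  # n_qtl x n_eval_timepoints

    # enforce the realized largest-QTL share over the phenotyped time points
    n_pheno_tp = tp.size
    if n_qtl > 1:
        for _ in range(100):
            sh = _qtl_variance_shares(G_qtl, effects[:, :n_pheno_tp])
            worst = float(sh.max())
            if abs(worst - cap) <= 0.005:
                break
            # exact single-QTL solve at the worst (QTL, time) cell: rescale
            # beta_j (at all time points) so v_j' / (V - v_j + v_j') = cap there
            j, t = np.unravel_index(int(np.argmax(sh)), sh.shape)
            tbv_t = G_qtl @ effects[:, t]
            V = tbv_t.var()
            v_j = vq[j] * effects[j, t] ** 2
            v_target = cap * (V - v_j) / (1.0 - cap)
            effects[j] *= np.sqrt(v_target / v_j)

    tbv = G_qtl @ effects
    return TruthSet(
        qtl_indices=qtl,
        qtl_effects_per_timepoint=effects,
        true_breeding_values=tbv,
        eval_timepoints=eval_tp,
        causal_genotypes=None if causal_genotypes is None else causal_genotypes.copy(),
    )


def simulate_phenotypes(
    genotypes: np.ndarray,
    truth: TruthSet,
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Phenotypes ``y_i(t) = mu(t) + TBV_i(t) + e_i(t)``.

    The residual variance at each time point is set from the realized TBV
    variance among phenotyped animals so that var(TBV)/var(y) matches the
    configured heritability in expectation.  No polygenic effect is
    simulated: all genetic variance is attributable to the QTL, matching
    the marker-determined architecture of the emulated benchmark.
    Validation animals keep their genotypes but get NaN phenotypes.

    Returns (phenotypes, mu_per_timepoint, residual_var_per_timepoint).
    """
    config.validate()
    if rng is None:
        rng = _spawn_streams(config.seed)["phenotypes"]
    tp = config.timepoints
    n = pedigree.n_animals
    mu = config.base_mean + config.mean_growth_per_day * (tp - tp[0])
    tbv = truth.true_breeding_values[:, : tp.size]

    train = pedigree.phenotyped
    var_g = tbv[train].var(axis=0)
    h2 = config.heritability
    var_e = var_g * (1.0 - h2) / h2

    y = mu[None, :] + tbv + rng.normal(size=(n, tp.size)) * np.sqrt(var_e)[None, :]
    y[~train] = np.nan
    return y, mu, var_e


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> Dataset:
    """Run the full generator: pedigree -> genotypes -> QTL -> phenotypes."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    streams = _spawn_streams(config.seed)
    ped = make_pedigree(config, streams["pedigree"])
    if config.qtl_mode == "tagged":
        G, causal, tag_cols = simulate_genotypes_tagged(ped, config, streams["genotypes"])
        truth = assign_qtl_effects(G, config, streams["effects"], causal_genotypes=causal)
        truth.tag_indices = tag_cols
        truth.qtl_indices = tag_cols[:, 0].copy()
    else:
        G = simulate_genotypes(ped, config, streams["genotypes"])
        truth = assign_qtl_effects(G, config, streams["effects"])
    y, mu, var_e = simulate_phenotypes(G, truth, ped, config, streams["phenotypes"])
    return Dataset(
        config=config, pedigree=ped, genotypes=G, phenotypes=y,
        mu_per_timepoint=mu, residual_var_per_timepoint=var_e, truth=truth,
    )
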