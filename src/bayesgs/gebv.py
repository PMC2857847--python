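"""Genomic breeding-value prediction and extrapolation to t = 600.

GEBV_i = sum_j x_ij * beta_hat_j with posterior-mean marker effects; the
pedigree polygenic term is excluded by default because unphenotyped
validation animals carry no polygenic estimate of their own and the
emulated data's genetic variance is entirely marker-determined.  The
growth trait is linear over the phenotyped window, so the value at an
unobserved later time point is obtained per animal by ordinary least
squares through the per-time-point GEBVs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorSummary

EXTRAPOLATION_TIMEPOINT = 600.0


def compute_gebv(
    genotypes: np.ndarray,
    posterior: PosteriorSummary,
    include_polygenic: bool = False,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Per-animal GEBV at the posterior's time point.

    Raises on missing genotype codes (no imputation is in scope).  With
    ``include_polygenic`` the posterior-mean u is added for the animals
    it was estimated on (``u`` must then align with the genotype rows).
    """
    G = np.asarray(genotypes, dtype=np.float64)
    if np.any(~np.isfinite(G)):
        raise ValueError("genotype matrix contains missing codes; imputation is out of scope")
    if G.shape[1] != posterior.beta.size:
        raise ValueError("genotype width does not match number of SNP effects")
    gebv = G @ posterior.beta
    if include_polygenic:
        uu = posterior.u if u is None else u
        if uu.shape[0] != G.shape[0]:
            raise ValueError("polygenic vector does not align with genotype rows")
        gebv = gebv + uu
    return gebv


def extrapolate(
    gebv_by_timepoint: np.ndarray,
    timepoints,
    target: float = EXTRAPOLATION_TIMEPOINT,
) -> np.ndarray:
    """OLS line per animal through (timepoint, GEBV) pairs, read at ``target``.

    ``gebv_by_timepoint`` is animals x timepoints.  Closed-form simple
    regression: slope = S_ty / S_tt on centered abscissae, value =
    mean + slope * (target - mean(t)).  Non-finite inputs propagate as
    NaN for the affected animal, with a warning.
    """
    g = np.asarray(gebv_by_timepoint, dtype=np.float64)
    t = np.asarray(timepoints, dtype=np.float64)
    if g.ndim != 2 or g.shape[1] != t.size or t.size < 2:
        raise ValueError("need an animals x timepoints array with >= 2 time points")
    bad = ~np.isfinite(g).all(axis=1)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} animals have non-finite GEBV; propagating NaN")
    tc = t - t.mean()
    slope = (g @ tc) / (tc @ tc)
    out = g.mean(axis=1) + slope * (target - t.mean())
    out[bad] = np.nan
    return out


def extrapolate_t600(gebv_265, gebv_397, gebv_530) -> np.ndarray:
    """Convenience wrapper for the study's three phenotyped time points."""
    g = np.column_stack([
        np.atleast_1d(np.asarray(gebv_265, dtype=float)),
        np.atleast_1d(np.asarray(gebv_397, dtype=float)),
        np.atleast_1d(np.asarray(gebv_530, dtype=float)),
    ])
    return extrapolate(g, (265.0, 397.0, 530.0), EXTRAPOLATION_TIMEPOINT)


@dataclass
class GEBVTable:
    """Per-animal GEBV at each phenotyped time point plus the target."""

    method: str
    animal_ids: np.ndarray
    timepoints: np.ndarray
    gebv: np.ndarray  # animals x timepoints
    gebv_target: np.ndarray
    target: float = EXTRAPOLATION_TIMEPOINT

    @classmethod
    def from_posteriors(
        cls, method: str, genotypes: np.ndarray, posteriors: list[PosteriorSummary],
        animal_ids: np.ndarray | None = None, target: float = EXTRAPOLATION_TIMEPOINT,
        include_polygenic: bool = False,
    ) -> "GEBVTable":
        tps = np.array([p.timepoint for p in posteriors], dtype=float)
        if np.any(np.isnan(tps)):
            raise ValueError("every posterior needs its timepoint label")
        order = np.argsort(tps)
        g = np.column_stack([
            compute_gebv(genotypes, posteriors[i], include_polygenic=include_polygenic)
            for i in order
        ])
        ids = np.arange(1, genotypes.shape[0] + 1) if animal_ids is None else animal_ids
        return cls(
            method=method, animal_ids=np.asarray(ids), timepoints=tps[order], gebv=g,
            gebv_target=extrapolate(g, tps[order], target), target=target,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"animal_id": self.animal_ids})
        for i, t in enumerate(self.timepoints):
            df[f"gebv_{t:g}"] = self.gebv[:, i]
        df[f"gebv_{self.target:g}"] = self.gebv_target
        return df
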