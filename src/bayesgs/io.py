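"""Plain-text readers and writers for the pipeline's tabular artifacts.

All formats are CSV with a header row and 1-based animal ids; missing
phenotypes are written as NA.  Binary chain dumps are deliberately not
produced — everything stays inspectable at desk scale.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gebv import GEBVTable
from .model import PosteriorSummary
from .pedigree import Pedigree, read_pedigree, write_pedigree  # re-export

__all__ = [
    "read_pedigree", "write_pedigree",
    "write_genotypes", "read_genotypes",
    "write_phenotypes", "read_phenotypes",
    "write_truth", "read_truth",
    "write_posterior", "read_posterior_effects",
    "write_gebv_table", "read_gebv_table",
]


def write_genotypes(genotypes: np.ndarray, path) -> None:
    """`animal_id` then one integer 0/1/2 column per SNP (snp_1..snp_p)."""
    n, p = genotypes.shape
    df = pd.DataFrame(genotypes, columns=[f"snp_{j + 1}" for j in range(p)])
    df.insert(0, "animal_id", np.arange(1, n + 1))
    df.to_csv(path, index=False)


def read_genotypes(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.drop(columns=["animal_id"]).to_numpy(dtype=np.int8)


def write_phenotypes(phenotypes: np.ndarray, timepoints, path) -> None:
    """`animal_id, y<t1>, y<t2>, ...`; unphenotyped animals marked NA."""
    cols = {f"y{t:g}": phenotypes[:, i] for i, t in enumerate(np.asarray(timepoints))}
    df = pd.DataFrame({"animal_id": np.arange(1, phenotypes.shape[0] + 1), **cols})
    df.to_csv(path, index=False, na_rep="NA")


def read_phenotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (phenotypes, timepoints); NA parses to NaN."""
    df = pd.read_csv(path, na_values=["NA"])
    ycols = [c for c in df.columns if c.startswith("y")]
    tps = np.array([float(c[1:]) for c in ycols])
    return df[ycols].to_numpy(dtype=float), tps


def write_truth(truth, path_tbv, path_qtl) -> None:
    tps = truth.eval_timepoints
    cols = {f"tbv_{t:g}": truth.true_breeding_values[:, i] for i, t in enumerate(tps)}
    pd.DataFrame(
        {"animal_id": np.arange(1, truth.true_breeding_values.shape[0] + 1), **cols}
    ).to_csv(path_tbv, index=False)
    qcols = {f"effect_{t:g}": truth.qtl_effects_per_timepoint[:, i] for i, t in enumerate(tps)}
    pd.DataFrame({"snp_index": truth.qtl_indices + 1, **qcols}).to_csv(path_qtl, index=False)


def read_truth(path_tbv, path_qtl=None):
    """Returns a TruthSet; QTL info is optional (zeros if absent)."""
    from .simulate import TruthSet

    df = pd.read_csv(path_tbv)
    tcols = [c for c in df.columns if c.startswith("tbv_")]
    tps = np.array([float(c[4:]) for c in tcols])
    tbv = df[tcols].to_numpy(dtype=float)
    if path_qtl is not None and Path(path_qtl).exists():
        qf = pd.read_csv(path_qtl)
        qtl = qf["snp_index"].to_numpy(dtype=int) - 1
        effects = qf[[c for c in qf.columns if c.startswith("effect_")]].to_numpy(dtype=float)
    else:
        qtl = np.array([], dtype=int)
        effects = np.zeros((0, tps.size))
    return TruthSet(
        qtl_indices=qtl, qtl_effects_per_timepoint=effects,
        true_breeding_values=tbv, eval_timepoints=tps,
    )


def write_posterior(summary: PosteriorSummary, outdir, tag: str) -> None:
    """SNP-effect and animal-effect tables plus a scalar summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "snp_index": np.arange(1, summary.beta.size + 1),
        "beta_mean": summary.beta,
        "inclusion_prob": summary.inclusion_prob,
    }).to_csv(outdir / f"snp_effects_{tag}.csv", index=False)
    pd.DataFrame({
        "animal_id": np.arange(1, summary.u.size + 1),
        "u_mean": summary.u,
    }).to_csv(outdir / f"animal_effects_{tag}.csv", index=False)
    pd.DataFrame([{
        "method": summary.method.value, "timepoint": summary.timepoint,
        "mu": summary.mu, "sigma2_u": summary.sigma2_u, "sigma2_e": summary.sigma2_e,
        "n_samples": summary.n_samples,
    }]).to_csv(outdir / f"scalars_{tag}.csv", index=False)


def read_posterior_effects(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["beta_mean"].to_numpy(dtype=float), df["inclusion_prob"].to_numpy(dtype=float)


def write_gebv_table(table: GEBVTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_gebv_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
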