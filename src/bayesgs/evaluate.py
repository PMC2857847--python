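"""Scoring of predicted against true breeding values.

Implements the four report statistics — Pearson correlation, mean
squared error, top-100 rank accuracy and the bias regression slope —
plus the between-method correlation matrix and the Bayes C pi
sensitivity sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats

from .model import ChainConfig, Method, PriorSpec

DEFAULT_PI_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.6, 1.0)


def _pair(pred, true):
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.size != t.size:
        raise ValueError("prediction and truth vectors differ in length")
    return p, t


def correlation(pred, true) -> float:
    """Pearson product-moment correlation."""
    p, t = _pair(pred, true)
    if p.size < 3:
        raise ValueError("need at least 3 pairs")
    if p.std() == 0 or t.std() == 0:
        raise ValueError("zero variance in one of the vectors")
    return float(stats.pearsonr(p, t).statistic)


def mse(pred, true) -> float:
    """Mean squared prediction error, trait units squared."""
    p, t = _pair(pred, true)
    return float(np.mean((p - t) ** 2))


def rank_accuracy(pred, true, top_n: int = 100) -> float:
    """Fraction of the true top-``top_n`` animals found in the predicted top-``top_n``.

    Ties are broken by animal position (lower index first), so the
    statistic is deterministic.
    """
    p, t = _pair(pred, true)
    if p.size < top_n:
        raise ValueError(f"need at least top_n={top_n} animals, got {p.size}")
    idx = np.arange(p.size)
    top_pred = set(idx[np.lexsort((idx, -p))][:top_n])
    top_true = set(idx[np.lexsort((idx, -t))][:top_n])
    return len(top_pred & top_true) / top_n


def rank_accuracy_spearman(pred, true, top_n: int = 100) -> float:
    """Alternative reading of "rank": Spearman correlation within the true top-``top_n``."""
    p, t = _pair(pred, true)
    idx = np.arange(p.size)
    top_true = idx[np.lexsort((idx, -t))][:top_n]
    return float(stats.spearmanr(p[top_true], t[top_true]).statistic)


def bias_regression(pred, true) -> float:
    """OLS slope of true on predicted; 1 means unbiased dispersion.

    Regressing truth on prediction is the animal-breeding convention for
    GEBV bias: a slope below 1 means predictions are over-dispersed.
    """
    p, t = _pair(pred, true)
    vp = p.var()
    if vp == 0:
        raise ValueError("zero variance in predictions")
    return float(np.cov(p, t, ddof=0)[0, 1] / vp)


def method_correlation_matrix(gebv_by_method: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson correlations between methods' GEBV, unit diagonal."""
    if len(gebv_by_method) < 2:
        raise ValueError("need at least two methods")
    names = list(gebv_by_method)
    lengths = {len(np.asarray(v).ravel()) for v in gebv_by_method.values()}
    if len(lengths) != 1:
        raise ValueError("methods report GEBV for differing animal sets")
    M = np.corrcoef(np.vstack([np.asarray(gebv_by_method[k]).ravel() for k in names]))
    return pd.DataFrame(np.atleast_2d(M), index=names, columns=names)


@dataclass
class EvaluationReport:
    """One method's agreement with the true breeding values."""

    method: str
    correlation: float
    mse: float
    rank_accuracy: float
    bias_slope: float
    top_n: int = 100
    rank_statistic: str = "top_n_overlap"  # alternative: spearman_top_n
    regression_direction: str = "true_on_predicted"

    @classmethod
    def from_vectors(cls, method: str, pred, true, top_n: int = 100,
                     rank_statistic: str = "top_n_overlap") -> "EvaluationReport":
        if rank_statistic == "top_n_overlap":
            rank = rank_accuracy(pred, true, top_n)
        elif rank_statistic == "spearman_top_n":
            rank = rank_accuracy_spearman(pred, true, top_n)
        else:
            raise ValueError(f"unknown rank statistic {rank_statistic!r}")
        return cls(
            method=method,
            correlation=correlation(pred, true),
            mse=mse(pred, true),
            rank_accuracy=rank,
            bias_slope=bias_regression(pred, true),
            top_n=top_n,
            rank_statistic=rank_statistic,
        )

    def to_dict(self) -> dict:
        return {
            "method": self.method, "correlation": self.correlation, "mse": self.mse,
            "rank": self.rank_accuracy, "regression": self.bias_slope,
        }


def report_table(reports: list[EvaluationReport]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in reports]).set_index("method")


def pi_sweep(
    dataset,
    pi_values=DEFAULT_PI_GRID,
    chain: ChainConfig | None = None,
    prior: PriorSpec | None = None,
    timepoints=None,
    A=None,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Bayes C sensitivity to the mixture proportion pi.

    Fits Bayes C at every pi on the grid, predicts validation-set GEBV
    at the extrapolation target and scores them against the true
    breeding values.  Returns one row per pi with the report statistics.
    """
    from .pipeline import fit_method_gebv  # local import: pipeline imports evaluate

    if chain is None:
        chain = ChainConfig()
    if prior is None:
        prior = PriorSpec(method=Method.C)
    rows = []
    val = dataset.validation_mask
    tbv = dataset.truth.tbv_at(dataset.truth.eval_timepoints[-1])[val]
    n_top = top_n if top_n is not None else min(100, int(val.sum()))
    for pi in pi_values:
        table = fit_method_gebv(
            dataset, dc_replace(prior, method=Method.C, pi=float(pi)), chain,
            A=A, timepoints=timepoints,
        )
        rep = EvaluationReport.from_vectors(
            f"bayesC(pi={pi:g})", table.gebv_target[val], tbv, top_n=n_top,
        )
        rows.append({"pi": float(pi), **rep.to_dict()})
    return pd.DataFrame(rows).set_index("pi")
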