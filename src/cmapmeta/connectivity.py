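"""Rank-correlation ("connectivity") between query contrasts and experiments.

The connectivity of a query signature *y* with a perturbation profile *x_i*
is the Spearman correlation rho_i = cor(R(x_i), R(y)), with R the average-tie
rank transform. It is computed on the gene intersection of query and
reference; where either vector has missing values, the pair is correlated on
its pairwise-complete genes. Zero-variance (constant) vectors yield a
missing correlation rather than a spurious number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import QueryMatrix, ReferenceDatabase

__all__ = ["ConnectivityMatrix", "rank_transform", "compute_connectivity"]

log = logging.getLogger(__name__)

#: Minimum gene overlap below which rank correlations are considered
#: too unstable to report.
DEFAULT_MIN_OVERLAP = 15


@dataclass
class ConnectivityMatrix:
    """Experiments x contrasts matrix of Spearman correlations in [-1, 1]."""

    rho: np.ndarray
    experiment_ids: list[str]
    contrast_names: list[str]
    n_genes_used: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        finite = self.rho[np.isfinite(self.rho)]
        if finite.size and (np.abs(finite) > 1 + 1e-12).any():
            raise ValueError("correlations outside [-1, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.experiment_ids,
                            columns=self.contrast_names)


def rank_transform(v: np.ndarray) -> np.ndarray:
    """Average-tie ranks of a vector; NaNs stay NaN and receive no rank.

    The observed values get ranks that are a permutation-with-ties of the
    averages of 1..m (m = number of observed values).
    """
    v = np.asarray(v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to rank")
    if np.isnan(v).all():
        raise ValueError("all-missing vector cannot be ranked")
    return stats.rankdata(v, method="average", nan_policy="omit")


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation matrix between a (n x p) and b (n x q)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / np.outer(sa, sb)
    r[:, sb == 0] = np.nan
    r[sa == 0, :] = np.nan
    return np.clip(r, -1.0, 1.0, out=r)  # NaN passes through unchanged


def compute_connectivity(
    query: QueryMatrix,
    ref: ReferenceDatabase,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> ConnectivityMatrix:
    """Spearman correlation of every reference experiment with every contrast.

    Parameters
    ----------
    query, ref
        The query signature(s) and the perturbation reference. Genes are
        matched by exact (whitespace-trimmed) identifier.
    min_overlap
        Required size of the gene intersection; smaller overlaps raise.

    Returns
    -------
    ConnectivityMatrix
        ``rho[i, c]`` is the connectivity of experiment *i* with contrast
        *c*; NaN where a vector was constant on the complete genes.
    """
    ref_pos = {g: k for k, g in enumerate(ref.gene_ids)}
    common = [g for g in query.gene_ids if g in ref_pos]
    n = len(common)
    if n < min_overlap:
        raise ValueError(
            f"gene intersection of query and reference has size {n}, "
            f"below the required minimum of {min_overlap}"
        )
    q_pos = {g: k for k, g in enumerate(query.gene_ids)}
    y = query.values[[q_pos[g] for g in common], :]
    x = ref.values[[ref_pos[g] for g in common], :]

    if not (np.isnan(x).any() or np.isnan(y).any()):
        # complete data: rank once per column, then one matrix product
        xr = stats.rankdata(x, method="average", axis=0)
        yr = stats.rankdata(y, method="average", axis=0)
        rho = _pearson_columns(xr, yr)
    else:
        rho = np.full((x.shape[1], y.shape[1]), np.nan)
        for c in range(y.shape[1]):
            yc = y[:, c]
            for i in range(x.shape[1]):
                xi = x[:, i]
                ok = ~(np.isnan(xi) | np.isnan(yc))
                if ok.sum() < min_overlap:
                    continue
                xr = rank_transform(xi[ok])
                yr = rank_transform(yc[ok])
                if np.ptp(xr) == 0 or np.ptp(yr) == 0:
                    continue  # zero variance -> missing
                rho[i, c] = np.corrcoef(xr, yr)[0, 1]
        np.clip(rho, -1.0, 1.0, out=rho)

    n_missing = int(np.isnan(rho).sum())
    if n_missing:
        log.info("connectivity: %d of %d entries missing (zero variance or "
                 "insufficient overlap)", n_missing, rho.size)
    return ConnectivityMatrix(rho, list(ref.experiment_ids),
                              list(query.contrast_names), n)
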