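"""Regulatory-factor enrichment at promoters of a gene set.

Input is a binary occupancy matrix (factors x genes).  For each factor the
question is whether it binds promoters of the query set (say, reductive-
charging-phase genes) more often than expected from its genome-wide
binding frequency; the test is the hypergeometric upper tail, and a factor
is called significant at raw p < alpha (default 0.01), the criterion the
motivating analysis used.  Benjamini-Hochberg q-values are reported
alongside for reference but do not drive the flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class FactorOccupancyMatrix:
    """Boolean factors x genes matrix wrapped around a DataFrame."""

    bound: pd.DataFrame  # index: factor names; columns: gene ids; dtype bool

    def __post_init__(self):
        self.bound = self.bound.astype(bool)
        if self.bound.index.duplicated().any():
            raise ValueError("duplicate factor names")
        if self.bound.columns.duplicated().any():
            raise ValueError("duplicate gene ids")

    @property
    def factors(self) -> list[str]:
        return list(self.bound.index)

    @property
    def genes(self) -> list[str]:
        return list(self.bound.columns)

    @classmethod
    def read_tsv(cls, path) -> "FactorOccupancyMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int).astype(bool))

    def write_tsv(self, path) -> None:
        self.bound.astype(int).to_csv(path, sep="\t")


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def factor_enrichment_test(matrix: FactorOccupancyMatrix, gene_set,
                           alpha: float = 0.01) -> pd.DataFrame:
    """Hypergeometric enrichment of each factor in ``gene_set``.

    ``p_hyper`` is P(X >= observed bound-in-set) when |gene_set| genes are
    drawn from the matrix's gene universe containing the factor's bound
    genes as successes.  A factor bound to zero genes gets p = 1 and a
    ``degenerate`` flag.

    Returns one row per factor: ``factor, n_bound_in_set, n_bound_total,
    p_hyper, q_bh, significant, degenerate``.
    """
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("gene set is empty")
    universe = set(matrix.genes)
    if not gene_set <= universe:
        missing = sorted(gene_set - universe)[:5]
        raise ValueError(f"gene set not within matrix genes, e.g. {missing}")
    n_u = len(universe)
    n_set = len(gene_set)
    in_set = matrix.bound.columns.isin(gene_set)
    bound = matrix.bound.to_numpy()
    n_bound_total = bound.sum(axis=1)
    n_bound_in_set = bound[:, in_set].sum(axis=1)
    p = hypergeom.sf(n_bound_in_set - 1, n_u, n_bound_total, n_set)
    p = np.minimum(p, 1.0)
    degenerate = (n_bound_total == 0) | (n_bound_total == n_u)
    p = np.where(n_bound_total == 0, 1.0, p)
    out = pd.DataFrame({
        "factor": matrix.factors,
        "n_bound_in_set": n_bound_in_set.astype(int),
        "n_bound_total": n_bound_total.astype(int),
        "p_hyper": p,
        "q_bh": _bh_qvalues(p),
        "degenerate": degenerate,
    })
    out["significant"] = out["p_hyper"] < alpha
    return out
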