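"""Genetic similarity between Mendelian diseases and cancers.

Two metrics: (1) significance of the overlap between the Mendelian causal
gene set and the cancer driver set (one-sided hypergeometric / Fisher
tail); (2) tissue co-expression — for each cancer driver gene, whether
the Mendelian genes' expression correlations with it across tissues are
larger than the background of all other genes (one-sided rank-sum),
Benjamini-Hochberg adjusted over that cancer's tested drivers.  A pair is
genetically similar when either metric is significant at 0.05.

Correlation is Spearman across tissues by default (robust to the heavy
right skew of expression summaries); Pearson on log1p values is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .core import MendelianDisease
from .stat_tests import bh_adjust, hypergeom_overlap_p, rank_sum_greater

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SimilarityCall",
    "gene_overlap_test",
    "coexpression_test",
    "similarity_call",
    "similarity_table",
]

ALPHA = 0.05


class ExpressionMatrix:
    """A complete gene x tissue expression matrix.

    Genes lacking a value in every tissue are dropped at load time (with a
    log message); at least three tissues are required.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.dropna(axis=0, how="any")
        if values.shape[1] < 3:
            raise ValueError("expression matrix needs at least 3 tissues")
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        self.values = values
        self._ranks: np.ndarray | None = None
        self._log: np.ndarray | None = None

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns

    def __contains__(self, gene: str) -> bool:
        return gene in self.values.index

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        """Build from long-form (gene, tissue, value) records.

        Genes without a value for every tissue are removed, mirroring the
        dropna in the constructor.
        """
        wide = df.pivot_table(
            index="gene", columns="tissue", values="value", aggfunc="mean"
        )
        n_before = wide.shape[0]
        out = cls(wide)
        n_dropped = n_before - out.values.shape[0]
        if n_dropped:
            logger.info(
                "dropped %d genes without full tissue coverage (%d kept)",
                n_dropped,
                out.values.shape[0],
            )
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        if {"gene", "tissue", "value"} <= set(df.columns):
            return cls.from_long(df)
        return cls(df.set_index(df.columns[0]))

    def _centered(self, method: str) -> np.ndarray:
        """Row-standardized matrix for the chosen correlation; zero-variance
        rows standardize to all-zero (their correlations come out NaN)."""
        if method == "spearman":
            if self._ranks is None:
                x = self.values.rank(axis=1).to_numpy(dtype=float)
                self._ranks = _standardize_rows(x)
            return self._ranks
        if method == "pearson_log":
            if self._log is None:
                self._log = _standardize_rows(np.log1p(self.values.to_numpy(float)))
            return self._log
        raise ValueError(f"unknown correlation method {method!r}")

    def correlations_with(self, gene: str, method: str = "spearman") -> pd.Series:
        """Correlation of every other gene with ``gene`` across tissues.

        Zero-variance genes yield NaN.  The anchor gene is excluded.
        """
        if gene not in self:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        z = self._centered(method)
        i = self.values.index.get_loc(gene)
        anchor = z[i]
        if not anchor.any():
            raise ValueError(f"gene {gene!r} has constant expression")
        corr = z @ anchor
        with np.errstate(invalid="ignore"):
            corr = np.where((z != 0).any(axis=1), corr, np.nan)
        out = pd.Series(corr, index=self.values.index)
        return out.drop(gene)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    norm = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(norm > 0, centered / norm, 0.0)
    return z


@dataclass(frozen=True)
class SimilarityCall:
    """Combined similarity verdict for one Mendelian-cancer pair."""

    mendelian_id: str
    cancer_id: str
    overlap_p: float
    coexpr_min_adj_p: float | None
    similar: bool


def gene_overlap_test(
    mendelian_genes: frozenset[str] | set[str],
    cancer_genes: frozenset[str] | set[str],
    universe: frozenset[str] | set[str],
) -> float:
    """One-sided hypergeometric enrichment p for the set overlap."""
    for label, genes in (("mendelian", mendelian_genes), ("cancer", cancer_genes)):
        extra = sorted(set(genes) - set(universe))
        if extra:
            raise ValueError(f"{label} genes outside the universe: {extra}")
    k = len(set(mendelian_genes) & set(cancer_genes))
    return hypergeom_overlap_p(
        k, len(set(mendelian_genes)), len(set(cancer_genes)), len(set(universe))
    )


def coexpression_test(
    cancer_gene: str,
    mendelian_genes: Iterable[str],
    expr: ExpressionMatrix,
    method: str = "spearman",
) -> float:
    """Raw one-sided rank-sum p that the Mendelian genes correlate more
    strongly with ``cancer_gene`` than the background of all other genes.

    The cancer gene itself is excluded from both groups; zero-variance
    genes are dropped from the comparison with a log message.
    """
    mend = sorted(set(mendelian_genes) & set(expr.genes) - {cancer_gene})
    if not mend:
        raise ValueError("no Mendelian gene with expression data")
    corr = expr.correlations_with(cancer_gene, method=method)
    n_bad = int(corr.isna().sum())
    if n_bad:
        logger.info("dropped %d constant-expression genes from background", n_bad)
        corr = corr.dropna()
    mend = [g for g in mend if g in corr.index]
    if not mend:
        raise ValueError("no Mendelian gene with non-constant expression")
    mend_corr = corr.loc[mend].to_numpy()
    background = corr.drop(mend).to_numpy()
    if background.size == 0:
        raise ValueError("empty background: Mendelian set covers all other genes")
    return rank_sum_greater(mend_corr, background)


def similarity_call(
    mendelian: MendelianDisease,
    cancer_id: str,
    cancer_genes: frozenset[str] | set[str],
    expr: ExpressionMatrix | None,
    universe: frozenset[str] | set[str] | None = None,
    method: str = "spearman",
    alpha: float = ALPHA,
) -> SimilarityCall:
    """Combined similarity verdict for one (Mendelian disease, cancer) pair.

    The overlap test uses ``universe`` (default: all genes in the
    expression matrix; gene sets are restricted to it first).  The
    co-expression metric runs per cancer driver with expression data, is
    BH-adjusted across those drivers, and is skipped — leaving the verdict
    to the overlap metric alone — when no Mendelian gene has expression.
    """
    if not cancer_genes:
        raise ValueError(f"cancer {cancer_id!r} has an empty driver set")
    if universe is None:
        if expr is None:
            raise ValueError("need either a universe or an expression matrix")
        universe = frozenset(expr.genes)
    universe = frozenset(universe)
    mend_in = frozenset(mendelian.causal_genes) & universe
    canc_in = frozenset(cancer_genes) & universe
    n_out = len(mendelian.causal_genes) + len(cancer_genes) - len(mend_in) - len(canc_in)
    if n_out:
        logger.debug(
            "pair (%s, %s): %d genes outside universe ignored in overlap test",
            mendelian.id,
            cancer_id,
            n_out,
        )
    overlap_p = gene_overlap_test(mend_in, canc_in, universe)

    coexpr_min: float | None = None
    if expr is not None:
        mend_expr = set(mendelian.causal_genes) & set(expr.genes)
        drivers = sorted(set(cancer_genes) & set(expr.genes))
        if mend_expr and drivers:
            raw = []
            for driver in drivers:
                try:
                    raw.append(coexpression_test(driver, mend_expr, expr, method))
                except ValueError as exc:
                    logger.debug("driver %s skipped: %s", driver, exc)
            if raw:
                coexpr_min = float(bh_adjust(raw).min())
        else:
            logger.info(
                "pair (%s, %s): co-expression skipped (no expressed genes); "
                "verdict rests on overlap",
                mendelian.id,
                cancer_id,
            )
    similar = overlap_p < alpha or (coexpr_min is not None and coexpr_min < alpha)
    return SimilarityCall(
        mendelian_id=mendelian.id,
        cancer_id=cancer_id,
        overlap_p=overlap_p,
        coexpr_min_adj_p=coexpr_min,
        similar=similar,
    )


def similarity_table(
    mendelian: Mapping[str, MendelianDisease],
    cancer_gene_sets: Mapping[str, frozenset[str]],
    expr: ExpressionMatrix | None,
    universe: frozenset[str] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """All-pairs similarity calls as a tidy frame."""
    rows = []
    for mid in sorted(mendelian):
        for cid in sorted(cancer_gene_sets):
            call = similarity_call(
                mendelian[mid],
                cid,
                cancer_gene_sets[cid],
                expr,
                universe=universe,
                method=method,
            )
            rows.append(
                {
                    "mendelian_id": call.mendelian_id,
                    "cancer_id": call.cancer_id,
                    "overlap_p": call.overlap_p,
                    "coexpr_min_adj_p": call.coexpr_min_adj_p,
                    "similar": call.similar,
                }
            )
    return pd.DataFrame(rows)
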