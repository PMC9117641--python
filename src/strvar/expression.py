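"""Tissue expression profiling and gene-set over-representation.

Expression values are rank-normalized within each tissue independently
(removing the cross-tissue depth bias of mean-expression matrices), gene
sets are profiled by their mean normalized expression per tissue, and
over-representation uses two-sided Fisher's exact tests with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import EmptySubsetError, InputError, NormalizationError

DEFAULT_ALPHA = 0.01


def rank_normalize(expression: pd.DataFrame) -> pd.DataFrame:
    """Rank-transform a genes x tissues matrix within each tissue.

    Each column's values are replaced by ascending midranks scaled to
    [0, 1] via (rank - 1) / (G - 1): monotone in expression, idempotent,
    and invariant under any strictly monotone transform of the column.
    """
    if expression.shape[0] < 2:
        raise NormalizationError("rank normalization needs >= 2 genes")
    if (expression.to_numpy(dtype=float) < 0).any():
        raise InputError("expression values must be non-negative")
    g = expression.shape[0]
    ranks = expression.apply(lambda col: stats.rankdata(col, method="average"), axis=0)
    return (ranks - 1.0) / (g - 1.0)


def tissue_profile(
    normalized: pd.DataFrame, gene_set: Iterable[str]
) -> tuple[pd.Series, list[str]]:
    """Per-tissue mean normalized expression of a gene set, sorted descending.

    Returns ``(profile, missing)`` where ``missing`` lists gene-set members
    absent from the matrix. Raises :class:`EmptySubsetError` when no member
    is present.
    """
    genes = set(gene_set)
    present = normalized.index.intersection(list(genes))
    if present.empty:
        raise EmptySubsetError("gene set has no members in the expression matrix")
    missing = sorted(genes - set(present))
    profile = normalized.loc[present].mean(axis=0).sort_values(ascending=False)
    profile.name = "mean_normalized_expression"
    return profile, missing


def fisher_enrichment(
    gene_set: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Fisher over-representation of a gene set against term annotations.

    For each term the 2x2 table (in-set/out-set x in-term/out-term) over
    the universe is tested two-sided; p-values are Benjamini-Hochberg
    adjusted across all tested terms. A term is called ``significant`` when
    its adjusted p < ``alpha`` and its odds ratio exceeds 1. Rows are
    sorted by adjusted p then term. Terms are intersected with the
    universe; empty terms are dropped.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty gene universe")
    genes = set(gene_set)
    outside = genes - universe
    if outside:
        raise InputError(
            f"gene set members outside the universe: {sorted(outside)[:5]}..."
            if len(outside) > 5
            else f"gene set members outside the universe: {sorted(outside)}"
        )
    n, big_n = len(genes), len(universe)
    rows = []
    for term, members in terms.items():
        term_genes = set(members) & universe
        big_k = len(term_genes)
        if big_k == 0:
            continue
        k = len(genes & term_genes)
        table = [[k, n - k], [big_k - k, big_n - n - big_k + k]]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {"term": term, "k": k, "K": big_k, "n": n, "N": big_n,
             "odds_ratio": float(odds), "p": float(p)}
        )
    result = pd.DataFrame(
        rows, columns=["term", "k", "K", "n", "N", "odds_ratio", "p"]
    )
    if len(result):
        result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
        result["significant"] = (result["p_adj"] < alpha) & (result["odds_ratio"] > 1)
        result = result.sort_values(["p_adj", "term"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        result["p_adj"] = []
        result["significant"] = []
    return result


def tissue_enrichment(
    normalized: pd.DataFrame,
    gene_set: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-tissue Fisher test of gene-set association with high expression.

    For each tissue, genes are split at the within-tissue median of
    normalized expression and the 2x2 table (set membership x
    high-expression) is tested; BH-adjusted across tissues. This realises
    tissue-level significance calls on top of :func:`tissue_profile`.
    """
    genes = set(gene_set) & set(normalized.index)
    if not genes:
        raise EmptySubsetError("gene set has no members in the expression matrix")
    rows = []
    for tissue in normalized.columns:
        col = normalized[tissue]
        high = set(col[col > col.median()].index)
        k = len(genes & high)
        table = [
            [k, len(genes) - k],
            [len(high) - k, len(normalized.index) - len(genes) - len(high) + k],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append({"tissue": tissue, "k": k, "odds_ratio": float(odds), "p": float(p)})
    result = pd.DataFrame(rows)
    result["p_adj"] = multipletests(result["p"], method="fdr_bh")[1]
    result["significant"] = (result["p_adj"] < alpha) & (result["odds_ratio"] > 1)
    return result.sort_values(["p_adj", "tissue"], kind="mergesort").reset_index(drop=True)
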