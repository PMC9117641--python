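"""Per-sample repeat genotyping from read-level repeat counts.

A sample's genotype at a locus — its estimated repeat count (ERC) — is the
read-level count at the top-25% position of the reads sorted by decreasing
repeat size. Loci covered by fewer than ``min_coverage`` reads in a sample
are reported as missing. The high-rank (rather than median) position makes
the estimate robust to the undercount bias of read-level repeat callers.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import StrLocus
from .errors import InputError, UndefinedCorrelationError

DEFAULT_MIN_COVERAGE = 8
DEFAULT_ERC_QUANTILE = 0.25

READS_COLUMNS = ("sample_id", "locus_id", "repeat_count")


def estimate_erc(
    read_counts: Iterable[int],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    quantile: float = DEFAULT_ERC_QUANTILE,
) -> Optional[int]:
    """ERC of one sample at one locus, or ``None`` below the coverage floor.

    The counts are sorted in decreasing order and the value at 1-based
    position ``ceil(quantile * N)`` is returned — always an observed read
    value, never an interpolation.

    Raises :class:`InputError` on negative counts.
    """
    counts = np.asarray(list(read_counts))
    if counts.size and counts.min() < 0:
        raise InputError("read repeat counts must be >= 0")
    n = counts.size
    if n < min_coverage:
        return None
    rank = math.ceil(quantile * n)  # 1-based from the top
    ordered = np.sort(counts)[::-1]
    return int(ordered[rank - 1])


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Check a read-observation table against its schema."""
    missing = [c for c in READS_COLUMNS if c not in obs.columns]
    if missing:
        raise InputError(f"read table is missing columns: {missing}")
    if len(obs) and (obs["repeat_count"] < 0).any():
        raise InputError("read repeat counts must be >= 0")
    return obs


def build_genotype_matrix(
    obs: pd.DataFrame,
    catalog: Sequence[StrLocus],
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    quantile: float = DEFAULT_ERC_QUANTILE,
) -> pd.DataFrame:
    """Merge per-read counts into a loci x samples ERC matrix.

    Rows follow the catalog order, columns are the sorted observed samples.
    Cells are floats with ``NaN`` marking missing genotypes (no reads, or
    coverage below ``min_coverage``). Unknown locus ids raise
    :class:`InputError` listing the offending ids.

    The per-cell values equal ``estimate_erc`` applied independently to that
    sample's reads at that locus; the implementation is vectorised for
    population-scale tables.
    """
    validate_observations(obs)
    locus_ids = [l.locus_id for l in catalog]
    known = set(locus_ids)
    unknown = sorted(set(obs["locus_id"]) - known)
    if unknown:
        raise InputError(f"observations reference unknown locus ids: {unknown}")

    samples = sorted(obs["sample_id"].unique())
    matrix = pd.DataFrame(np.nan, index=pd.Index(locus_ids, name="locus_id"), columns=samples)
    if not len(obs):
        return matrix

    locus_codes = pd.Categorical(obs["locus_id"], categories=locus_ids).codes
    sample_codes = pd.Categorical(obs["sample_id"], categories=samples).codes
    counts = obs["repeat_count"].to_numpy()
    cell = locus_codes.astype(np.int64) * len(samples) + sample_codes

    # Group reads per (locus, sample) cell; within each group sort counts
    # descending and pick the 1-based ceil(q*n) rank.
    order = np.lexsort((-counts, cell))
    cell_sorted = cell[order]
    counts_sorted = counts[order]
    uniq, starts, sizes = np.unique(cell_sorted, return_index=True, return_counts=True)
    ok = sizes >= min_coverage
    ranks = np.ceil(quantile * sizes[ok]).astype(np.int64)
    picked = counts_sorted[starts[ok] + ranks - 1]

    values = matrix.to_numpy()
    flat_rows, flat_cols = np.divmod(uniq[ok], len(samples))
    values[flat_rows, flat_cols] = picked
    return matrix


def concordance(a: pd.DataFrame, b: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation between two genotype matrices.

    Computed over the (locus, sample) cells non-missing in both matrices
    after aligning on shared rows and columns. Returns ``(r, n_pairs)``.
    Raises :class:`UndefinedCorrelationError` with <2 shared cells or a
    zero-variance vector.
    """
    from scipy import stats

    rows = a.index.intersection(b.index)
    cols = a.columns.intersection(b.columns)
    x = a.loc[rows, cols].to_numpy(dtype=float).ravel()
    y = b.loc[rows, cols].to_numpy(dtype=float).ravel()
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise UndefinedCorrelationError(
            f"need >= 2 shared non-missing cells, got {x.size}"
        )
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the matrices")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(x.size)
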