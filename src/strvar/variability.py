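"""Locus variability scoring: the repeat dynamic index (RDI) and friends.

Per locus, the population's estimated repeat counts are trimmed to the
[5th, 95th] percentile range (nearest-rank percentiles — observed integer
values, never interpolated) and the RDI is the population standard
deviation (divisor N) of the retained counts. RDI ranks are normalized to
nRDI in [0, 1] and cut into five equal-width variability tiers.

Percentile convention
---------------------
Percentiles use the ascending 1-based nearest-rank index ``ceil(q * n)``,
with one refinement at the upper bound: when ``q * n`` is not an integer
the upper index is capped at ``n - 1`` so that a lone maximum outlier is
excluded even at small n (trimming exists precisely to drop extreme
values). The source prose for the trimming rule is internally
contradictory ("above the fifth percentile or low 95th percentile"); the
two-sided keep-[p5, p95] reading is implemented. Trimming is value-based
and inclusive, so ties at the bounds are retained.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    EmptySubsetError,
    InputError,
    InsufficientDataError,
    NormalizationError,
)

DEFAULT_TRIM = (0.05, 0.95)
DEFAULT_MIN_FRACTION = 0.8

#: Variability tiers, in ascending nRDI order (equal-width 0.2 bins).
TIERS = ("vlSTR", "lSTR", "mSTR", "hSTR", "vhSTR")

_INT_TOL = 1e-9  # q*n within this of an integer is treated as exact


def nearest_rank_index(q: float, n: int, cap_upper: bool = False) -> int:
    """1-based ascending nearest-rank index for quantile ``q`` of ``n`` values."""
    if not 0 < q < 1:
        raise InputError(f"quantile must be in (0,1), got {q}")
    x = q * n
    if abs(x - round(x)) < _INT_TOL:
        k = int(round(x))
    else:
        k = math.ceil(x)
        if cap_upper:
            k = min(k, n - 1)
    return max(k, 1)


def trim_counts(
    ercs: Sequence[int],
    q_low: float = DEFAULT_TRIM[0],
    q_high: float = DEFAULT_TRIM[1],
) -> tuple[list[int], float, float]:
    """Trim a locus's repeat counts to the [p_low, p_high] percentile range.

    Returns ``(kept, p_low, p_high)`` where ``kept`` preserves the input
    order and contains every value v with ``p_low <= v <= p_high``
    (bounds inclusive). Requires >= 2 values.
    """
    values = list(ercs)
    n = len(values)
    if n < 2:
        raise InsufficientDataError(f"trimming needs >= 2 values, got {n}")
    if not q_low < q_high:
        raise InputError(f"trim bounds must satisfy low < high: {q_low}, {q_high}")
    ordered = sorted(values)
    p_low = ordered[nearest_rank_index(q_low, n) - 1]
    p_high = ordered[nearest_rank_index(q_high, n, cap_upper=True) - 1]
    kept = [v for v in values if p_low <= v <= p_high]
    return kept, p_low, p_high


def compute_rdi(kept: Sequence[int]) -> float:
    """Population standard deviation sqrt(sum((R - mean)^2) / N) of the kept counts."""
    arr = np.asarray(list(kept), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("RDI needs at least one retained count")
    return float(np.sqrt(np.mean((arr - arr.mean()) ** 2)))


def normalize_rdi(rdi_by_locus: Mapping[str, float]) -> dict[str, float]:
    """Rank-normalize RDI scores to nRDI in [0, 1].

    nRDI = (rank - 1) / (L - 1) with ascending midranks (ties share the
    average rank); the minimum maps to 0 and the maximum to 1. Requires at
    least two loci.
    """
    ids = list(rdi_by_locus)
    if len(ids) < 2:
        raise NormalizationError(
            f"rank normalization needs >= 2 loci, got {len(ids)}"
        )
    scores = np.array([rdi_by_locus[i] for i in ids], dtype=float)
    ranks = rankdata(scores, method="average")
    nrdi = (ranks - 1.0) / (len(ids) - 1.0)
    return dict(zip(ids, nrdi.tolist()))


def classify(nrdi: float) -> str:
    """Variability tier for one nRDI value.

    Bins are left-closed: [0,0.2) -> vlSTR, [0.2,0.4) -> lSTR, [0.4,0.6) ->
    mSTR, [0.6,0.8) -> hSTR, [0.8,1.0] -> vhSTR.
    """
    if not 0.0 <= nrdi <= 1.0:
        raise InputError(f"nRDI must be in [0,1], got {nrdi}")
    return TIERS[min(int(nrdi * 5), 4)]


def tier_proportions(nrdis: Iterable[float]) -> np.ndarray:
    """Proportion of values per tier, in :data:`TIERS` order."""
    values = list(nrdis)
    if not values:
        raise EmptySubsetError("no nRDI values to bin")
    counts = np.zeros(5)
    for v in values:
        counts[min(int(v * 5), 4)] += 1
    return counts / counts.sum()


def decile_distribution(
    records: pd.DataFrame, subset: Iterable[str] | None = None
) -> np.ndarray:
    """Proportion of (subset) loci per nRDI decile [0,0.1), ..., [0.9,1.0].

    ``records`` must carry ``locus_id`` and ``nrdi`` columns (unscored loci
    with missing nrdi are ignored); ``subset`` restricts to those locus ids.
    """
    frame = records
    if "locus_id" in frame.columns:
        frame = frame.set_index("locus_id")
    nrdi = frame["nrdi"].dropna()
    if subset is not None:
        subset = set(subset)
        if not subset:
            raise EmptySubsetError("empty locus subset")
        nrdi = nrdi[nrdi.index.isin(subset)]
    if nrdi.empty:
        raise EmptySubsetError("subset contains no scored loci")
    counts = np.zeros(10)
    for v in nrdi.to_numpy():
        counts[min(int(v * 10), 9)] += 1
    return counts / counts.sum()


def normal_range(
    ercs: Sequence[int],
    mode: str = "two_sided",
    q_low: float = DEFAULT_TRIM[0],
    q_high: float = DEFAULT_TRIM[1],
) -> tuple[float, float]:
    """Cohort normal repeat range of a locus.

    ``upper_trim`` -> (min, p95): display range excluding maximum outliers.
    ``two_sided``  -> (p5, p95): the database-record range.
    """
    if mode not in {"upper_trim", "two_sided"}:
        raise InputError(f"unknown normal-range mode {mode!r}")
    values = sorted(ercs)
    n = len(values)
    if n < 2:
        raise InsufficientDataError(f"normal range needs >= 2 values, got {n}")
    high = values[nearest_rank_index(q_high, n, cap_upper=True) - 1]
    if mode == "upper_trim":
        return values[0], high
    return values[nearest_rank_index(q_low, n) - 1], high


def repeat_histogram(ercs: Sequence[int], cap: int = 30) -> pd.Series:
    """Distribution of repeat sizes over bins 1..cap plus a pooled ">cap" bin.

    Values above ``cap`` are combined into the terminal bin (labelled e.g.
    "30+"); values below 1 are counted in bin 1. Proportions sum to 1.
    """
    values = list(ercs)
    if not values:
        raise InsufficientDataError("histogram needs at least one value")
    counts = np.zeros(cap + 1)
    for v in values:
        counts[min(max(int(v), 1), cap + 1) - 1] += 1
    labels = [str(i) for i in range(1, cap + 1)] + [f"{cap}+"]
    return pd.Series(counts / counts.sum(), index=labels, name="proportion")


def score_loci(
    genotypes: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    q_low: float = DEFAULT_TRIM[0],
    q_high: float = DEFAULT_TRIM[1],
) -> pd.DataFrame:
    """Variability records for every locus of a genotype matrix.

    A locus is scored only when its non-missing ERCs cover at least
    ``min_fraction`` of the cohort samples (and at least 2 samples). The
    returned frame (indexed by locus_id) carries n_total, n_used, p5, p95,
    rdi, nrdi and tier; unscored loci have NaN statistics.
    """
    n_samples = genotypes.shape[1]
    rows = []
    rdis: dict[str, float] = {}
    for locus_id, row in genotypes.iterrows():
        values = row.dropna()
        n_total = int(values.size)
        rec = {
            "locus_id": locus_id,
            "n_total": n_total,
            "n_used": np.nan,
            "p5": np.nan,
            "p95": np.nan,
            "rdi": np.nan,
            "nrdi": np.nan,
            "tier": None,
        }
        if n_total >= 2 and n_total >= min_fraction * n_samples:
            kept, p5, p95 = trim_counts(values.to_numpy(), q_low, q_high)
            rdi = compute_rdi(kept)
            rec.update(n_used=len(kept), p5=p5, p95=p95, rdi=rdi)
            rdis[locus_id] = rdi
        rows.append(rec)
    frame = pd.DataFrame(rows).set_index("locus_id")
    if len(rdis) >= 2:
        nrdi = normalize_rdi(rdis)
        frame.loc[list(nrdi), "nrdi"] = list(nrdi.values())
        frame.loc[list(nrdi), "tier"] = [classify(v) for v in nrdi.values()]
    return frame
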