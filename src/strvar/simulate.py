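"""Seeded generators for every input the pipeline consumes.

The cohort generator emulates the read-level output of a long-read repeat
caller: per-locus true repeat-count distributions across samples (single-
or two-mode discretized normals floored at 1), Poisson read depth, and
read-level miscounts that are biased toward undercounting — the failure
mode the top-25% genotype rule is designed to resist. Ground truth is
returned alongside every artifact so recovery can be tested.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import GeneModel, StrLocus, annotate_catalog
from .errors import InputError

DEFAULT_DEPTH_MEAN = 17.5  # mirrors the cohort's mean sequencing depth
DEFAULT_N_SAMPLES = 193  # mirrors the cohort size
DEFAULT_ERROR_RATE = 0.10
DEFAULT_UNDERCOUNT_BIAS = 0.8
DEFAULT_STEP_GEOM_P = 0.5

_MOTIF_BASES = np.array(list("ACGT"))

#: Default placement weights over intended region classes.
REGION_WEIGHTS = {
    "exonic": 0.12,
    "utr": 0.08,
    "intronic_proximal": 0.20,
    "intronic_distal": 0.25,
    "upstream": 0.14,
    "downstream": 0.14,
    "unassigned": 0.07,
}


@dataclass(frozen=True)
class LocusSimModel:
    """True repeat-count distribution of one locus across the population."""

    locus_id: str
    base_repeat: int
    sigma_true: float
    n_modes: int = 1
    mode_offset: int = 0
    mode_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_true < 0:
            raise InputError("sigma_true must be >= 0")
        if self.n_modes not in (1, 2):
            raise InputError("n_modes must be 1 or 2")
        if not 0.0 <= self.mode_weight <= 1.0:
            raise InputError("mode_weight must be in [0,1]")


@dataclass(frozen=True)
class NoiseModel:
    """Read-level observation noise.

    A read's count is perturbed with probability ``error_rate``; the
    perturbation magnitude is 1 + a shifted geometric (mean magnitude
    ``1/step_geom_p``) and its sign is negative with probability
    ``undercount_bias``.
    """

    depth_mean: float = DEFAULT_DEPTH_MEAN
    error_rate: float = DEFAULT_ERROR_RATE
    undercount_bias: float = DEFAULT_UNDERCOUNT_BIAS
    step_geom_p: float = DEFAULT_STEP_GEOM_P

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise InputError("depth_mean must be > 0")
        for name in ("error_rate", "undercount_bias", "step_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0,1]")


# ---------------------------------------------------------------------------
# catalog generation
# ---------------------------------------------------------------------------

# Toy gene template (offsets from the gene origin, half-open):
#   exons   [0,600) [4300,4900) [9400,10000)
#   UTRs    [600,800) [9200,9400)   (disjoint from exons in this toy model)
_TX_LEN = 10_000
_GENE_SPACING = 60_000
_GENE0_ORIGIN = 20_000
_EXONS = ((0, 600), (4_300, 4_900), (9_400, 10_000))
_UTRS = ((600, 800), (9_200, 9_400))


def _make_gene(index: int, chrom: str = "chr1") -> GeneModel:
    origin = _GENE0_ORIGIN + index * _GENE_SPACING
    return GeneModel(
        gene_id=f"G{index + 1:04d}",
        chrom=chrom,
        strand="+" if index % 2 == 0 else "-",
        tx_start=origin,
        tx_end=origin + _TX_LEN,
        exons=tuple((origin + s, origin + e) for s, e in _EXONS),
        utr=tuple((origin + s, origin + e) for s, e in _UTRS),
    )


def _placement_window(gene: GeneModel, region: str, length: int) -> tuple[int, int]:
    """Start-coordinate window that realises ``region`` for this gene."""
    o = gene.tx_start
    if region == "exonic":
        return o + 4_310, o + 4_890 - length
    if region == "utr":
        return o + 610, o + 790 - length
    if region == "intronic_proximal":
        # inside intron 1, <=1 kb from exon 1's end, clear of the UTR
        return o + 850, o + 1_500 - length
    if region == "intronic_distal":
        # middle of intron 2, >1 kb from both exon boundaries
        return o + 5_950, o + 8_350 - length
    # flanks: 500-9000 bp outside the gene body; strand decides which side
    # is upstream.  unassigned sits mid-intergap, >10 kb from every gene.
    left = (o - 9_000, o - 500 - length)
    right = (gene.tx_end + 500, gene.tx_end + 9_000 - length)
    if region == "upstream":
        return left if gene.strand == "+" else right
    if region == "downstream":
        return right if gene.strand == "+" else left
    if region == "unassigned":
        return gene.tx_end + 20_000, gene.tx_end + 30_000 - length
    raise InputError(f"unknown region {region!r}")


def simulate_catalog(
    n_loci: int,
    n_genes: int,
    seed: int,
    region_weights: Optional[dict[str, float]] = None,
) -> tuple[list[StrLocus], list[GeneModel], pd.DataFrame]:
    """Generate an annotated STR catalog over toy gene models.

    Loci get random motifs of length 3-6 and are placed in exons, UTRs,
    introns (proximal/distal), flanks, or intergenic space according to
    ``region_weights``, then annotated with the real gene-assignment and
    region-classification code. Returns ``(catalog, genes, truth)`` where
    ``truth`` records the intended region and gene per locus.
    """
    if n_loci < 1 or n_genes < 1:
        raise InputError("n_loci and n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [_make_gene(i) for i in range(n_genes)]
    weights = region_weights or REGION_WEIGHTS
    regions = list(weights)
    probs = np.array([weights[r] for r in regions], dtype=float)
    probs /= probs.sum()

    loci: list[StrLocus] = []
    truth_rows = []
    for i in range(n_loci):
        region = regions[rng.choice(len(regions), p=probs)]
        gene = genes[int(rng.integers(n_genes))]
        motif_len = int(rng.integers(3, 7))
        motif = "".join(rng.choice(_MOTIF_BASES, size=motif_len))
        copies = int(rng.integers(5, 13))
        length = motif_len * copies
        lo, hi = _placement_window(gene, region, length)
        start = int(rng.integers(lo, hi + 1))
        locus_id = f"L{i + 1:06d}"
        loci.append(
            StrLocus(
                locus_id=locus_id,
                chrom=gene.chrom,
                start=start,
                end=start + length,
                motif=motif,
            )
        )
        truth_rows.append(
            {"locus_id": locus_id, "intended_region": region,
             "intended_gene": None if region == "unassigned" else gene.gene_id}
        )
    annotated = annotate_catalog(loci, genes)
    return annotated, genes, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def simulate_locus_models(
    catalog: Sequence[StrLocus],
    seed: int,
    sigma_range: tuple[float, float] = (0.0, 4.0),
    base_range: tuple[int, int] = (5, 25),
    bimodal_fraction: float = 0.0,
    mode_offset_range: tuple[int, int] = (5, 15),
) -> list[LocusSimModel]:
    """Draw a true-distribution model per catalog locus (seeded)."""
    rng = np.random.default_rng(seed)
    models = []
    for locus in catalog:
        bimodal = rng.random() < bimodal_fraction
        models.append(
            LocusSimModel(
                locus_id=locus.locus_id,
                base_repeat=int(rng.integers(base_range[0], base_range[1] + 1)),
                sigma_true=float(rng.uniform(*sigma_range)),
                n_modes=2 if bimodal else 1,
                mode_offset=int(rng.integers(*mode_offset_range)) if bimodal else 0,
                mode_weight=float(rng.uniform(0.2, 0.5)) if bimodal else 0.0,
            )
        )
    return models


def simulate_cohort(
    catalog: Sequence[StrLocus],
    models: Sequence[LocusSimModel],
    n_samples: int,
    noise: NoiseModel,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate read-level repeat counts for a cohort.

    Per sample and locus the true count is drawn from the locus model
    (discretized normal, second mode shifted by ``mode_offset`` with
    probability ``mode_weight``, floored at 1); read depth is Poisson and
    each read's count passes through the noise model (floored at 0).

    Returns ``(observations, truth_genotypes, sigma_table)``:
    the observation table has columns sample_id/locus_id/repeat_count, the
    truth matrix is loci x samples of true counts, and the sigma table maps
    locus_id to sigma_true.

    Truth and noise use separate child RNG streams of ``seed``, so the same
    seed with two different noise models yields two read sets observed from
    the identical true genotypes (the cross-platform concordance setting).
    """
    by_id = {m.locus_id: m for m in models}
    missing = [l.locus_id for l in catalog if l.locus_id not in by_id]
    if missing:
        raise InputError(f"no simulation model for loci: {missing[:5]}")
    truth_rng, noise_rng = np.random.default_rng(seed).spawn(2)
    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n_samples)])
    locus_ids = [l.locus_id for l in catalog]

    truth = np.empty((len(locus_ids), n_samples), dtype=np.int64)
    for row, locus_id in enumerate(locus_ids):
        m = by_id[locus_id]
        centers = np.full(n_samples, m.base_repeat, dtype=float)
        if m.n_modes == 2:
            in_second = truth_rng.random(n_samples) < m.mode_weight
            centers[in_second] += m.mode_offset
        truth[row] = np.maximum(
            np.rint(truth_rng.normal(centers, m.sigma_true)).astype(np.int64), 1
        )

    obs_locus, obs_sample, obs_count = [], [], []
    for row, locus_id in enumerate(locus_ids):
        true_counts = truth[row]
        rng = noise_rng
        depth = rng.poisson(noise.depth_mean, size=n_samples)
        total = int(depth.sum())
        if total == 0:
            continue
        reads = np.repeat(true_counts, depth)
        errored = rng.random(total) < noise.error_rate
        n_err = int(errored.sum())
        if n_err:
            magnitude = rng.geometric(noise.step_geom_p, size=n_err)
            sign = np.where(rng.random(n_err) < noise.undercount_bias, -1, 1)
            reads[errored] = np.maximum(reads[errored] + sign * magnitude, 0)
        obs_locus.append(np.repeat(row, total))
        obs_sample.append(np.repeat(np.arange(n_samples), depth))
        obs_count.append(reads)

    locus_arr = np.concatenate(obs_locus) if obs_locus else np.array([], dtype=int)
    sample_arr = np.concatenate(obs_sample) if obs_sample else np.array([], dtype=int)
    count_arr = np.concatenate(obs_count) if obs_count else np.array([], dtype=int)
    observations = pd.DataFrame(
        {
            "sample_id": sample_ids[sample_arr],
            "locus_id": np.array(locus_ids, dtype=object)[locus_arr],
            "repeat_count": count_arr,
        }
    )
    truth_frame = pd.DataFrame(
        truth, index=pd.Index(locus_ids, name="locus_id"), columns=list(sample_ids)
    )
    sigma_frame = pd.DataFrame(
        {"locus_id": locus_ids, "sigma_true": [by_id[i].sigma_true for i in locus_ids]}
    ).set_index("locus_id")
    return observations, truth_frame, sigma_frame


# ---------------------------------------------------------------------------
# expression / annotation generation
# ---------------------------------------------------------------------------


def simulate_expression(
    genes: Sequence[str],
    tissues: Sequence[str],
    boosted_set: Iterable[str],
    boosted_tissue: Optional[str],
    effect_sd_units: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Log-normal genes x tissues expression with one optionally boosted tissue.

    Members of ``boosted_set`` have their expression in ``boosted_tissue``
    shifted upward by ``effect_sd_units`` within-tissue standard
    deviations. Returns the matrix and a truth bundle.
    """
    boosted = sorted(set(boosted_set))
    unknown = set(boosted) - set(genes)
    if unknown:
        raise InputError(f"boosted genes not in gene list: {sorted(unknown)[:5]}")
    if boosted_tissue is not None and boosted_tissue not in set(tissues):
        raise InputError(f"unknown boosted tissue {boosted_tissue!r}")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(len(genes), len(tissues)))
    frame = pd.DataFrame(
        values, index=pd.Index(list(genes), name="gene_id"), columns=list(tissues)
    )
    if boosted_tissue is not None and effect_sd_units != 0 and boosted:
        sd = float(frame[boosted_tissue].std(ddof=0))
        frame.loc[boosted, boosted_tissue] += effect_sd_units * sd
    truth = {
        "boosted_set": boosted,
        "boosted_tissue": boosted_tissue,
        "effect_sd_units": effect_sd_units,
    }
    return frame, truth


def simulate_terms(
    genes: Sequence[str],
    n_terms: int,
    seed: int,
    size_range: tuple[int, int] = (5, 40),
    enriched_for: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Random term -> gene annotations in long format.

    When ``enriched_for`` is given, an extra term ``T_ENRICHED`` is built
    mostly from that gene set so over-representation is recoverable.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    rows = []
    for t in range(n_terms):
        size = int(rng.integers(size_range[0], min(size_range[1], len(genes)) + 1))
        members = rng.choice(genes, size=size, replace=False)
        rows.extend({"term": f"T{t + 1:03d}", "gene_id": g} for g in sorted(members))
    if enriched_for is not None:
        target = sorted(set(enriched_for) & set(genes))
        take = max(1, int(0.8 * len(target)))
        members = list(rng.choice(target, size=take, replace=False)) if target else []
        padding = rng.choice(
            sorted(set(genes) - set(members)), size=max(0, 5 - len(members)), replace=False
        )
        rows.extend(
            {"term": "T_ENRICHED", "gene_id": g} for g in sorted([*members, *padding])
        )
    return pd.DataFrame(rows, columns=["term", "gene_id"])
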