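"""STR catalog model: loci, repeat-unit canonicalization, region classification.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import InputError

MOTIF_ALPHABET = frozenset("ACGT")
MIN_MOTIF_LEN = 3
MAX_MOTIF_LEN = 6

#: Region classes in classification priority order (unassigned last).
REGION_CLASSES = (
    "exonic",
    "utr",
    "intronic_proximal",
    "intronic_distal",
    "upstream",
    "downstream",
    "unassigned",
)

#: Maximum gap (bp) between a locus and a gene body for gene assignment.
GENE_WINDOW = 10_000

#: Intronic loci within this distance of an exon boundary are "proximal".
PROXIMAL_DISTANCE = 1_000

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def validate_motif(sequence: str) -> str:
    """Validate a repeat-unit string (uppercase ACGT, length 3-6).

    Returns the sequence unchanged; raises :class:`InputError` otherwise.
    """
    if not isinstance(sequence, str):
        raise InputError(f"motif must be a string, got {type(sequence).__name__}")
    if not MIN_MOTIF_LEN <= len(sequence) <= MAX_MOTIF_LEN:
        raise InputError(
            f"motif length must be in [{MIN_MOTIF_LEN},{MAX_MOTIF_LEN}], "
            f"got {len(sequence)} ({sequence!r})"
        )
    bad = set(sequence) - MOTIF_ALPHABET
    if bad:
        raise InputError(f"motif {sequence!r} contains invalid characters {sorted(bad)}")
    return sequence


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _rotations(sequence: str) -> Iterable[str]:
    doubled = sequence + sequence
    n = len(sequence)
    for i in range(n):
        yield doubled[i : i + n]


def canonical_unit(motif: str) -> str:
    """Class representative of a repeat unit.

    The representative is the lexicographically smallest string among all
    cyclic rotations of the motif and all cyclic rotations of its reverse
    complement, so every member of one strand/phase equivalence class maps
    to the same unit. Idempotent.

    Examples
    --------
    >>> canonical_unit("CAG")
    'AGC'
    >>> canonical_unit("CTG")
    'AGC'
    """
    validate_motif(motif)
    candidates = list(_rotations(motif))
    candidates.extend(_rotations(reverse_complement(motif)))
    return min(candidates)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene body used for region classification.

    Exon and UTR intervals are half-open; exons must be sorted and
    non-overlapping; UTR intervals must lie within the gene body.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise InputError(f"gene {self.gene_id}: tx_start must be < tx_end")
        prev_end = None
        for s, e in self.exons:
            if not s < e:
                raise InputError(f"gene {self.gene_id}: empty exon interval ({s},{e})")
            if prev_end is not None and s < prev_end:
                raise InputError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        for s, e in self.utr:
            if s < self.tx_start or e > self.tx_end:
                raise InputError(
                    f"gene {self.gene_id}: UTR ({s},{e}) outside gene body"
                )


@dataclass
class StrLocus:
    """One STR catalog entry with optional gene/region annotation."""

    locus_id: str
    chrom: str
    start: int
    end: int
    motif: str
    canonical: str = ""
    region_class: str = "unassigned"
    gene_id: Optional[str] = None
    gene_distance: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise InputError(f"locus {self.locus_id}: start must be < end")
        validate_motif(self.motif)
        if not self.canonical:
            self.canonical = canonical_unit(self.motif)
        if self.region_class not in REGION_CLASSES:
            raise InputError(
                f"locus {self.locus_id}: unknown region class {self.region_class!r}"
            )
        if self.gene_id is None:
            if self.region_class != "unassigned":
                raise InputError(
                    f"locus {self.locus_id}: region class without assigned gene"
                )
            if self.gene_distance is not None:
                raise InputError(f"locus {self.locus_id}: distance without gene")
        else:
            if self.gene_distance is None or self.gene_distance < 0:
                raise InputError(
                    f"locus {self.locus_id}: gene present requires distance >= 0"
                )
            if self.gene_distance > GENE_WINDOW:
                raise InputError(
                    f"locus {self.locus_id}: gene distance exceeds {GENE_WINDOW} bp"
                )

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between half-open intervals; 0 if they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def _overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_gene(
    locus: StrLocus,
    genes: Sequence[GeneModel],
    max_distance: int = GENE_WINDOW,
) -> tuple[Optional[str], Optional[int]]:
    """Nearest gene within ``max_distance`` bp of the locus.

    A gene whose body overlaps the locus wins with distance 0; otherwise the
    gene with the smallest gap is chosen (ties broken by lexicographic
    gene_id for determinism). Returns ``(None, None)`` when no gene lies
    within the window.
    """
    best: Optional[tuple[int, str]] = None
    for gene in genes:
        if gene.chrom != locus.chrom:
            continue
        gap = _gap(locus.start, locus.end, gene.tx_start, gene.tx_end)
        if _overlap_len(locus.start, locus.end, gene.tx_start, gene.tx_end) > 0:
            gap = 0
        if gap > max_distance:
            continue
        key = (gap, gene.gene_id)
        if best is None or key < best:
            best = key
    if best is None:
        return None, None
    return best[1], best[0]


def classify_region(locus: StrLocus, gene: GeneModel) -> str:
    """Region class of a locus relative to its assigned gene.

    Priority: exonic > utr > intronic (proximal when the distance from the
    locus to the nearest exon boundary is <= 1 kb, else distal) > upstream/
    downstream (outside the gene body, 5'/3' side, strand-aware).
    """
    if gene.chrom != locus.chrom:
        raise InputError(
            f"locus {locus.locus_id} and gene {gene.gene_id} are on "
            f"different chromosomes"
        )
    for s, e in gene.exons:
        if _overlap_len(locus.start, locus.end, s, e) > 0:
            return "exonic"
    for s, e in gene.utr:
        if _overlap_len(locus.start, locus.end, s, e) > 0:
            return "utr"
    if _overlap_len(locus.start, locus.end, gene.tx_start, gene.tx_end) > 0:
        boundaries = gene.exons if gene.exons else ((gene.tx_start, gene.tx_end),)
        dist = min(_gap(locus.start, locus.end, s, e) for s, e in boundaries)
        return "intronic_proximal" if dist <= PROXIMAL_DISTANCE else "intronic_distal"
    five_prime_side = locus.end <= gene.tx_start  # left of gene body
    if gene.strand == "-":
        five_prime_side = not five_prime_side
    return "upstream" if five_prime_side else "downstream"


def annotate_catalog(
    loci: Sequence[StrLocus],
    genes: Sequence[GeneModel],
    max_distance: int = GENE_WINDOW,
) -> list[StrLocus]:
    """Assign genes and region classes to every locus (returns new objects)."""
    by_id = {g.gene_id: g for g in genes}
    out = []
    for locus in loci:
        gene_id, dist = assign_gene(locus, genes, max_distance=max_distance)
        region = "unassigned" if gene_id is None else classify_region(locus, by_id[gene_id])
        out.append(
            StrLocus(
                locus_id=locus.locus_id,
                chrom=locus.chrom,
                start=locus.start,
                end=locus.end,
                motif=locus.motif,
                canonical=locus.canonical,
                region_class=region,
                gene_id=gene_id,
                gene_distance=dist,
            )
        )
    return out


@dataclass(frozen=True)
class LocusPair:
    """A matched pair from two catalogs with their interval overlap in bp."""

    a_id: str
    b_id: str
    overlap: int


def overlap_catalog(
    a: Sequence[StrLocus], b: Sequence[StrLocus]
) -> list[LocusPair]:
    """Pair loci from two catalogs that intersect and share a canonical unit.

    Greedy matching by largest interval overlap (ties: smallest start
    coordinates, then ids); each locus appears in at most one pair. The pair
    content is symmetric in the argument order.
    """
    candidates = []
    b_by_chrom: dict[str, list[StrLocus]] = {}
    for lb in b:
        b_by_chrom.setdefault(lb.chrom, []).append(lb)
    for la in a:
        for lb in b_by_chrom.get(la.chrom, ()):
            if la.canonical != lb.canonical:
                continue
            ov = _overlap_len(la.start, la.end, lb.start, lb.end)
            if ov > 0:
                candidates.append((la, lb, ov))
    candidates.sort(
        key=lambda t: (
            -t[2],
            min(t[0].start, t[1].start),
            max(t[0].start, t[1].start),
            t[0].locus_id,
            t[1].locus_id,
        )
    )
    used_a: set[str] = set()
    used_b: set[str] = set()
    pairs = []
    for la, lb, ov in candidates:
        if la.locus_id in used_a or lb.locus_id in used_b:
            continue
        used_a.add(la.locus_id)
        used_b.add(lb.locus_id)
        pairs.append(LocusPair(a_id=la.locus_id, b_id=lb.locus_id, overlap=ov))
    return pairs
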