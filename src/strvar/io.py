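"""Readers and writers for the pipeline's TSV interchange formats.

Conventions: tab-separated text, ``NA`` encodes missing values (distinct
from 0), coordinates are 0-based half-open, gzip is transparent by file
extension, and written column order is deterministic. Catalog files are
BED6-extended with a ``#``-prefixed header line.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .catalog import GeneModel, StrLocus, canonical_unit
from .errors import SchemaError

PathLike = Union[str, Path]

NA = "NA"

CATALOG_COLUMNS = (
    "chrom", "start", "end", "locus_id", "motif", "canonical_unit",
    "region_class", "gene_id", "gene_distance",
)
GENE_COLUMNS = ("gene_id", "chrom", "strand", "tx_start", "tx_end", "exons", "utrs")


def _open_text(path: PathLike, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def _require_columns(frame: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    extra = [c for c in frame.columns if c not in required]
    if missing:
        raise SchemaError(
            f"{what}: missing columns {missing}"
            + (f" (unexpected columns present: {extra})" if extra else "")
        )


# -- catalog ----------------------------------------------------------------


def write_catalog(loci: Sequence[StrLocus], path: PathLike) -> None:
    with _open_text(path, "w") as fh:
        fh.write("#" + "\t".join(CATALOG_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                "\t".join(
                    [
                        l.chrom, str(l.start), str(l.end), l.locus_id, l.motif,
                        l.canonical, l.region_class,
                        l.gene_id if l.gene_id is not None else NA,
                        str(l.gene_distance) if l.gene_distance is not None else NA,
                    ]
                )
                + "\n"
            )


def read_catalog(path: PathLike) -> list[StrLocus]:
    """Read a BED6-extended catalog; a blank canonical_unit is computed."""
    loci = []
    with _open_text(path, "r") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: catalog must start with a '#' header line")
        cols = header.lstrip("#").rstrip("\n").split("\t")
        for required in CATALOG_COLUMNS[:5]:
            if required not in cols:
                raise SchemaError(f"{path}: catalog header missing {required!r}")
        idx = {c: i for i, c in enumerate(cols)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise SchemaError(
                    f"{path}: line {lineno}: expected {len(cols)} fields, "
                    f"got {len(fields)}"
                )

            def get(col: str, default: str = NA) -> str:
                return fields[idx[col]] if col in idx else default

            try:
                start, end = int(get("start")), int(get("end"))
            except ValueError:
                raise SchemaError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            canonical = get("canonical_unit", "")
            gene_id = get("gene_id")
            distance = get("gene_distance")
            loci.append(
                StrLocus(
                    locus_id=get("locus_id"),
                    chrom=get("chrom"),
                    start=start,
                    end=end,
                    motif=get("motif"),
                    canonical="" if canonical == NA else canonical,
                    region_class=(
                        get("region_class") if get("region_class") != NA else "unassigned"
                    ),
                    gene_id=None if gene_id == NA else gene_id,
                    gene_distance=None if distance == NA else int(distance),
                )
            )
    return loci


# -- gene models ------------------------------------------------------------


def _format_intervals(intervals) -> str:
    return ",".join(f"{s}-{e}" for s, e in intervals) if intervals else NA


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    if text in (NA, ""):
        return ()
    out = []
    for token in text.split(","):
        s, e = token.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_gene_models(genes: Sequence[GeneModel], path: PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
            "tx_start": g.tx_start, "tx_end": g.tx_end,
            "exons": _format_intervals(g.exons), "utrs": _format_intervals(g.utr),
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path: PathLike) -> list[GeneModel]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(frame, GENE_COLUMNS, f"{path} (gene models)")
    return [
        GeneModel(
            gene_id=row.gene_id, chrom=row.chrom, strand=row.strand,
            tx_start=int(row.tx_start), tx_end=int(row.tx_end),
            exons=_parse_intervals(row.exons), utr=_parse_intervals(row.utrs),
        )
        for row in frame.itertuples()
    ]


# -- read observations ------------------------------------------------------


def write_reads(obs: pd.DataFrame, path: PathLike) -> None:
    obs.to_csv(path, sep="\t", index=False, columns=["sample_id", "locus_id", "repeat_count"])


def read_reads(path: PathLike) -> pd.DataFrame:
    """Read a per-read repeat-count table, validating counts line by line."""
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    _require_columns(frame, ["sample_id", "locus_id", "repeat_count"], f"{path} (reads)")
    raw = frame["repeat_count"]
    numeric = pd.to_numeric(raw, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.any():
        # +2: 1-based lines plus the header
        lineno = int(bad.idxmax()) + 2
        raise SchemaError(
            f"{path}: line {lineno}: repeat_count must be a non-negative "
            f"integer, got {raw[bad.idxmax()]!r}"
        )
    frame["repeat_count"] = numeric.astype(np.int64)
    return frame


# -- matrices and tables ----------------------------------------------------


def write_matrix(matrix: pd.DataFrame, path: PathLike, index_name: str = "locus_id") -> None:
    out = matrix.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=NA, float_format="%.10g")


def read_matrix(path: PathLike, index_name: str = "locus_id") -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    if frame.columns[0] != index_name:
        raise SchemaError(f"{path}: first column must be {index_name!r}")
    return frame.set_index(index_name).astype(float)


def write_variability(records: pd.DataFrame, path: PathLike) -> None:
    out = records.reset_index()
    cols = ["locus_id", "n_total", "n_used", "p5", "p95", "rdi", "nrdi", "tier"]
    out.to_csv(path, sep="\t", index=False, columns=cols, na_rep=NA, float_format="%.10g")


def read_variability(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)
    _require_columns(
        frame,
        ["locus_id", "n_total", "n_used", "p5", "p95", "rdi", "nrdi", "tier"],
        f"{path} (variability)",
    )
    return frame.set_index("locus_id")


def write_expression(matrix: pd.DataFrame, path: PathLike) -> None:
    write_matrix(matrix, path, index_name="gene_id")


def read_expression(path: PathLike) -> pd.DataFrame:
    return read_matrix(path, index_name="gene_id")


def read_terms(path: PathLike) -> dict[str, set[str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(frame, ["term", "gene_id"], f"{path} (terms)")
    terms: dict[str, set[str]] = {}
    for row in frame.itertuples():
        terms.setdefault(row.term, set()).add(row.gene_id)
    return terms


def write_terms(terms: pd.DataFrame, path: PathLike) -> None:
    terms.to_csv(path, sep="\t", index=False, columns=["term", "gene_id"])


def read_gene_list(path: PathLike) -> list[str]:
    with _open_text(path, "r") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: PathLike) -> None:
    with _open_text(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_subset_table(path: PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if "locus_id" not in frame.columns and not {"chrom", "start", "end"} <= set(
        frame.columns
    ):
        raise SchemaError(
            f"{path}: subset table needs locus_id or chrom/start/end columns"
        )
    return frame
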