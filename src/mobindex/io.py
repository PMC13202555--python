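"""Parsing, filtering and joining of contig-level annotation tables.

The pipeline consumes tabular outputs of an upstream annotation workflow
(assembly, ORF prediction and protein alignment are all upstream): alignment
hit tables in blast outfmt-6 dialect or the package's native TSV dialect, a
contig table, and a sample-metadata table.  Everything downstream — the
carrying-rate / co-occurrence / mobility-potential indices, diversity layers
and regressions — reads the joined :class:`SampleAnnotationSet` built here.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GENE_CLASSES = ("MRG", "ARG", "VFG")
MGE_CLASS = "MGE"
MGE_CATEGORIES = ("plasmid_gene", "IS", "transposon", "integron", "ICE")
MOBILITY_CONTEXTS = ("chromosome-like", "plasmid", "phage", "unknown")

#: Default alignment-quality filter: hits with E-value above 1e-5 or percent
#: identity below 80 are discarded (both comparisons inclusive).
DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 80.0

BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore"
).split()

HIT_COLUMNS = [
    "sample_id",
    "contig_id",
    "gene_class",
    "subclass",
    "gene_name",
    "pident",
    "evalue",
    "bitscore",
]

CONTIG_COLUMNS = ["sample_id", "contig_id", "length_bp", "mobility_context"]


class AnnotationError(ValueError):
    """Raised for malformed annotation inputs (carries a line number)."""


def _parse_float(text: str, *, line_no: int, column: str, path) -> float:
    try:
        return float(text)
    except ValueError:
        raise AnnotationError(
            f"{path}: line {line_no}: non-numeric value {text!r} in column "
            f"{column!r}"
        ) from None


def parse_hit_table(
    path,
    gene_class: str,
    dialect: str = "blast6",
    *,
    sample_id: str | None = None,
    subclass: str = "",
) -> pd.DataFrame:
    """Parse one alignment-hit table into a hits DataFrame, unfiltered.

    Parameters
    ----------
    path
        Input file.  ``dialect="blast6"`` expects the 12 standard tabular
        columns (qseqid sseqid pident length mismatch gapopen qstart qend
        sstart send evalue bitscore); qseqid is taken as the contig id and
        sseqid as the gene name.  ``dialect="native"`` expects the package's
        headered TSV (sample_id, contig_id, gene_class, subclass, gene_name,
        pident, evalue, bitscore).
    gene_class
        Class label to assign to every hit ("MRG", "ARG", "VFG" or "MGE").
        For the native dialect it must agree with the file's own column.
    sample_id
        Required for blast6 input (blast tables carry no sample column).
    subclass
        Subclass assigned to blast6 hits (e.g. an MGE category).

    Returns one row per input row, in file order, with numeric fields
    validated; malformed rows raise :class:`AnnotationError` naming the line.
    """
    if gene_class not in GENE_CLASSES + (MGE_CLASS,):
        raise ValueError(f"unknown gene_class {gene_class!r}")
    if gene_class == MGE_CLASS and subclass and subclass not in MGE_CATEGORIES:
        raise ValueError(f"unknown MGE category {subclass!r}")
    path = Path(path)
    if dialect == "blast6":
        if sample_id is None:
            raise ValueError("sample_id is required for blast6 input")
        return _parse_blast6(path, gene_class, sample_id, subclass)
    if dialect == "native":
        return _parse_native_hits(path, gene_class)
    raise ValueError(f"unknown dialect {dialect!r}")


def _parse_blast6(path: Path, gene_class, sample_id, subclass) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST6_COLUMNS):
                raise AnnotationError(
                    f"{path}: line {line_no}: expected "
                    f"{len(BLAST6_COLUMNS)} tab-separated columns, got "
                    f"{len(fields)}"
                )
            pident = _parse_float(fields[2], line_no=line_no, column="pident", path=path)
            evalue = _parse_float(fields[10], line_no=line_no, column="evalue", path=path)
            bitscore = _parse_float(fields[11], line_no=line_no, column="bitscore", path=path)
            if evalue < 0 or bitscore < 0 or not (0 <= pident <= 100):
                raise AnnotationError(
                    f"{path}: line {line_no}: out-of-range numeric field "
                    f"(pident={pident}, evalue={evalue}, bitscore={bitscore})"
                )
            rows.append(
                (sample_id, fields[0], gene_class, subclass, fields[1], pident, evalue, bitscore)
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _parse_native_hits(path: Path, gene_class: str) -> pd.DataFrame:
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        header = header_line.split("\t")
        if header != HIT_COLUMNS:
            raise AnnotationError(
                f"{path}: line 1: native hits TSV must have header "
                f"{HIT_COLUMNS}, got {header}"
            )
        rows = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(HIT_COLUMNS):
                raise AnnotationError(
                    f"{path}: line {line_no}: expected {len(HIT_COLUMNS)} "
                    f"columns, got {len(fields)}"
                )
            if fields[2] != gene_class:
                raise AnnotationError(
                    f"{path}: line {line_no}: gene_class column "
                    f"{fields[2]!r} does not match requested {gene_class!r}"
                )
            pident = _parse_float(fields[5], line_no=line_no, column="pident", path=path)
            evalue = _parse_float(fields[6], line_no=line_no, column="evalue", path=path)
            bitscore = _parse_float(fields[7], line_no=line_no, column="bitscore", path=path)
            rows.append(
                (fields[0], fields[1], fields[2], fields[3], fields[4], pident, evalue, bitscore)
            )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def filter_hits(
    hits: pd.DataFrame,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> pd.DataFrame:
    """Keep hits with ``evalue <= max_evalue`` and ``pident >= min_identity``.

    Both thresholds are inclusive.  Idempotent; preserves row order.
    """
    if not np.isfinite(max_evalue) or not np.isfinite(min_identity):
        raise ValueError("filter thresholds must be finite")
    if not 0 <= min_identity <= 100:
        raise ValueError("min_identity must be in [0, 100]")
    mask = (hits["evalue"] <= max_evalue) & (hits["pident"] >= min_identity)
    return hits.loc[mask].reset_index(drop=True)


def resolve_best_hit(hits: pd.DataFrame, *, dedup: bool = True) -> pd.DataFrame:
    """Collapse each (sample, contig, gene_class, gene_name) group to one hit.

    The retained hit is the one with the highest bit score; ties are broken by
    the lowest E-value, then lexicographically smallest subclass, so the
    result is deterministic regardless of input order.  Running the operation
    on its own output is the identity.  ``dedup=False`` returns the input
    unchanged (sorted), for workflows whose upstream already deduplicates.
    """
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        by=["sample_id", "contig_id", "gene_class", "gene_name", "bitscore", "evalue", "subclass"],
        ascending=[True, True, True, True, False, True, True],
        kind="mergesort",
    )
    if not dedup:
        return ordered.reset_index(drop=True)
    best = ordered.drop_duplicates(
        subset=["sample_id", "contig_id", "gene_class", "gene_name"], keep="first"
    )
    return best.reset_index(drop=True)


@dataclass
class SampleAnnotationSet:
    """Joined per-sample annotation: contigs, deduplicated hits, metadata.

    Every hit's contig resolves to a row of ``contigs``; the constructor via
    :func:`build_sample_set` enforces this.  ``metadata`` maps covariate
    names (metal concentrations, physicochemical properties, group label) to
    values.
    """

    sample_id: str
    contigs: pd.DataFrame
    hits: pd.DataFrame
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    def n_genes(self, gene_class: str) -> int:
        """Number of deduplicated gene records of a class in this sample."""
        return int((self.hits["gene_class"] == gene_class).sum())

    def contigs_carrying(self, gene_class: str) -> set:
        """Contig ids carrying at least one gene of the class."""
        sub = self.hits.loc[self.hits["gene_class"] == gene_class, "contig_id"]
        return set(sub)


def build_sample_set(
    contig_table: pd.DataFrame,
    hit_collections: Iterable[pd.DataFrame] | pd.DataFrame,
    metadata_row: Mapping[str, object] | pd.Series | None = None,
    *,
    sample_id: str | None = None,
    dedup: bool = True,
) -> SampleAnnotationSet:
    """Join contigs, hits and metadata for one sample.

    Hits are concatenated across the given collections, restricted to the
    sample, deduplicated with :func:`resolve_best_hit`, and checked against
    the contig table: a hit whose contig is absent raises an error listing
    the offending ids.
    """
    if isinstance(hit_collections, pd.DataFrame):
        hit_collections = [hit_collections]
    hits = (
        pd.concat(list(hit_collections), ignore_index=True)
        if hit_collections
        else pd.DataFrame(columns=HIT_COLUMNS)
    )
    if sample_id is None:
        candidates = set(contig_table["sample_id"].unique())
        if len(candidates) != 1:
            raise ValueError(
                "sample_id not given and contig table does not identify a "
                f"single sample: {sorted(candidates)}"
            )
        sample_id = next(iter(candidates))
    contigs = contig_table.loc[contig_table["sample_id"] == sample_id].reset_index(drop=True)
    hits = hits.loc[hits["sample_id"] == sample_id].reset_index(drop=True)
    _validate_contigs(contigs, sample_id)
    hits = resolve_best_hit(hits, dedup=dedup)
    orphans = sorted(set(hits["contig_id"]) - set(contigs["contig_id"]))
    if orphans:
        raise ValueError(
            f"sample {sample_id!r}: {len(orphans)} hit(s) reference contigs "
            f"absent from the contig table: {orphans[:10]}"
        )
    metadata = dict(metadata_row) if metadata_row is not None else {}
    return SampleAnnotationSet(sample_id=sample_id, contigs=contigs, hits=hits, metadata=metadata)


def _validate_contigs(contigs: pd.DataFrame, sample_id: str) -> None:
    if contigs["contig_id"].duplicated().any():
        dupes = contigs.loc[contigs["contig_id"].duplicated(), "contig_id"]
        raise ValueError(f"sample {sample_id!r}: duplicate contig ids {sorted(set(dupes))[:10]}")
    if (contigs["length_bp"] < 1).any():
        raise ValueError(f"sample {sample_id!r}: contig lengths must be >= 1")
    bad = set(contigs["mobility_context"]) - set(MOBILITY_CONTEXTS)
    if bad:
        raise ValueError(f"sample {sample_id!r}: unknown mobility_context values {sorted(bad)}")


def build_dataset(
    contig_table: pd.DataFrame,
    hit_collections: Iterable[pd.DataFrame] | pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    *,
    dedup: bool = True,
) -> list[SampleAnnotationSet]:
    """Build one :class:`SampleAnnotationSet` per sample in the contig table."""
    if isinstance(hit_collections, pd.DataFrame):
        hit_collections = [hit_collections]
    hit_collections = list(hit_collections)
    sets = []
    for sid in sorted(contig_table["sample_id"].unique()):
        row = None
        if metadata is not None:
            match = metadata.loc[metadata["sample_id"] == sid]
            if match.empty:
                raise ValueError(f"metadata table has no row for sample {sid!r}")
            row = match.iloc[0].to_dict()
        sets.append(
            build_sample_set(contig_table, hit_collections, row, sample_id=sid, dedup=dedup)
        )
    return sets


# ---------------------------------------------------------------------------
# Native TSV round trip

def read_contig_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "contig_id": str})
    missing = set(CONTIG_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: contig table missing columns {sorted(missing)}")
    return df[CONTIG_COLUMNS]


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise AnnotationError(f"{path}: metadata table missing 'sample_id' column")
    return df


def write_contig_table(contigs: pd.DataFrame, path) -> None:
    contigs[CONTIG_COLUMNS].to_csv(path, sep="\t", index=False)


def write_hit_table(hits: pd.DataFrame, path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def sample_set_to_tsv(sset: SampleAnnotationSet) -> tuple[str, str]:
    """Serialize one sample's contigs and hits to native TSV strings."""
    cbuf, hbuf = _io.StringIO(), _io.StringIO()
    write_contig_table(sset.contigs, cbuf)
    write_hit_table(sset.hits, hbuf)
    return cbuf.getvalue(), hbuf.getvalue()
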