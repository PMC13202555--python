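"""Contig-level co-localization indices: CR, CoR and MP.

Three dimensionless ratios summarize, per sample, how metal-resistance
(MRG), antibiotic-resistance (ARG) and virulence (VFG) genes are carried on
assembled contigs and how closely they associate with mobile genetic
elements (MGEs):

* carrying rate ``CR = N_contigs(class) / N_contigs`` — the fraction of
  contigs bearing at least one gene of a class;
* co-occurrence rate ``CoR = N_contigs(co-occurrence) / N_contigs`` — the
  fraction of contigs bearing genes of two or more classes simultaneously;
* mobility potential ``MP = N(class genes co-located with MGEs) / N(class
  genes)`` — the fraction of a class's genes sharing a contig with an MGE,
  a proxy for horizontal-transfer likelihood (not a transfer frequency).

With 100,000 contigs, one additional carrier contig moves CR by exactly
1e-5; numerators and denominators are kept as exact rationals until the
final float conversion so this calibration holds to the bit.

Mobility categories: ``IS``, ``transposon``, ``integron``, ``ICE`` and
``plasmid_gene`` are detected from MGE hits on the contig; ``plasmid`` and
``phage`` use the contig's upstream mobility-context label; ``overall``
is the union of all routes.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import GENE_CLASSES, MGE_CATEGORIES, MGE_CLASS, SampleAnnotationSet

#: Sentinel for the generic "two or more distinct classes" numerator.
ANY_PAIR = "any-pair"

#: Mobility categories detected from MGE hits on the same contig.
HIT_CATEGORIES = MGE_CATEGORIES
#: Mobility categories taken from the contig's mobility_context label.
CONTEXT_CATEGORIES = ("plasmid", "phage")
OVERALL = "overall"
MP_CATEGORIES = (OVERALL,) + HIT_CATEGORIES + CONTEXT_CATEGORIES


def carrying_rate(
    sset: SampleAnnotationSet, gene_class: str, *, as_fraction: bool = False
) -> float | Fraction:
    """Fraction of contigs carrying at least one gene of ``gene_class``."""
    _check_class(gene_class)
    if sset.n_contigs == 0:
        raise ValueError(f"sample {sset.sample_id!r}: carrying rate undefined with 0 contigs")
    carriers = sset.contigs_carrying(gene_class)
    value = Fraction(len(carriers), sset.n_contigs)
    return value if as_fraction else float(value)


def cooccurrence_rate(
    sset: SampleAnnotationSet,
    type_subset: Iterable[str] | str = ANY_PAIR,
    *,
    as_fraction: bool = False,
) -> float | Fraction:
    """Fraction of contigs carrying genes of several classes simultaneously.

    ``type_subset`` is either a collection of >= 2 classes drawn from
    MRG/ARG/VFG (the contig must carry every listed class) or the sentinel
    ``"any-pair"`` (the contig must carry >= 2 distinct classes).
    """
    if sset.n_contigs == 0:
        raise ValueError(f"sample {sset.sample_id!r}: co-occurrence rate undefined with 0 contigs")
    per_class = {c: sset.contigs_carrying(c) for c in GENE_CLASSES}
    if isinstance(type_subset, str):
        if type_subset != ANY_PAIR:
            raise ValueError(f"type_subset must be a collection of classes or {ANY_PAIR!r}")
        counts: dict[str, int] = {}
        for members in per_class.values():
            for cid in members:
                counts[cid] = counts.get(cid, 0) + 1
        numerator = sum(1 for v in counts.values() if v >= 2)
    else:
        subset = list(type_subset)
        if len(subset) < 2 or len(set(subset)) != len(subset):
            raise ValueError("type_subset needs >= 2 distinct gene classes")
        for c in subset:
            _check_class(c)
        common = set.intersection(*(per_class[c] for c in subset))
        numerator = len(common)
    value = Fraction(numerator, sset.n_contigs)
    return value if as_fraction else float(value)


def mobile_contigs(sset: SampleAnnotationSet, category: str = OVERALL) -> set:
    """Contig ids counted as mobile for the given category.

    Hit-based categories require an MGE hit of that subclass on the contig;
    plasmid/phage use the mobility-context label; ``overall`` is the union.
    """
    if category in HIT_CATEGORIES:
        mge = sset.hits
        mask = (mge["gene_class"] == MGE_CLASS) & (mge["subclass"] == category)
        return set(mge.loc[mask, "contig_id"])
    if category in CONTEXT_CATEGORIES:
        ctx = sset.contigs
        return set(ctx.loc[ctx["mobility_context"] == category, "contig_id"])
    if category == OVERALL:
        out: set = set()
        for cat in HIT_CATEGORIES + CONTEXT_CATEGORIES:
            out |= mobile_contigs(sset, cat)
        return out
    raise ValueError(f"unknown mobility category {category!r}")


def mobility_potential(
    sset: SampleAnnotationSet,
    gene_class: str,
    mge_category: str = OVERALL,
    *,
    as_fraction: bool = False,
) -> float | Fraction | None:
    """Fraction of a class's genes co-located with an MGE of the category.

    A gene counts once, however many MGE partners share its contig
    (set semantics).  Returns ``None`` — reported downstream as missing,
    never as zero — when the sample has no genes of the class: a sample
    with no ARGs has no measurable ARG mobility and imputing 0 would bias
    regressions.
    """
    _check_class(gene_class)
    genes = sset.hits.loc[sset.hits["gene_class"] == gene_class]
    denominator = len(genes)
    if denominator == 0:
        return None
    mobile = mobile_contigs(sset, mge_category)
    numerator = int(genes["contig_id"].isin(mobile).sum())
    value = Fraction(numerator, denominator)
    return value if as_fraction else float(value)


_PAIRS = (("ARG", "MRG"), ("ARG", "VFG"), ("MRG", "VFG"))

INDEX_COLUMNS = (
    ["cr_mrg", "cr_arg", "cr_vfg"]
    + ["cor_arg_mrg", "cor_arg_vfg", "cor_mrg_vfg", "cor_all3", "cor_any_pair"]
    + [f"mp_{c.lower()}" for c in GENE_CLASSES]
    + [f"mp_{c.lower()}_{cat}" for c in GENE_CLASSES for cat in HIT_CATEGORIES + CONTEXT_CATEGORIES]
)


def sample_indices(sset: SampleAnnotationSet) -> dict:
    """All CR/CoR/MP values and denominators for one sample."""
    row: dict = {"sample_id": sset.sample_id}
    for c in GENE_CLASSES:
        row[f"cr_{c.lower()}"] = carrying_rate(sset, c)
    for a, b in _PAIRS:
        row[f"cor_{a.lower()}_{b.lower()}"] = cooccurrence_rate(sset, (a, b))
    row["cor_all3"] = cooccurrence_rate(sset, GENE_CLASSES)
    row["cor_any_pair"] = cooccurrence_rate(sset, ANY_PAIR)
    for c in GENE_CLASSES:
        row[f"mp_{c.lower()}"] = mobility_potential(sset, c, OVERALL)
        for cat in HIT_CATEGORIES + CONTEXT_CATEGORIES:
            row[f"mp_{c.lower()}_{cat}"] = mobility_potential(sset, c, cat)
    row["n_contigs"] = sset.n_contigs
    for c in GENE_CLASSES:
        row[f"n_genes_{c.lower()}"] = sset.n_genes(c)
    return row


def index_table(dataset: Sequence[SampleAnnotationSet]) -> pd.DataFrame:
    """One row per sample with all indices, sorted by sample id.

    Missing mobility potentials (no genes of the class) appear as NaN and
    serialize to empty fields.  Column order is fixed and documented in
    :data:`INDEX_COLUMNS`.
    """
    if not dataset:
        raise ValueError("index_table needs at least one sample")
    rows = []
    for sset in dataset:
        try:
            rows.append(sample_indices(sset))
        except ValueError as exc:
            raise ValueError(f"sample {sset.sample_id!r}: {exc}") from exc
    df = pd.DataFrame(rows).sort_values("sample_id").reset_index(drop=True)
    ordered = ["sample_id"] + INDEX_COLUMNS + [
        "n_contigs",
        "n_genes_mrg",
        "n_genes_arg",
        "n_genes_vfg",
    ]
    df = df[ordered]
    value_cols = [c for c in ordered if c != "sample_id"]
    df[value_cols] = df[value_cols].astype(float)
    return df


def write_index_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def _check_class(gene_class: str) -> None:
    if gene_class not in GENE_CLASSES:
        raise ValueError(f"gene_class must be one of {GENE_CLASSES}, got {gene_class!r}")
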