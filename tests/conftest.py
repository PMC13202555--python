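import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mobindex.io import CONTIG_COLUMNS, HIT_COLUMNS, SampleAnnotationSet, build_sample_set

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

GENE_CLASSES = ("MRG", "ARG", "VFG")
MGE_CATEGORIES = ("plasmid_gene", "IS", "transposon", "integron", "ICE")


def make_contigs(sample_id, n, contexts=None, lengths=None):
    return pd.DataFrame(
        {
            "sample_id": sample_id,
            "contig_id": [f"{sample_id}_c{i}" for i in range(n)],
            "length_bp": lengths if lengths is not None else [1000] * n,
            "mobility_context": contexts if contexts is not None else ["chromosome-like"] * n,
        }
    )


def make_hits(rows):
    """rows: (sample_id, contig_id, gene_class, subclass, gene_name[, pident, evalue, bitscore])"""
    full = []
    for r in rows:
        r = tuple(r)
        if len(r) == 5:
            r = r + (95.0, 1e-10, 100.0)
        full.append(r)
    return pd.DataFrame(full, columns=HIT_COLUMNS)


@pytest.fixture
def sample_set_factory():
    def build(n_contigs, hit_rows, sample_id="S1", contexts=None, metadata=None):
        contigs = make_contigs(sample_id, n_contigs, contexts=contexts)
        hits = make_hits([(sample_id,) + tuple(r) for r in hit_rows])
        return build_sample_set(contigs, hits, metadata, sample_id=sample_id)

    return build


@pytest.fixture
def random_sample_set():
    """Random small annotation sets for oracle-equivalence checks."""

    def build(rng, n_contigs=30, sample_id="R1"):
        contexts = rng.choice(
            ["chromosome-like", "plasmid", "phage", "unknown"],
            size=n_contigs,
            p=[0.85, 0.07, 0.05, 0.03],
        )
        contigs = make_contigs(sample_id, n_contigs, contexts=list(contexts))
        rows = []
        for i in range(n_contigs):
            for c in GENE_CLASSES:
                for g in range(rng.integers(0, 3)):
                    if rng.random() < 0.4:
                        rows.append(
                            (sample_id, f"{sample_id}_c{i}", c, "sub", f"{c.lower()}_{g}")
                        )
            for cat in MGE_CATEGORIES:
                if rng.random() < 0.15:
                    rows.append(
                        (sample_id, f"{sample_id}_c{i}", "MGE", cat, f"{cat}_0")
                    )
        hits = make_hits(rows)
        return build_sample_set(contigs, hits, sample_id=sample_id)

    return build
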