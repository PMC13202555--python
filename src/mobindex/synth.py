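"""Synthetic metagenome-annotation generator with closed-form ground truth.

Emulates the study design the pipeline targets: 12 soil samples (8 from a
metal-contaminated mining area, 4 controls) with metal and physicochemical
covariates, ~5,000 assembled contigs per sample, and per-contig placements
of MRG/ARG/VFG genes and MGE hits.  Gene carriage follows a clamped
linear-probability model in the raw covariates, ``p_class(x) = clamp(b0 +
sum_m b_m (x_m - ref_m))`` — linear rather than logistic so that the
expected carrying rate, co-occurrence rate and mobility potential have
exact closed forms (:func:`truth_indices`) usable as oracles.  MGE hits are
placed per category with a base probability raised by a configurable boost
on gene-carrying contigs, which induces a non-trivial mobility potential.

Everything is deterministic under the seed: the same config + seed
reproduce byte-identical tables.  Clamping of probabilities is counted and
configs that clamp more than 1% of draws are rejected by default.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CONTIG_COLUMNS,
    GENE_CLASSES,
    HIT_COLUMNS,
    MGE_CATEGORIES,
    MGE_CLASS,
    write_contig_table,
    write_hit_table,
    write_metadata,
)

#: Covariate model: name -> (MS mean, MS sd, control mean, control sd).
#: Units follow the study convention: Fe (and WS, SOM, N) in g/kg, trace
#: metals and AP/AK in mg/kg, EC in uS/cm, pH unitless.
DEFAULT_COVARIATES: dict[str, tuple[float, float, float, float]] = {
    "Fe": (100.0, 40.0, 30.0, 8.0),
    "Cr": (80.0, 25.0, 40.0, 10.0),
    "V": (120.0, 30.0, 50.0, 15.0),
    "Mn": (600.0, 150.0, 400.0, 100.0),
    "Zn": (90.0, 25.0, 60.0, 15.0),
    "Cu": (50.0, 15.0, 25.0, 8.0),
    "Ni": (35.0, 10.0, 20.0, 6.0),
    "pH": (8.0, 0.3, 7.8, 0.2),
    "EC": (1500.0, 800.0, 300.0, 120.0),
    "WS": (2.0, 1.0, 0.5, 0.2),
    "SOM": (10.0, 3.0, 12.0, 3.0),
    "N": (0.067, 0.02, 0.037, 0.004),
    "AP": (5.0, 2.0, 8.0, 2.0),
    "AK": (150.0, 50.0, 120.0, 40.0),
}

#: Per-class carriage model: baseline probability at the pooled covariate
#: reference point plus per-raw-unit linear effects (the 1e-6..1e-4 scale of
#: realistic per-unit effects on contig-level rates).
DEFAULT_CARRIAGE: dict[str, dict] = {
    "MRG": {"baseline": 0.030, "effects": {"Fe": 6e-5, "Cu": 1e-4, "Ni": -1e-4}},
    "ARG": {"baseline": 0.020, "effects": {"Cu": 8e-5, "Ni": -1e-4, "Zn": -4e-5}},
    "VFG": {"baseline": 0.025, "effects": {"Cr": 5e-5, "Zn": -5e-5}},
}

#: Per-category MGE placement probability on a non-carrier contig.
DEFAULT_MGE_P: dict[str, float] = {
    "plasmid_gene": 0.004,
    "IS": 0.008,
    "transposon": 0.006,
    "integron": 0.003,
    "ICE": 0.002,
}

_SUBCLASSES = {
    "MRG": ["Fe", "Cu", "Hg", "As", "multi-metal", "Cr", "Zn", "Ni"],
    "ARG": [
        "multidrug",
        "glycopeptide",
        "aminoglycoside",
        "peptide",
        "rifamycin",
        "tetracycline",
        "beta-lactam",
        "macrolide",
    ],
    "VFG": [
        "adherence",
        "stress survival",
        "regulation",
        "immune modulation",
        "effector delivery system",
        "motility",
        "nutritional factor",
        "exotoxin",
    ],
}


@dataclass
class SynthConfig:
    """Study conditions for the generator.  Seed is mandatory downstream."""

    n_ms: int = 8
    n_control: int = 4
    contigs_per_sample: int = 5000
    covariates: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    carriage: Mapping[str, dict] = field(default_factory=lambda: {
        k: {"baseline": v["baseline"], "effects": dict(v["effects"])}
        for k, v in DEFAULT_CARRIAGE.items()
    })
    mge_p: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MGE_P))
    #: added to every category's placement probability on gene-carrying contigs
    mge_boost: float = 0.03
    plasmid_context_p: float = 0.03
    phage_context_p: float = 0.01
    #: mean extra genes per carrier contig (1 + Poisson(lambda) gene records)
    gene_multiplicity_lambda: float = 0.3
    #: optional within-contig coupling: hotspot contigs get all class
    #: probabilities raised by `coupling`, creating genuine co-selection
    hotspot_p: float = 0.0
    coupling: float = 0.0
    #: sd of additive noise for sample-level linear index responses
    index_noise_sd: float = 0.001
    catalog_size: int = 40
    contaminate: bool = False
    max_clamp_fraction: float = 0.01

    @property
    def n_samples(self) -> int:
        return self.n_ms + self.n_control

    def validate(self) -> None:
        for name, (m1, s1, m0, s0) in self.covariates.items():
            if s1 < 0 or s0 < 0:
                raise ValueError(f"covariate {name!r}: sds must be non-negative")
        for c in GENE_CLASSES:
            if c not in self.carriage:
                raise ValueError(f"carriage model missing class {c!r}")
        if not 0 <= self.mge_boost <= 1:
            raise ValueError("mge_boost must be in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually used: per-sample expected indices, the
    linear coefficients, covariate reference point, and the clamp report."""

    expected: pd.DataFrame
    coefficients: dict
    reference: dict
    clamp_fraction: float
    n_clamped: int
    n_probabilities: int


def covariate_reference(config: SynthConfig) -> dict[str, float]:
    """Pooled (sample-size weighted) covariate means: the model's ref point."""
    n1, n0 = config.n_ms, config.n_control
    n = n1 + n0
    return {
        name: (n1 * m1 + n0 * m0) / n
        for name, (m1, _, m0, _) in config.covariates.items()
    }


def generate_metadata(config: SynthConfig, seed: int) -> pd.DataFrame:
    """Group-structured covariate table: truncated-normal draws (>= 0)."""
    config.validate()
    rng = np.random.default_rng(seed)
    sample_ids = [f"MS{i + 1:02d}" for i in range(config.n_ms)] + [
        f"CT{i + 1:02d}" for i in range(config.n_control)
    ]
    groups = ["MS"] * config.n_ms + ["control"] * config.n_control
    rows = {"sample_id": sample_ids, "group": groups}
    for name, (m1, s1, m0, s0) in config.covariates.items():
        vals = []
        for g in groups:
            mean, sd = (m1, s1) if g == "MS" else (m0, s0)
            v = rng.normal(mean, sd) if sd > 0 else mean
            while v < 0:  # truncate at zero: concentrations are non-negative
                v = rng.normal(mean, sd)
            vals.append(v)
        rows[name] = vals
    return pd.DataFrame(rows)


def _carriage_probs(config: SynthConfig, metadata: pd.DataFrame) -> dict:
    """Per-sample, per-class carriage probabilities (raw, unclamped)."""
    ref = covariate_reference(config)
    probs = {}
    for _, row in metadata.iterrows():
        per_class = {}
        for c in GENE_CLASSES:
            model = config.carriage[c]
            p = model["baseline"]
            for cov, coef in model["effects"].items():
                p += coef * (row[cov] - ref[cov])
            per_class[c] = p
        probs[row["sample_id"]] = per_class
    return probs


def _catalog(config: SynthConfig, gene_class: str) -> tuple[list[str], list[str]]:
    subs = _SUBCLASSES[gene_class]
    names = [f"{gene_class.lower()}_{i + 1:04d}" for i in range(config.catalog_size)]
    subclasses = [subs[i % len(subs)] for i in range(config.catalog_size)]
    return names, subclasses


def _hit_quality(rng, size):
    pident = rng.uniform(80.0, 100.0, size)
    evalue = 10 ** rng.uniform(-30.0, -6.0, size)
    bitscore = rng.uniform(60.0, 300.0, size)
    return pident, evalue, bitscore


def generate_contigs_and_hits(
    config: SynthConfig, metadata: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, float, int, int]:
    """Realize contig and hit tables under the generative model.

    Returns ``(contigs, hits, clamp_fraction, n_clamped, n_probs)``; raises
    if the clamped fraction exceeds the configured tolerance.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    probs = _carriage_probs(config, metadata)
    n_clamped = 0
    n_probs = 0
    contig_frames = []
    hit_rows: list[tuple] = []
    catalogs = {c: _catalog(config, c) for c in GENE_CLASSES}
    mge_names = {
        cat: [f"{cat.lower()}_{i + 1:03d}" for i in range(config.catalog_size)]
        for cat in MGE_CATEGORIES
    }
    for sid in metadata["sample_id"]:
        n = config.contigs_per_sample
        lengths = np.maximum(
            np.exp(rng.normal(8.3, 0.8, n)).astype(np.int64), 200
        )
        ctx_draw = rng.random(n)
        context = np.where(
            ctx_draw < config.plasmid_context_p,
            "plasmid",
            np.where(
                ctx_draw < config.plasmid_context_p + config.phage_context_p,
                "phage",
                "chromosome-like",
            ),
        )
        contig_ids = np.array([f"{sid}_c{i + 1:06d}" for i in range(n)])
        contig_frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "contig_id": contig_ids,
                    "length_bp": lengths,
                    "mobility_context": context,
                }
            )
        )
        if n == 0:
            continue
        hotspot = (
            rng.random(n) < config.hotspot_p
            if config.hotspot_p > 0
            else np.zeros(n, dtype=bool)
        )
        carries = {}
        for c in GENE_CLASSES:
            p = probs[sid][c] + config.coupling * hotspot
            n_clamped += int(((p < 0) | (p > 1)).sum())
            n_probs += n
            p = np.clip(p, 0.0, 1.0)
            carries[c] = rng.random(n) < p
        carrier_any = np.logical_or.reduce(list(carries.values()))
        # gene placements
        for c in GENE_CLASSES:
            idx = np.flatnonzero(carries[c])
            names, subs = catalogs[c]
            for i in idx:
                k = 1 + rng.poisson(config.gene_multiplicity_lambda)
                k = min(k, config.catalog_size)
                chosen = rng.choice(config.catalog_size, size=k, replace=False)
                pid, ev, bs = _hit_quality(rng, k)
                for j, g in enumerate(chosen):
                    hit_rows.append(
                        (sid, contig_ids[i], c, subs[g], names[g], pid[j], ev[j], bs[j])
                    )
        # MGE placements: base probability, boosted on gene-carrying contigs
        for cat in MGE_CATEGORIES:
            p = config.mge_p[cat] + config.mge_boost * carrier_any
            n_clamped += int(((p < 0) | (p > 1)).sum())
            n_probs += n
            p = np.clip(p, 0.0, 1.0)
            placed = np.flatnonzero(rng.random(n) < p)
            if len(placed) == 0:
                continue
            pid, ev, bs = _hit_quality(rng, len(placed))
            gname = rng.choice(config.catalog_size, size=len(placed))
            for j, i in enumerate(placed):
                hit_rows.append(
                    (
                        sid,
                        contig_ids[i],
                        MGE_CLASS,
                        cat,
                        mge_names[cat][gname[j]],
                        pid[j],
                        ev[j],
                        bs[j],
                    )
                )
        if config.contaminate and n > 0:
            # below-threshold rows that the quality filter must remove
            n_bad = max(1, int(0.02 * n))
            bad_contigs = rng.choice(n, size=n_bad)
            for i in bad_contigs:
                names, subs = catalogs["ARG"]
                g = int(rng.integers(config.catalog_size))
                fail_identity = rng.random() < 0.5
                pid = rng.uniform(20.0, 79.0) if fail_identity else rng.uniform(80, 100)
                ev = 10 ** rng.uniform(-30, -6) if fail_identity else 10 ** rng.uniform(-4, -1)
                hit_rows.append(
                    (sid, contig_ids[i], "ARG", subs[g], names[g], pid, ev, rng.uniform(10, 50))
                )
    contigs = (
        pd.concat(contig_frames, ignore_index=True)
        if contig_frames
        else pd.DataFrame(columns=CONTIG_COLUMNS)
    )
    hits = pd.DataFrame(hit_rows, columns=HIT_COLUMNS)
    clamp_fraction = n_clamped / max(n_probs, 1)
    if clamp_fraction > config.max_clamp_fraction:
        raise ValueError(
            f"config clamps {100 * clamp_fraction:.2f}% of probabilities "
            f"(> {100 * config.max_clamp_fraction:.0f}% tolerated); adjust "
            "baselines or effects"
        )
    return contigs, hits, clamp_fraction, n_clamped, n_probs


def truth_indices(config: SynthConfig, metadata: pd.DataFrame) -> pd.DataFrame:
    """Closed-form expected CR/CoR/MP per sample under the generative model.

    Independent-Bernoulli algebra: E[CR_c] = p_c; E[CoR_{a,b}] = p_a p_b
    (plus hotspot mixture terms when coupling is on); mobility potentials
    are conditional MGE probabilities on carrier contigs, e.g.
    E[MP(c, cat)] = p_cat + boost, and the overall MP composes the five hit
    categories with the plasmid/phage context labels.
    """
    probs = _carriage_probs(config, metadata)
    h = config.hotspot_p
    rows = []
    for sid, per_class in probs.items():
        row: dict = {"sample_id": sid}

        def p_eff(c, hot):
            return min(max(per_class[c] + config.coupling * hot, 0.0), 1.0)

        def mix(f):
            # expectation over the hotspot indicator
            return (1 - h) * f(0.0) + h * f(1.0) if h > 0 else f(0.0)

        for c in GENE_CLASSES:
            row[f"cr_{c.lower()}"] = mix(lambda hot, c=c: p_eff(c, hot))
        pairs = (("ARG", "MRG"), ("ARG", "VFG"), ("MRG", "VFG"))
        for a, b in pairs:
            row[f"cor_{a.lower()}_{b.lower()}"] = mix(
                lambda hot, a=a, b=b: p_eff(a, hot) * p_eff(b, hot)
            )
        row["cor_all3"] = mix(lambda hot: math.prod(p_eff(c, hot) for c in GENE_CLASSES))

        def p_ge2(hot):
            ps = [p_eff(c, hot) for c in GENE_CLASSES]
            none = math.prod(1 - p for p in ps)
            exactly_one = sum(
                p * math.prod(1 - q for j, q in enumerate(ps) if j != i)
                for i, p in enumerate(ps)
            )
            return 1 - none - exactly_one

        row["cor_any_pair"] = mix(p_ge2)
        # MP: conditional on being a carrier, every hit category is boosted
        not_any_mge = math.prod(
            1 - min(config.mge_p[cat] + config.mge_boost, 1.0) for cat in MGE_CATEGORIES
        )
        overall = 1 - not_any_mge * (1 - config.plasmid_context_p) * (
            1 - config.phage_context_p
        )
        for c in GENE_CLASSES:
            row[f"mp_{c.lower()}"] = overall
            for cat in MGE_CATEGORIES:
                row[f"mp_{c.lower()}_{cat}"] = min(
                    config.mge_p[cat] + config.mge_boost, 1.0
                )
            row[f"mp_{c.lower()}_plasmid"] = config.plasmid_context_p
            row[f"mp_{c.lower()}_phage"] = config.phage_context_p
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SyntheticDataset:
    metadata: pd.DataFrame
    contigs: pd.DataFrame
    hits: pd.DataFrame
    truth: GroundTruth
    seed: int


def generate_dataset(config: SynthConfig, seed: int) -> SyntheticDataset:
    """Metadata + contigs + hits + ground truth, fully determined by seed."""
    meta_seed, table_seed = _fan_out(seed)
    metadata = generate_metadata(config, meta_seed)
    contigs, hits, clamp_fraction, n_clamped, n_probs = generate_contigs_and_hits(
        config, metadata, table_seed
    )
    truth = GroundTruth(
        expected=truth_indices(config, metadata),
        coefficients={c: dict(config.carriage[c]["effects"]) for c in GENE_CLASSES},
        reference=covariate_reference(config),
        clamp_fraction=clamp_fraction,
        n_clamped=n_clamped,
        n_probabilities=n_probs,
    )
    return SyntheticDataset(metadata=metadata, contigs=contigs, hits=hits, truth=truth, seed=seed)


def _fan_out(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    return (
        int(children[0].generate_state(1)[0] % (2**31)),
        int(children[1].generate_state(1)[0] % (2**31)),
    )


def generate_linear_response(
    metadata: pd.DataFrame,
    intercept: float,
    coefficients: Mapping[str, float],
    noise_sd: float,
    seed: int,
    name: str = "response",
) -> pd.Series:
    """Sample-level linear response y = b0 + sum b_m x_m + N(0, sd) noise.

    Used to create index-like responses with known per-unit coefficients for
    regression parameter-recovery studies.
    """
    rng = np.random.default_rng(seed)
    y = np.full(len(metadata), float(intercept))
    for cov, coef in coefficients.items():
        y = y + coef * metadata[cov].to_numpy(dtype=float)
    y = y + rng.normal(0.0, noise_sd, len(metadata))
    return pd.Series(y, index=metadata.index, name=name)


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Emit meta.tsv, contigs.tsv, per-class hit TSVs and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"meta": outdir / "meta.tsv", "contigs": outdir / "contigs.tsv"}
    write_metadata(ds.metadata, paths["meta"])
    write_contig_table(ds.contigs, paths["contigs"])
    for c in GENE_CLASSES + (MGE_CLASS,):
        p = outdir / f"hits_{c.lower()}.tsv"
        write_hit_table(ds.hits.loc[ds.hits["gene_class"] == c], p)
        paths[f"hits_{c.lower()}"] = p
    truth_path = outdir / "truth.json"
    payload = {
        "seed": ds.seed,
        "coefficients": ds.truth.coefficients,
        "reference": ds.truth.reference,
        "clamp_fraction": ds.truth.clamp_fraction,
        "n_clamped": ds.truth.n_clamped,
        "n_probabilities": ds.truth.n_probabilities,
        "expected": ds.truth.expected.to_dict(orient="records"),
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["truth"] = truth_path
    return {k: str(v) for k, v in paths.items()}
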