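"""End-to-end orchestration: ingest/synth -> indices -> diversity -> regress.

A run is driven by one YAML (or dict) config and a single seed; every
stochastic stage derives its stream as ``(seed + crc32(stage_name)) %
2**31``, so reruns with identical inputs + config + seed reproduce
identical numeric outputs.  Regression models use collected-error
semantics: one singular fit is recorded in the manifest without aborting
the other models.  All outputs are written atomically (tmp file + rename).
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import diversity as dv
from . import indices as ix
from . import io as aio
from . import regress as rg
from . import synth as sy


def stage_seed(run_seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out from the run seed."""
    return (int(run_seed) + zlib.crc32(stage.encode())) % (2**31)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _atomic_to_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=kw.pop("index", False), na_rep="", **kw)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def validate_config(cfg: dict) -> None:
    """Fail fast, before any stage runs."""
    if "seed" not in cfg:
        raise ValueError("config must set 'seed'")
    if "outdir" not in cfg:
        raise ValueError("config must set 'outdir'")
    if ("synth" in cfg) == ("inputs" in cfg):
        raise ValueError("config must set exactly one of 'synth' or 'inputs'")
    if "inputs" in cfg:
        inp = cfg["inputs"]
        for key in ("contigs", "meta"):
            if key not in inp:
                raise ValueError(f"inputs section must set {key!r}")
            if not Path(inp[key]).exists():
                raise ValueError(f"input file does not exist: {inp[key]}")
        for h in inp.get("hits", []):
            if not Path(h["path"] if isinstance(h, dict) else h).exists():
                raise ValueError(f"input file does not exist: {h}")
    for model in cfg.get("regress", {}).get("models", []):
        if "response" not in model or "predictors" not in model:
            raise ValueError("each regression model needs 'response' and 'predictors'")


def run_all(config) -> dict:
    """Run every configured stage in dependency order; return the manifest."""
    cfg = load_config(config)
    validate_config(cfg)
    seed = int(cfg["seed"])
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": {},
        "stages": {},
        "outputs": {},
    }

    t0 = time.perf_counter()
    if "synth" in cfg:
        synth_cfg = sy.SynthConfig(**(cfg["synth"] or {}))
        ds = sy.generate_dataset(synth_cfg, stage_seed(seed, "synth"))
        metadata, contigs, hits = ds.metadata, ds.contigs, ds.hits
        paths = sy.write_dataset(ds, outdir / "synth")
        manifest["outputs"]["synth"] = paths
        manifest["stages"]["data"] = {
            "status": "ok",
            "mode": "synth",
            "seconds": round(time.perf_counter() - t0, 3),
            "n_samples": len(metadata),
            "clamp_fraction": ds.truth.clamp_fraction,
        }
    else:
        inp = cfg["inputs"]
        contigs = aio.read_contig_table(inp["contigs"])
        metadata = aio.read_metadata(inp["meta"])
        hit_frames = []
        for h in inp.get("hits", []):
            if isinstance(h, dict):
                hit_frames.append(
                    aio.parse_hit_table(
                        h["path"],
                        h["gene_class"],
                        h.get("dialect", "native"),
                        sample_id=h.get("sample_id"),
                        subclass=h.get("subclass", ""),
                    )
                )
                manifest["input_checksums"][str(h["path"])] = _sha256(Path(h["path"]))
            else:
                raise ValueError(
                    "each hits entry must be a mapping with 'path' and 'gene_class'"
                )
        hits = (
            pd.concat(hit_frames, ignore_index=True)
            if hit_frames
            else pd.DataFrame(columns=aio.HIT_COLUMNS)
        )
        for key in ("contigs", "meta"):
            manifest["input_checksums"][str(inp[key])] = _sha256(Path(inp[key]))
        manifest["stages"]["data"] = {
            "status": "ok",
            "mode": "ingest",
            "seconds": round(time.perf_counter() - t0, 3),
            "n_samples": metadata["sample_id"].nunique(),
        }

    # quality filter + join
    fl = cfg.get("filter", {})
    hits = aio.filter_hits(
        hits,
        float(fl.get("max_evalue", aio.DEFAULT_MAX_EVALUE)),
        float(fl.get("min_identity", aio.DEFAULT_MIN_IDENTITY)),
    )
    min_len = int(cfg.get("indices", {}).get("min_contig_length", 0))
    if min_len > 0:
        contigs = contigs.loc[contigs["length_bp"] >= min_len].reset_index(drop=True)
        hits = hits.loc[hits["contig_id"].isin(set(contigs["contig_id"]))].reset_index(drop=True)
    dataset = aio.build_dataset(contigs, hits, metadata)

    # indices
    t0 = time.perf_counter()
    table = ix.index_table(dataset)
    indices_path = outdir / "indices.tsv"
    _atomic_to_csv(table, indices_path)
    denominators = table[
        ["sample_id", "n_contigs", "n_genes_mrg", "n_genes_arg", "n_genes_vfg"]
    ].to_dict(orient="records")
    _atomic_write(
        outdir / "indices.json",
        json.dumps(
            {
                "indices": json.loads(table.to_json(orient="records")),
                "denominators": denominators,
            },
            indent=1,
            sort_keys=True,
        ),
    )
    manifest["outputs"]["indices"] = {
        "tsv": str(indices_path),
        "json": str(outdir / "indices.json"),
    }
    manifest["stages"]["indices"] = {
        "status": "ok",
        "seconds": round(time.perf_counter() - t0, 3),
        "n_rows": len(table),
    }

    # diversity
    div_cfg = cfg.get("diversity")
    if div_cfg:
        t0 = time.perf_counter()
        gene_class = div_cfg.get("gene_class", "ARG").upper()
        metric = div_cfg.get("metric", "bray")
        abundance = dv.abundance_from_hits(hits, gene_class)
        alpha = dv.alpha_table(abundance)
        _atomic_to_csv(alpha.reset_index(), outdir / "alpha.tsv")
        dm = dv.horn(abundance) if metric == "horn" else dv.bray_curtis(abundance)
        _atomic_to_csv(dm, outdir / f"dissim_{metric}.tsv", index=True)
        ord_res = dv.pcoa(dm)
        _atomic_to_csv(ord_res.coordinates.reset_index(), outdir / f"pcoa_{metric}.tsv")
        grouping = metadata.set_index("sample_id").loc[abundance.index, "group"]
        perm = dv.permanova(
            dm,
            grouping.to_numpy(),
            n_permutations=int(div_cfg.get("permutations", 999)),
            seed=stage_seed(seed, "permanova"),
        )
        _atomic_write(
            outdir / "permanova.json",
            json.dumps(
                {
                    "pseudo_F": perm.pseudo_F,
                    "R2": perm.R2,
                    "p_value": perm.p_value,
                    "n_permutations": perm.n_permutations,
                    "seed": perm.seed,
                    "exhaustive": perm.exhaustive,
                    "metric": metric,
                    "gene_class": gene_class,
                },
                indent=1,
                sort_keys=True,
            ),
        )
        manifest["outputs"]["diversity"] = {
            "alpha": str(outdir / "alpha.tsv"),
            "dissim": str(outdir / f"dissim_{metric}.tsv"),
            "pcoa": str(outdir / f"pcoa_{metric}.tsv"),
            "permanova": str(outdir / "permanova.json"),
        }
        manifest["stages"]["diversity"] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "permanova_p": perm.p_value,
        }

    # regressions: collected-error semantics
    reg_cfg = cfg.get("regress")
    if reg_cfg:
        t0 = time.perf_counter()
        merged = table.merge(metadata, on="sample_id")
        results = {}
        errors = {}
        for model in reg_cfg.get("models", []):
            name = model.get("name", model["response"])
            spec = rg.RegressionSpec(
                response=model["response"],
                predictors=list(model["predictors"]),
                family=model.get("family", "auto"),
                vif_threshold=float(model.get("vif_threshold", 5.0)),
                seed=stage_seed(seed, f"regress:{name}"),
                chains=int(model.get("chains", 4)),
                draws=int(model.get("draws", 1000)),
                warmup=int(model.get("warmup", 1000)),
            )
            try:
                res = rg.auto_cascade(spec, merged)
            except Exception as exc:  # noqa: BLE001 - collected, reported, not fatal
                errors[name] = str(exc)
                continue
            results[name] = {
                "family_used": res.family_used,
                "n_obs": res.n_obs,
                "coefficients": json.loads(res.coefficients.to_json(orient="index")),
                "diagnostics": _plain(res.diagnostics),
                "excluded_predictors": _plain(res.excluded_predictors),
                "branch_trail": res.extras.get("branch_trail", []),
            }
        payload = {"models": results, "errors": errors}
        _atomic_write(
            outdir / "regression_results.json",
            json.dumps(payload, indent=1, sort_keys=True, default=float),
        )
        manifest["outputs"]["regress"] = {"json": str(outdir / "regression_results.json")}
        if reg_cfg.get("spearman"):
            sp = reg_cfg["spearman"]
            spearman = rg.spearman_matrix(
                merged[list(sp["covariates"])],
                merged[list(sp["outcomes"])],
                adjust=sp.get("adjust", "none"),
            )
            _atomic_to_csv(spearman, outdir / "spearman.tsv")
            manifest["outputs"]["regress"]["spearman"] = str(outdir / "spearman.tsv")
        manifest["stages"]["regress"] = {
            "status": "ok" if not errors else "partial",
            "seconds": round(time.perf_counter() - t0, 3),
            "n_models": len(results),
            "n_errors": len(errors),
            "errors": errors,
        }

    _atomic_write(
        outdir / "manifest.json", json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    manifest["outputs"]["manifest"] = str(outdir / "manifest.json")
    return manifest


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (bool, str)) or obj is None:
        return obj
    if isinstance(obj, (int,)):
        return int(obj)
    try:
        return float(obj)
    except (TypeError, ValueError):
        return str(obj)


def report(manifest: dict) -> str:
    """Human-readable markdown summary regenerated purely from the manifest."""
    lines = ["# mobindex run report", ""]
    lines.append(f"- package version: {manifest.get('package_version', '?')}")
    lines.append(f"- seed: {manifest.get('seed', '?')}")
    lines.append(f"- config hash: `{manifest.get('config_hash', '?')}`")
    lines.append("")
    lines.append("## Stages")
    lines.append("")
    lines.append("| stage | status | seconds |")
    lines.append("|---|---|---|")
    stages = manifest.get("stages", {})
    for name, info in stages.items():
        lines.append(f"| {name} | {info.get('status', '?')} | {info.get('seconds', '?')} |")
    if not stages:
        lines.append("| (none) | incomplete | - |")
        lines.append("")
        lines.append("**Warning:** manifest contains no completed stages.")
    data = stages.get("data", {})
    if data:
        lines.append("")
        lines.append(f"Samples: {data.get('n_samples', '?')} ({data.get('mode', '?')} mode).")
    reg = stages.get("regress")
    if reg:
        lines.append("")
        lines.append("## Regression models")
        lines.append("")
        lines.append(
            f"{reg.get('n_models', 0)} model(s) fitted, {reg.get('n_errors', 0)} "
            "collected error(s)."
        )
        for name, err in (reg.get("errors") or {}).items():
            lines.append(f"- `{name}`: ERROR {err}")
        reg_out = manifest.get("outputs", {}).get("regress", {})
        path = reg_out.get("json")
        if path and Path(path).exists():
            payload = json.loads(Path(path).read_text())
            for name, model in sorted(payload.get("models", {}).items()):
                lines.append("")
                lines.append(
                    f"### {name} — family: {model['family_used']}, n = {model['n_obs']}"
                )
                lines.append("")
                lines.append("| term | estimate | 95% low | 95% high |")
                lines.append("|---|---|---|---|")
                for term, row in model["coefficients"].items():
                    est, lo, hi = row["estimate"], row["ci_low"], row["ci_high"]
                    lines.append(f"| {term} | {est:.6g} | {lo:.6g} | {hi:.6g} |")
                diag = model.get("diagnostics", {})
                if "max_rhat" in diag:
                    lines.append("")
                    lines.append(
                        f"Convergence: max R-hat {diag['max_rhat']:.3f}, min bulk ESS "
                        f"{diag['min_bulk_ess']:.0f}, PPC p(mean) {diag['ppc_p_mean']:.2f}, "
                        f"PPC p(sd) {diag['ppc_p_sd']:.2f}."
                    )
    idx_out = manifest.get("outputs", {}).get("indices", {})
    path = idx_out.get("tsv")
    if path and Path(path).exists():
        table = pd.read_csv(path, sep="\t")
        lines.append("")
        lines.append("## Indices (per-sample summary)")
        lines.append("")
        lines.append("| sample | CR(MRG) | CR(ARG) | CR(VFG) | CoR(any pair) | MP(ARG) |")
        lines.append("|---|---|---|---|---|---|")
        for _, r in table.iterrows():
            mp = r["mp_arg"]
            mp_txt = "missing" if pd.isna(mp) else f"{mp:.4f}"
            lines.append(
                f"| {r['sample_id']} | {r['cr_mrg']:.4f} | {r['cr_arg']:.4f} | "
                f"{r['cr_vfg']:.4f} | {r['cor_any_pair']:.5f} | {mp_txt} |"
            )
    lines.append("")
    return "\n".join(lines)
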