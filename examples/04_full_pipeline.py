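"""One-shot pipeline run: synth -> filter -> indices -> diversity -> regress.

Equivalent to `mobindex run --config run.yaml`; everything derives from the
single run seed, so re-running reproduces identical outputs.
"""

import tempfile
from pathlib import Path

from mobindex import report, run_all

outdir = Path(tempfile.mkdtemp(prefix="mobindex_demo_"))
config = {
    "seed": 17,
    "outdir": str(outdir),
    "synth": {"contigs_per_sample": 1000},
    "diversity": {"gene_class": "ARG", "metric": "bray", "permutations": 499},
    "regress": {
        "models": [
            {"name": "cr_mrg_drivers", "response": "cr_mrg", "predictors": ["Fe", "Cu", "Ni"]},
            {"name": "cr_arg_drivers", "response": "cr_arg", "predictors": ["Cu", "Ni"]},
        ],
        "spearman": {"covariates": ["Fe", "V", "Cu"], "outcomes": ["cr_mrg", "mp_arg"]},
    },
}

manifest = run_all(config)
print(report(manifest))
print("outputs in:", outdir)
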