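"""Run every stage from one config and inspect the report directory."""

import json
from pathlib import Path

import soilpem as sp

cfg = sp.PipelineConfig(outdir="scratch/example_report", seed=1,
                        n_perm=199, bootstrap_n=99, rf_trees=100, rf_perm=49)
cfg.generator = sp.GeneratorConfig(
    richness={"bacteria": 80, "fungi": 40, "archaea": 20})
outdir = sp.run_all(cfg)

manifest = json.loads((Path(outdir) / "manifest.json").read_text())
print("stages run:", manifest["stages"])
print("outputs:")
for p in sorted(Path(outdir).glob("*.tsv")):
    print("  ", p.name)
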