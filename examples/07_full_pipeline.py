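"""Run the bundled end-to-end toy study.

Equivalent to `hybgen run-all --seed 0 --out hybgen_run` on the command
line; every stage writes TSV/JSON outputs and a manifest with the seed and
config hash, and a rerun with the same seed is byte-identical.
"""

import json

from hybgen import pipeline

config = pipeline.toy_config(outdir="hybgen_run", seed=0)
report = pipeline.run(config)
print(json.dumps(report["stages"], indent=2, default=str))
print("outputs under:", config.outdir)
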