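"""Run the whole analysis from one config and inspect the artifacts.

Equivalent shell command:  ftdpls run-all config.yaml
"""

import json
from pathlib import Path

from ftdpls import RunConfig, SimConfig, run_pipeline

out = Path("scratch/example_run")
config = RunConfig(outdir=str(out), seed=42, sim=SimConfig(),
                   n_perm=200, n_boot=200, cv_repeats=10, n_learners=50)
manifest = run_pipeline(config)

print("Stages and artifacts:")
for stage, info in manifest["stages"].items():
    print(f"  {stage:12s} {info['seconds']:7.2f}s  {', '.join(info['outputs'])}")

metrics = json.loads((out / "metrics.json").read_text())
print("\nCross-validated subtype classification accuracy:")
for name, rep in metrics.items():
    print(f"  {name:22s} {rep['accuracy_mean']:6.2f}% (SD {rep['accuracy_sd']:.2f}%)")
print("\nEvery number above is reproducible from the single master seed; "
      "rerunning this script yields byte-identical artifacts.")
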