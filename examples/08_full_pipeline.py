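"""One-call end-to-end run: simulate -> build -> census -> nulls -> models
-> village, with a manifest and figure-analogue report tables.

Equivalent shell command:  cyclewealth run --out-dir run1 --n-villages 5 --seed 9
"""

import json

from cyclewealth import RunConfig, report, run_pipeline

config = RunConfig(out_dir="scratch/example_run", seed=9, n_villages=5,
                   village={"n_households": 12}, K=4,
                   null_replicates=25, permutation_B=150)
manifest = run_pipeline(config)
print("stage timings (s):",
      json.dumps({s["stage"]: s["elapsed_s"] for s in manifest["stages"]}))

tables = report(manifest)
missing = tables.pop("missing")
for name, df in tables.items():
    print(f"  report/{name}.csv: {df.shape[0]} rows x {df.shape[1]} cols")
print("missing:", missing or "none")
print("\nEvery table in the run directory is traceable through run_manifest.json "
      "(stage, seed, content hash); rerunning the same config reproduces "
      "identical hashes.")
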