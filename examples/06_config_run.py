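"""Config-driven runs with reproducible manifests.

The runner module executes a validated configuration (phantom generation,
phoneme posture, convergence study, quality report) and writes a manifest
recording the config hash, seed and package versions.  A dry run resolves
the activation schedules without touching the solver.
"""
import json

from tonguefem.runner import RunConfig, run

cfg = RunConfig(command="phoneme", phoneme="i", dry_run=True,
                output_dir="runs/i_dry")
manifest = run(cfg)
print("dry-run resolved schedules (Pa):",
      json.dumps(manifest["schedules_pa"], indent=1))
print("config hash:", manifest["config_hash"])

cfg2 = RunConfig(command="quality", output_dir="runs/quality",
                 phantom={"resolution": 9.0})
manifest2 = run(cfg2)
print("\nmesh quality summary:")
for k, v in manifest2["quality"].items():
    print(f"  {k}: {v}")
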