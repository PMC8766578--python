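"""End-to-end run: simulate inputs, classify, aggregate, match, estimate.

Writes every inter-stage artifact (CSV/JSON) plus a manifest with file
digests into ./scratch_run/ and prints a per-stage summary.
"""

import json
from pathlib import Path

from dietscape import PipelineConfig, run_all

config = PipelineConfig(
    simulate=dict(n_zips=40, participants_per_zip=32, active_days_mean=14),
    bootstrap_reps=200,
    seed=11,
)
outdir = Path("scratch_run")
manifest = run_all(config, outdir)

for stage in manifest.stages:
    print(f"{stage.name:12s} {stage.status:6s} {stage.seconds:5.1f}s  "
          f"records out: {stage.records_out}")

results = json.loads((outdir / "results.json").read_text())
print(f"\n{len(results)} factor x outcome estimates written to {outdir}/results.json, e.g.:")
r = results[0]
print(f"  {r['factor']} -> {r['outcome']}: {r['relative_diff_pct']:+.2f}% "
      f"[{r['ci_low_pct']:+.2f}, {r['ci_high_pct']:+.2f}], {r['n_pairs']} pairs")
print(
    "\nEach stage's inputs/outputs are digest-recorded in manifest.json, so "
    "re-running the same configuration reproduces identical files."
)
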