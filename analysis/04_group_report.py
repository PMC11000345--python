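#!/usr/bin/env python
"""Aggregate per-subject accuracies and permutation nulls into the group
summary: mean above-chance accuracy, SEM, p-values, significance flags,
and the bar-with-points figure.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from erpdecode import DecodingResult, load_config, plot_group_report, summarize
from erpdecode.significance import PermutationNull

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--config", default=Path(__file__).parent / "config.yaml")
args = ap.parse_args()

cfg = load_config(args.config)
out_dir = Path(cfg["out_dir"])
df = pd.read_csv(out_dir / "decoding.csv")
nulls_raw = json.loads((out_dir / "nulls.json").read_text())
tuning_info = json.loads((out_dir / "tuning.json").read_text())

results = [
    DecodingResult(
        subject_id=row["subject"],
        scheme=row["scheme"],
        per_repeat_accuracy=[v for k, v in row.items() if k.startswith("repeat_")],
        mean_accuracy=row["mean_accuracy"],
        chance=row["chance"],
    )
    for row in df.to_dict(orient="records")
]
nulls = [
    PermutationNull(
        scheme=scheme,
        n_perm=blob["n_perm"],
        per_subject=np.array(list(blob["per_subject"].values())),
        group_null=np.array(blob["group_null"]),
        alpha=blob["alpha"],
        boundary=blob["boundary"],
    )
    for scheme, blob in nulls_raw.items()
]

report = summarize(results, nulls, alpha=cfg["alpha"],
                   tuning_subject_ids=tuple(tuning_info["tuning_subjects"]))
(out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=1, sort_keys=True))
plot_group_report(report, out_dir / "figure.png")

print(f"group report over {next(iter(report.schemes.values())).n_subjects} subjects "
      f"(alpha {cfg['alpha']}):")
for scheme in ("happy-sad", "happy-neutral", "sad-neutral", "multiclass"):
    sm = report.schemes[scheme]
    star = " *" if sm.significant else ""
    print(f"  {scheme:15s} {sm.mean_above_chance:+6.2f} +/- {sm.sem:.2f} pts, "
          f"p = {sm.p_value:.4f}{star}")
print(f"report -> {out_dir / 'report.json'}, figure -> {out_dir / 'figure.png'}")
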