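#!/usr/bin/env python
"""Statistical validation studies of the pipeline itself.

Three simulation studies (shared with the test suite and the acceptance
script): the trial-rejection floor, the type-I error of the group
permutation boundary on zero-effect cohorts, and decoding power versus
emotion-effect size. The calibration study takes several minutes on one
CPU; shrink --cohorts for a quick look. Writes results/validation.json.
"""

import argparse
import json
from pathlib import Path

from erpdecode.studies import (
    null_calibration_study,
    power_study,
    rejection_floor_study,
)

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=0)
ap.add_argument("--cohorts", type=int, default=50, help="null cohorts for the type-I study")
ap.add_argument("--out", default="results/validation.json")
args = ap.parse_args()

floor = rejection_floor_study(seed=args.seed, n_subjects=20)
print(f"rejection floor: min {floor['min_retained_per_stimulus']} trials per stimulus "
      f"over {floor['n_subjects']} subjects (mean {floor['mean_rejected']:.1f} rejected)")

power = power_study(seed=args.seed)
curve = power["mean_above_chance_by_scale"]
print("power: mean above-chance accuracy by effect scale "
      + ", ".join(f"{k:g} -> {v:+.2f} pts" for k, v in sorted(curve.items()))
      + f" (monotone: {power['monotone']})")
print(f"  at effect scale {power['large_scale']:g}: significant schemes = "
      f"{power['significant_at_large']}")

calib = null_calibration_study(seed=args.seed, n_cohorts=args.cohorts)
print(f"type-I error: {calib['n_significant']}/{calib['n_cohorts']} null cohorts "
      f"declared significant ({calib['false_positive_rate']:.3f}; "
      f"binomial 95% envelope {calib['binomial_upper_fraction']:.3f})")

out = Path(args.out)
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(json.dumps(
    {"rejection_floor": floor, "power": power, "type_one_error": calib},
    indent=1, sort_keys=True,
))
print(f"-> {out}")
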