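#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes a 150-participant cohort (113 healthy, ~17 athletes, ~20 movement
impaired in expectation) under scratch/cohort/: per-activity motion-trace
CSVs with JSON sidecars, overall-score trials, raw functional-test
measurements, and the manifest with each participant's latent impairment.
The raw cohort is bulky regenerable data, hence scratch/ rather than
results/.
"""

import argparse
from pathlib import Path

from movemetrics.pipeline import simulate_stage
from movemetrics.simulate import CohortSpec

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--n", type=int, default=150)
    parser.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = parser.parse_args()

    spec = CohortSpec(seed=args.seed, n=args.n)
    manifest = simulate_stage(spec, args.out)
    counts: dict[str, int] = {}
    for p in manifest["participants"]:
        counts[p["class_label"]] = counts.get(p["class_label"], 0) + 1
    print(f"cohort of {args.n} written to {args.out} (seed {args.seed})")
    print("class counts:", dict(sorted(counts.items())))


if __name__ == "__main__":
    main()
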