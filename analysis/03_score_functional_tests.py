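#!/usr/bin/env python
"""Score the thirteen reference functional movement tests.

Reads the raw trial measurements of the cohort (tests.csv, balance-trial
acceleration samples, limb lengths) and applies each test's aggregation
rule, producing the 15 scalar scores per participant in
results/test_scores.csv. Tests a participant did not complete stay empty.
"""

import argparse
from pathlib import Path

from movemetrics.pipeline import score_tests_stage

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=ROOT / "scratch" / "cohort")
    parser.add_argument("--out", type=Path,
                        default=ROOT / "results" / "test_scores.csv")
    args = parser.parse_args()

    scores = score_tests_stage(args.cohort, args.out)
    completion = scores.notna().sum()
    print(f"scored {scores.shape[1]} tests for {len(scores)} participants "
          f"-> {args.out}")
    print("completion counts per test:")
    print(completion.to_string())


if __name__ == "__main__":
    main()
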