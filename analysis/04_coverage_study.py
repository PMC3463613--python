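#!/usr/bin/env python
"""Coverage of the percentile-bootstrap median interval.

Simulates repeated lifespan assays from the reference cubic-logit curve
(median near day 18), bootstraps each, and reports how often the 95%
interval contains the true median.  A 50-replicate run keeps this script
quick; the acceptance script runs the full 200-replicate version.
"""

from pathlib import Path

import lumispan as ls
from lumispan import io as lio

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 314
REPS = 50
B = 300


def main() -> None:
    curve = ls.default_cubic_curve()
    design = ls.LifespanDesign(seed=SEED)
    result = ls.coverage_experiment(
        curve, design, reps=REPS, B=B, config=ls.ModelConfig(degree=3),
        seed=SEED,
    )
    print(
        f"true median {curve.true_median:.2f} d; "
        f"{result.n_success}/{REPS} replicates succeeded; "
        f"coverage {result.coverage:.2%} (nominal 95%)"
    )
    lio.write_json(
        {
            "seed": SEED,
            "reps": REPS,
            "B": B,
            "true_median_days": result.true_median,
            "coverage": result.coverage,
        },
        OUT / "coverage_study.json",
    )
    print(f"wrote {OUT / 'coverage_study.json'}")


if __name__ == "__main__":
    main()
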