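#!/usr/bin/env python
"""How fast does averaging more strides stabilize the cost estimate?

Draws i.i.d. synthetic strides, computes the N-stride mean torque-squared
cost for N in {1, 2, 5, 10, 20} (2000 resamples each) and measures how its
variance shrinks — the 1/N law that motivates multi-stride averaging.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

from stridecost.effort import TorqueSquaredCost
from stridecost.stats import variance_scaling_experiment
from stridecost.synthetic import SyntheticGaitConfig


def main() -> None:
    cfg = SyntheticGaitConfig(seed=0, sigma_period=0.0)
    out = variance_scaling_experiment(
        cfg, TorqueSquaredCost(), [1, 2, 5, 10, 20], n_resamples=2000, seed=3
    )
    table = out["table"]
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "variance_scaling.csv", index=False)
    print(table.to_string(index=False))
    lo, hi = out["ratio_ci"]
    print(f"\nlog-log slope of variance vs N: {out['loglog_slope']:.3f} (1/N law -> -1)")
    print(f"var(5)/var(1) = {out['ratio_5_1']:.4f}, bootstrap 95% CI [{lo:.4f}, {hi:.4f}]")


if __name__ == "__main__":
    main()
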