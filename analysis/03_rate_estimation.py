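#!/usr/bin/env python
"""Validation of rate estimation from biased escape times.

Four experiments on synthetic escape-time ensembles drawn from the
survival law S(t) = exp(-k0 int e^{gamma beta V_MB} dt'):

* zero-bias reduction -- the fitter must collapse to the exponential MLE;
* parameter recovery at n = 500 (20 replicates, full pipeline);
* KS-test calibration under the true model (200 replicates, 41 runs);
* coverage of the 30th-70th bootstrap percentile interval at the
  41-run study scale (50 replicates).

Writes results/ktr_validation.json.

Finding: the fitter is exact in the unbiased limit, recovers k0 with a
median error under 10% at n = 500, and the KS filter is well
calibrated.  The 30th-70th bootstrap band is a ~40%-nominal interval:
its measured coverage sits near that level, far below what a casual
reading might hope -- single-ensemble rate estimates at n = 41 carry
multiplicative uncertainty well beyond the printed band.
"""

import json
import warnings
from pathlib import Path

from unbindkit import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260924


def main() -> None:
    warnings.filterwarnings("ignore")
    res = {
        "zero_bias": ex.zero_bias_reduction(seed=SEED),
        "recovery_n500": ex.ktr_recovery(seed=SEED),
        "ks_calibration": ex.ks_calibration(seed=SEED),
        "bootstrap_coverage": ex.bootstrap_coverage(seed=SEED),
    }
    OUT.mkdir(exist_ok=True)
    with open(OUT / "ktr_validation.json", "w") as fh:
        json.dump(res, fh, indent=2, default=float)
    print(f"zero-bias rel. error: {res['zero_bias']['rel_error']:.2e}")
    print(
        "n=500 recovery: median |k0_hat - k0|/k0 = "
        f"{res['recovery_n500']['median_rel_error']:.3f}"
    )
    print(
        "KS calibration: "
        f"{100 * res['ks_calibration']['fraction_p_above_005']:.0f}% "
        "of replicates pass at p > 0.05"
    )
    print(
        "bootstrap 30-70 interval coverage at n=41: "
        f"{100 * res['bootstrap_coverage']['coverage']:.0f}%"
    )
    print(f"wrote {OUT / 'ktr_validation.json'}")


if __name__ == "__main__":
    main()
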