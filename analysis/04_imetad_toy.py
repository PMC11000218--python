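#!/usr/bin/env python
"""Full-stack toy infrequent metadynamics: biased escapes -> unbiased rate.

41 independent infrequent-metadynamics Langevin runs on the 8 kT radial
binding landscape (bias on rho, commitment when the synthetic
coordination number drops below 0.01) are fed through the survivor-
averaged maximum-bias fit and the time-dependent-rate likelihood.  The
resulting k0 is checked against a direct measurement: long unbiased
first-passage runs on a 4 kT copy of the same landscape, rescaled to
8 kT with the one-dimensional Kramers ratio.  Writes
results/imetad_toy.json.

Finding: the KTR estimate lands within a factor ~2 of the rescaled
direct rate (well inside one order of magnitude), with gamma near 1 --
the radial CV is an ideal coordinate for this landscape, and here the
hyperdynamics rescaling estimator agrees too.
"""

import json
import warnings
from pathlib import Path

from unbindkit import experiments as ex

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260924


def main() -> None:
    warnings.filterwarnings("ignore")
    r = ex.imetad_order_of_magnitude(seed=SEED)
    OUT.mkdir(exist_ok=True)
    with open(OUT / "imetad_toy.json", "w") as fh:
        json.dump(r, fh, indent=2, default=float)
    print(f"KTR unbiased rate:        {r['k0_ktr']:.3e} /time")
    print(f"rescaled direct rate:     {r['k0_reference']:.3e} /time")
    print(f"log10 ratio:              {r['log10_ratio']:+.2f}")
    print(f"bias-quality gamma:       {r['gamma_ktr']:.2f}")
    print(f"KS p-value of the fit:    {r['ks_pvalue']:.2f}")
    print(f"hyperdynamics rate:       {r['k_hyperdynamics']:.3e} /time "
          f"(KS p = {r['hyper_ks_pvalue']:.2f})")
    print(f"wrote {OUT / 'imetad_toy.json'}")


if __name__ == "__main__":
    main()
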