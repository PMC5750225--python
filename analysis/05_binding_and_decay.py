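"""Fit equilibrium binding and RNA stability curves.

Simulates anisotropy saturation curves (K_d = 300 nM, 2% noise, 12
concentrations, triplicate) and serum-stability decay curves (t1/2 = 18 h,
5% proportional noise, the 0-24 h time grid, triplicate), fits both models,
and reports parameter-recovery statistics; a flat "stabilized oligo" series
demonstrates the censored lower-bound path.
"""

import json
import sys
from pathlib import Path

import numpy as np

from seqrs_kit import DecayCurve, fit_half_life
from seqrs_kit.protocols import (
    DECAY_GRID,
    HALF_LIFE_TRUE,
    KD_TRUE,
    half_life_recovery,
    kd_recovery,
)

OUT = Path("results/curves")


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    kd = kd_recovery(seed)
    print(f"K_d recovery (true {KD_TRUE:.0f} nM): noiseless rel. err "
          f"{kd['noiseless_rel_err']:.2e}; median rel. err over 100 noisy "
          f"curves {kd['median_rel_err']*100:.1f}%")

    hl = half_life_recovery(seed)
    print(f"half-life recovery (true {HALF_LIFE_TRUE:.0f} h): median rel. err "
          f"over 100 noisy curves {hl['median_rel_err']*100:.1f}%")
    flat = hl["flat_fit"]
    print(f"flat series (stabilized oligo analogue): censored={flat.censored}, "
          f"reported bound t1/2 > {flat.param:.0f} h")

    summary = {
        "kd_true_nM": KD_TRUE,
        "kd_noiseless_rel_err": kd["noiseless_rel_err"],
        "kd_median_rel_err": kd["median_rel_err"],
        "half_life_true_h": HALF_LIFE_TRUE,
        "half_life_median_rel_err": hl["median_rel_err"],
        "flat_series_censored_bound_h": hl["flat_fit"].param,
        "seed": seed,
    }
    with open(OUT / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"wrote {OUT}/summary.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
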