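"""Simulate the dual-flip-angle multi-echo FLASH protocol and re-estimate
the quantitative maps.

Checks the estimator round trip: noise-free acquisitions must invert back
to the generating R1/PD/R2* maps to numerical precision, and 1 % signal
noise should leave median relative errors at the few-percent level. Writes
the error table to results/map_estimation_errors.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from morphosynth.map_estimation import MultiEchoFlashSet, estimate_maps
from morphosynth.phantom import PhantomGeometry, build_phantom, make_b1_field, simulate_flash
from morphosynth.protocols import PDW_FLASH, T1W_FLASH

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def errors(maps, est):
    m = maps.mask
    rows = {}
    for name in ("r1", "pd", "r2s"):
        rel = np.abs(getattr(est, name)[m] - getattr(maps, name)[m]) / np.abs(
            getattr(maps, name)[m]
        )
        rows[name] = {"median_rel_err": float(np.nanmedian(rel)),
                      "max_rel_err": float(np.nanmax(rel))}
    return rows


def main():
    RESULTS.mkdir(exist_ok=True)
    geometry = PhantomGeometry.create((64, 64, 64))
    maps, _ = build_phantom(geometry, rng_seed=SEED)
    b1 = make_b1_field(geometry, amplitude=0.15, rng_seed=SEED + 1)

    records = []
    for label, sigma_frac in (("noise_free", 0.0), ("noise_1pct", 0.01)):
        clean = simulate_flash(maps, PDW_FLASH, b1)
        sigma = sigma_frac * float(clean[..., 0][maps.mask].mean())
        pdw = simulate_flash(maps, PDW_FLASH, b1, sigma, SEED + 2)
        t1w = simulate_flash(maps, T1W_FLASH, b1, sigma, SEED + 3)
        est, qc = estimate_maps(
            MultiEchoFlashSet(pdw, t1w, PDW_FLASH, T1W_FLASH, maps.mask), b1
        )
        for name, err in errors(maps, est).items():
            records.append({"condition": label, "map": name, **err,
                            "n_nonphysical": qc.n_nonphysical_e1,
                            "n_r2s_clipped": qc.n_negative_r2s_clipped})
    table = pd.DataFrame(records)
    table.to_csv(RESULTS / "map_estimation_errors.csv", index=False)
    print("map estimation round trip (B1-corrected, 8-echo, 6/21 deg):")
    print(table.to_string(index=False))
    nf = table[table.condition == "noise_free"]["max_rel_err"].max()
    print(f"\nnoise-free worst-case relative error: {nf:.2e} "
          "(exact inversion up to float precision)")


if __name__ == "__main__":
    main()
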