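"""Synthesise the four MPRAGE image types and tabulate tissue intensities.

From the phantom's quantitative maps, computes T1w({R1}), T1w({R1,PD}),
T1w({R1,R2*}) and T1w({R1,PD,R2*}) with the default contrast-optimised
protocol, and reports the mean intensity of each tissue in each image —
the raw material of every downstream contrast and morphometry effect.
Writes results/synthetic_intensities.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from morphosynth.mprage import synthesize_set
from morphosynth.phantom import LABELS, PhantomGeometry, build_phantom
from morphosynth.protocols import DEFAULT_MPRAGE

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    geometry = PhantomGeometry.create((64, 64, 64))
    maps, labels = build_phantom(geometry, rng_seed=SEED)
    images = synthesize_set(maps, DEFAULT_MPRAGE)

    rows = []
    for tag, img in images.items():
        for name, code in LABELS.items():
            if name == "background":
                continue
            rows.append({"modality": tag, "tissue": name,
                         "mean_intensity": float(np.nanmean(img.intensity[labels == code]))})
    table = pd.DataFrame(rows).pivot(index="tissue", columns="modality",
                                     values="mean_intensity")
    table.to_csv(RESULTS / "synthetic_intensities.csv")
    print(f"protocol: alpha={DEFAULT_MPRAGE.flip_deg} deg, ES={DEFAULT_MPRAGE.es_ms} ms, "
          f"TI={DEFAULT_MPRAGE.ti_ms} ms, tau={DEFAULT_MPRAGE.tau_ms} ms, "
          f"TR={DEFAULT_MPRAGE.tr_ms} ms, TE={DEFAULT_MPRAGE.te_ms} ms")
    print("\nmean tissue intensity by image type (arbitrary units):")
    print(table.round(4).to_string())
    print("\nnote the T1w polarity (WM > GM > CSF in the {R1} image), the "
          "GM-WM gap narrowing once PD is included, and the nucleus dimming "
          "once R2* is included.")


if __name__ == "__main__":
    main()
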