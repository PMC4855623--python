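"""Apparent morphometry of each image type: the confound made visible.

Segments the four synthetic images of the same anatomy (1 % within-tissue
heterogeneity, 2 mm intensity smoothing) and measures apparent GM volume,
slab thickness, and nucleus-region GM voxels. Because the underlying
anatomy is identical, every between-modality difference is spurious —
contrast masquerading as morphology. Also regresses the site-wise
thickness change on the contrast change between T1w({R1}) and
T1w({R1,PD}). Writes results/morphometry_by_modality.csv and
results/thickness_contrast_regression.json.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from morphosynth.contrast import compute_contrast, regress_delta, sample_boundary
from morphosynth.morphometry import classify_and_measure, measure_slab_thickness
from morphosynth.mprage import synthesize_set
from morphosynth.phantom import LABELS, PhantomGeometry, build_phantom
from morphosynth.protocols import DEFAULT_MPRAGE

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    geometry = PhantomGeometry.create((64, 64, 64))
    maps, labels = build_phantom(geometry, rng_seed=SEED, heterogeneity_sigma=0.01)
    images = synthesize_set(maps, DEFAULT_MPRAGE)
    nucleus_zone = ndimage.binary_dilation(labels == LABELS["nucleus_gm"], iterations=2)

    rows = []
    thickness = {}
    for tag, img in images.items():
        report = classify_and_measure(img, maps.mask, smooth_fwhm_mm=2.0,
                                      rng_seed=SEED)
        th, missing = measure_slab_thickness(report.label_volume, geometry)
        thickness[tag] = np.asarray(th)
        rows.append({
            "modality": tag,
            "gm_volume_mm3": report.gm_volume_mm3,
            "wm_volume_mm3": report.wm_volume_mm3,
            "csf_volume_mm3": report.csf_volume_mm3,
            "mean_thickness_mm": float(np.nanmean(th)),
            "nucleus_zone_gm_voxels": int(((report.label_volume == 2)
                                           & nucleus_zone).sum()),
            "n_thickness_missing": missing,
        })
    table = pd.DataFrame(rows).set_index("modality")
    table.to_csv(RESULTS / "morphometry_by_modality.csv")
    print("apparent morphometry by image type (identical anatomy underneath):")
    print(table.round(2).to_string())
    print("\ndirections: GM volume and slab thickness fall when PD enters the "
          "signal; nucleus-region GM appears once R2* enters.")

    # thickness change regressed on contrast change across boundary sites
    s_r1, _ = sample_boundary(images["r1"], labels, geometry)
    s_r1pd, _ = sample_boundary(images["r1pd"], labels, geometry)
    ids = [s.location_id for s in s_r1]
    dC = np.array([compute_contrast(a) - compute_contrast(b)
                   for a, b in zip(s_r1, s_r1pd)])
    dCt = (thickness["r1"] - thickness["r1pd"])[ids]
    keep = np.isfinite(dCt)
    res = regress_delta(dCt[keep], dC[keep], smooth_fwhm_sites=15.0)
    payload = {"beta_mm_per_contrast_unit": res.beta, "t_value": res.t_value,
               "n_sites": int(keep.sum())}
    (RESULTS / "thickness_contrast_regression.json").write_text(
        json.dumps(payload, indent=2) + "\n"
    )
    print("\nthickness change vs contrast change (no-intercept, "
          "15-site FWHM smoothing):")
    print(f"  beta = {res.beta:.3f} mm per contrast unit, t = {res.t_value:.1f} "
          f"over {int(keep.sum())} sites (positive: losing contrast loses "
          "apparent thickness)")


if __name__ == "__main__":
    main()
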