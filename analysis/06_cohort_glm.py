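"""Ageing cohorts and the modality-by-age interaction.

Generates two 40-subject cohorts (ages 18-78): one whose cortical proton
density rises with age (emulating age-related fibre-density reduction) and
one without any PD trend. For each subject the T1w({R1}) and T1w({R1,PD})
images are segmented and apparent GM volume extracted; a GLM with modality
indicators, centred age and a modality-by-age interaction then asks
whether the apparent ageing trajectory depends on which parameters entered
the signal equation. Writes results/cohort_volumes_{label}.csv and
results/cohort_glm.json.
"""

import json
import sys
from pathlib import Path

from morphosynth.glm import build_design, fit_glm
from morphosynth.phantom import (
    CohortSpec,
    DEFAULT_GM_PD_AGE_SLOPE,
    PhantomGeometry,
    generate_cohort,
)
from morphosynth.pipeline import cohort_modality_volumes
from morphosynth.protocols import DEFAULT_MPRAGE

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    RESULTS.mkdir(exist_ok=True)
    geometry = PhantomGeometry.create((64, 64, 64))
    out = {}
    for label, slopes in (
        ("with_pd_trend", {"cortical_gm": {"pd": DEFAULT_GM_PD_AGE_SLOPE},
                           "sensorimotor_gm": {"pd": DEFAULT_GM_PD_AGE_SLOPE}}),
        ("without_trend", {}),
    ):
        spec = CohortSpec(n_subjects=40, linear_slopes=slopes, rng_seed=SEED + 20)
        subjects, _ = generate_cohort(spec, geometry)
        volumes = cohort_modality_volumes(subjects, geometry, DEFAULT_MPRAGE,
                                          rng_seed=SEED)
        volumes.to_csv(RESULTS / f"cohort_volumes_{label}.csv", index=False)
        design = build_design(volumes, ("modality", "age", "modality:age"))
        res = fit_glm(design, volumes["gm_volume_mm3"].to_numpy()[None, :],
                      {"modality[r1pd]:age_c": -1.0})
        out[label] = {"t": float(res.t[0]), "p_one_tailed": float(res.p_one_tailed[0]),
                      "dof": res.dof, "n_obs": len(volumes)}
        print(f"{label}: interaction t = {out[label]['t']:.2f}, "
              f"one-tailed p = {out[label]['p_one_tailed']:.2e} "
              f"({spec.n_subjects} subjects x 2 image types)")
    (RESULTS / "cohort_glm.json").write_text(json.dumps(out, indent=2) + "\n")
    print("\na PD ageing trend makes the apparent GM-volume decline steeper in "
          "the PD-including image; without the trend the two image types age "
          "in parallel. The anatomy's true geometry is identical throughout.")


if __name__ == "__main__":
    main()
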