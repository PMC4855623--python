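# morphosynth

Microstructural tissue properties leave fingerprints in T1-weighted MRI
contrast — and therefore in every morphometric measure derived from it.
`morphosynth` simulates this confound end to end: it synthesises MPRAGE
T1-weighted images from quantitative R1 / PD / R2\* maps with each
parameter's contribution individually removable, and then measures how much
*apparent* gray-matter volume and cortical thickness change when nothing
about the anatomy has changed at all.

It is aimed at researchers in quantitative MRI and computational anatomy
who want a controlled, fully synthetic testbed for contrast-driven
morphometry artefacts: every effect is measured on a labelled brain phantom
whose ground truth is known exactly.

## The model

The steady-state MPRAGE signal, read at the centre of the excitation
train, factorises into per-parameter contributions:

```
S = sin(α) · f_R1(R1) · f_PD(PD) · f_R2*(R2*)

f_PD  = PD
f_R2* = exp(−TE·R2*)
f_R1  = [E4·(1 − 2E1 + E1E2) + T1*R1·(1 + E1E2E3 − E4 − E4E1E2)] / (1 + E1E2E3)
```

with `1/T1* = R1 − ln(cos α)/ES`, `E1 = exp(−TI·R1)`, `E2 = exp(−TD·R1)`,
`E3 = exp(−τ/T1*)`, `E4 = exp(−τ/(2T1*))`. Setting a factor to 1 removes
that parameter from the image, giving four image types: T1w(R1),
T1w(R1,PD), T1w(R1,R2\*), T1w(R1,PD,R2\*). The closed form is verified
against an independent discrete Bloch pulse-train simulator (agreement
better than 1 % at the default protocol: α = 9°, ES = 9.9 ms, TI = 960 ms,
τ = 176·ES, TR = 2420 ms).

Around this core the package provides:

- **`map_estimation`** — R1/PD from dual-flip-angle FLASH via the exact
  two-point linearisation of the Ernst equation (`S/sin α = E1·S/tan α +
  PD(1−E1)`), R2\* from the log-linear multi-echo fit, optional B1
  correction. Noise-free simulated acquisitions round-trip to the
  generating maps at float precision.
- **`phantom`** — a labelled digital phantom (WM core, cortical GM shell
  with a sensorimotor-like high-R1 subregion, iron-rich deep nuclei, CSF),
  the FLASH forward model, smooth B1 bias fields, and a multi-subject
  ageing-cohort generator.
- **`contrast`** — gray–white contrast `C = (WM−GM)/((WM+GM)/2)` sampled
  1 mm below / 35 % above the GM–WM border, plus the closed-form
  prediction of the contrast change caused by PD,
  `ΔC = 4·R_T1w(R1)·(R_PD−1) / ((1+R_T1w(R1))(1+R_PD·R_T1w(R1)))`.
- **`morphometry`** — a desk-scale VBM/surface stand-in: EM-fitted
  Gaussian-mixture tissue classification, apparent class volumes, and slab
  cortical thickness.
- **`glm`** — mass-univariate OLS with modality indicators, mean-centred
  (and squared-centred) age, sex and interactions; one-tailed t-tests and
  Bonferroni control.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
64³, 1 mm phantom (`python analysis/01_build_phantom.py`, … `06_cohort_glm.py`;
each takes an optional seed argument and writes tables under `results/`).
Step 5 prints the central result — the same anatomy, segmented from the
four image types:

```
apparent morphometry by image type (identical anatomy underneath):
          gm_volume_mm3  wm_volume_mm3  csf_volume_mm3  mean_thickness_mm  nucleus_zone_gm_voxels
modality
r1              79433.0        34118.0         81561.0               7.67                       0
r1pd            75367.0        38182.0         81563.0               6.14                       0
r1r2s           79826.0        33722.0         81564.0               7.67                     396
r1pdr2s         75778.0        37769.0         81565.0               6.12                     509
```

Including PD in the signal equation costs ~4000 mm³ of apparent gray
matter and ~1.5 mm of apparent cortical thickness; including R2\* makes
the iron-rich nuclei emerge as gray matter. None of this is anatomy — the
label volume underneath is identical in every row. Step 4 shows the
mechanism: the measured cortical contrast change due to PD (0.1803)
matches the closed-form prediction from the two GM/WM ratios
(R_PD = 1.203, R_T1w(R1) = 0.670) to machine precision. Step 6 injects an
ageing trend into cortical PD only and recovers a significant
modality-by-age interaction on apparent GM volume (t = 4.14,
p = 4.5·10⁻⁵, 40 subjects), while a trend-free cohort shows none
(t = 1.00) — an apparent "differential ageing" produced purely by image
contrast.

A `morphosynth` CLI wraps the same stages
(`morphosynth run-all --seed 0 --out-dir out/` chains phantom → map
fitting → synthesis → contrast → morphometry → GLM and writes a checksummed
manifest; identical seeds give bit-identical outputs).

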