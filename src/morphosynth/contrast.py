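"""Gray-white matter contrast analysis.

Contrast at a boundary site is the normalised intensity difference

    C = (WM - GM) / ((WM + GM) / 2),

positive when WM is brighter than GM (the usual T1w polarity). Because the
synthetic image types differ only by multiplicative per-parameter factors,
the change in C between the {R1} image and the {R1,PD} image is a closed
function of two GM/WM ratios: R_PD (ratio of proton density) and
R_T1w(R1) (ratio of the {R1} image intensity). Two algebraic forms of that
prediction are provided (see :func:`predict_contrast_change`), and a
no-intercept regression links thickness changes to contrast changes
across sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .mprage import SyntheticImage
from .phantom import PhantomGeometry

__all__ = [
    "ContrastSample",
    "ContrastRatios",
    "ContrastRegressionResult",
    "compute_contrast",
    "sample_boundary",
    "predict_contrast_change",
    "regress_delta",
    "fwhm_to_sigma",
]


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian full-width-at-half-maximum to standard deviation."""
    return fwhm / np.sqrt(8.0 * np.log(2.0))


@dataclass(frozen=True)
class ContrastSample:
    """Paired WM/GM intensities at one gray-white boundary site."""

    wm_intensity: float
    gm_intensity: float
    location_id: int

    def __post_init__(self) -> None:
        if not (self.wm_intensity > 0 and self.gm_intensity > 0):
            raise ValueError("boundary intensities must be positive")


@dataclass(frozen=True)
class ContrastRatios:
    """GM/WM ratios entering the analytic contrast-change prediction."""

    r_pd: float
    r_t1w_r1: float

    def __post_init__(self) -> None:
        if not (self.r_pd > 0 and self.r_t1w_r1 > 0):
            raise ValueError("ratios must be positive")


@dataclass(frozen=True)
class ContrastRegressionResult:
    """No-intercept OLS of thickness change on contrast change."""

    beta: float
    t_value: float
    residuals: np.ndarray
    zero_residual_variance: bool = False


def compute_contrast(sample: ContrastSample) -> float:
    """Normalised WM-GM contrast; lies in (-2, 2), positive iff WM > GM."""
    wm, gm = sample.wm_intensity, sample.gm_intensity
    return (wm - gm) / ((wm + gm) / 2.0)


def sample_boundary(
    image: SyntheticImage,
    labels: np.ndarray,
    geometry: PhantomGeometry,
    depth_fraction: float = 0.35,
    wm_offset_mm: float = 1.0,
) -> tuple[list[ContrastSample], int]:
    """Sample paired WM/GM intensities at every slab boundary site.

    For each column crossing the planar GM-WM border, the WM intensity is
    taken ``wm_offset_mm`` inside WM along the border normal and the GM
    intensity at ``depth_fraction`` of the local GM run length from the
    border (nearest voxel, ``round``, at least one voxel deep). Sites with
    no GM voxel above the border, or without room for the WM sample, are
    skipped and counted.

    Returns (samples, n_skipped).
    """
    labels = np.asarray(labels)
    if labels.shape != image.intensity.shape:
        raise ValueError("label volume and image grids differ")
    gm_codes = geometry.gm_label_codes
    wm_code = geometry.wm_label
    border_z = geometry.slab_border_z
    wm_off = max(1, round(wm_offset_mm / geometry.voxel_size_mm))

    samples: list[ContrastSample] = []
    n_skipped = 0
    for site_id, (x, y) in enumerate(geometry.slab_columns()):
        wm_z = border_z - wm_off
        if wm_z < 0 or labels[x, y, wm_z] != wm_code:
            n_skipped += 1
            continue
        # contiguous GM run upward from the border along the normal (+z)
        z = border_z
        while z < labels.shape[2] and labels[x, y, z] in gm_codes:
            z += 1
        thickness_vox = z - border_z
        if thickness_vox < 1:
            n_skipped += 1
            continue
        depth = max(1, round(depth_fraction * thickness_vox))
        gm_z = border_z + depth - 1
        wm_int = float(image.intensity[x, y, wm_z])
        gm_int = float(image.intensity[x, y, gm_z])
        if not (np.isfinite(wm_int) and np.isfinite(gm_int)) or wm_int <= 0 or gm_int <= 0:
            n_skipped += 1
            continue
        samples.append(ContrastSample(wm_intensity=wm_int, gm_intensity=gm_int, location_id=site_id))
    return samples, n_skipped


def predict_contrast_change(ratios: ContrastRatios, form: str = "derived") -> float:
    """Analytic contrast change C({R1}) - C({R1,PD}) from the GM/WM ratios.

    ``form="derived"`` evaluates the exact algebraic consequence of the
    contrast definition applied to the two image types,

        dC = 4 R_T1 (R_PD - 1) / ((1 + R_T1)(1 + R_PD R_T1)),

    which matches the brute-force pipeline difference to machine precision.
    ``form="printed"`` evaluates the alternative closed form

        dC = 4 (R_PD - 1) R_T1 / ((1 + R_PD)(1 + R_T1)),

    which agrees with it in sign and at the R_PD = 1 zero but differs in
    magnitude away from R_PD = 1; both are retained deliberately.
    """
    rpd, rt1 = ratios.r_pd, ratios.r_t1w_r1
    if form == "derived":
        return 4.0 * rt1 * (rpd - 1.0) / ((1.0 + rt1) * (1.0 + rpd * rt1))
    if form == "printed":
        return 4.0 * (rpd - 1.0) * rt1 / ((1.0 + rpd) * (1.0 + rt1))
    raise ValueError(f"form must be 'printed' or 'derived', got {form!r}")


def regress_delta(
    delta_thickness: Sequence[float],
    delta_contrast: Sequence[float],
    smooth_fwhm_sites: float | None = None,
) -> ContrastRegressionResult:
    """No-intercept OLS of thickness change on contrast change across sites.

    beta = sum(x*y) / sum(x^2); t = beta / SE with the usual single-regressor
    no-intercept variance, n - 1 degrees of freedom. If ``smooth_fwhm_sites``
    is given, both vectors are first smoothed with a 1-D Gaussian along the
    site ordering (an analogue of surface smoothing for ordered phantom
    sites). A perfect fit yields zero residuals and an infinite-t sentinel
    with ``zero_residual_variance`` set.
    """
    y = np.asarray(delta_thickness, dtype=float)
    x = np.asarray(delta_contrast, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if y.size < 2:
        raise ValueError("at least two sites are required")
    if smooth_fwhm_sites:
        sigma = fwhm_to_sigma(smooth_fwhm_sites)
        y = ndimage.gaussian_filter1d(y, sigma)
        x = ndimage.gaussian_filter1d(x, sigma)
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all-zero contrast change: slope undefined")
    beta = float(np.dot(x, y)) / sxx
    resid = y - beta * x
    dof = y.size - 1
    sigma2 = float(np.dot(resid, resid)) / dof
    if sigma2 == 0.0:
        return ContrastRegressionResult(beta=beta, t_value=np.inf, residuals=resid,
                                        zero_residual_variance=True)
    t = beta / np.sqrt(sigma2 / sxx)
    return ContrastRegressionResult(beta=beta, t_value=float(t), residuals=resid)
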