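"""Synthetic brain phantom: ground-truth maps, simulated acquisitions, cohort.

The phantom is a labelled 3-D volume with the tissue classes whose contrast
regimes matter for T1w morphometry: a white-matter core, a flat cortical
gray-matter slab with a planar GM-WM border of known normal (+z), a
"sensorimotor-like" GM subregion (high R1, PD close to WM), two iron-rich
deep-nucleus blobs embedded in WM (high R2*), and a CSF rim. Per-tissue R1,
PD and R2* values populate ground-truth quantitative maps; a spoiled
gradient-echo forward model simulates the dual-flip-angle multi-echo FLASH
acquisitions from which the maps can be re-estimated; and a cohort
generator draws subjects whose tissue parameters drift with age.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

from .map_estimation import B1Map, QuantitativeMaps
from .protocols import FlashProtocol

__all__ = [
    "LABELS",
    "TissueParams",
    "TissueParameterTable",
    "DEFAULT_TISSUES",
    "PhantomGeometry",
    "CohortSpec",
    "Subject",
    "build_phantom",
    "simulate_flash",
    "flash_signal",
    "make_b1_field",
    "generate_cohort",
    "DEFAULT_GM_PD_AGE_SLOPE",
    "DEFAULT_GM_R1_AGE_SLOPE",
]

#: Integer label codes of the phantom volume.
LABELS = {
    "background": 0,
    "wm": 1,
    "cortical_gm": 2,
    "sensorimotor_gm": 3,
    "nucleus_gm": 4,
    "csf": 5,
}


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue quantitative parameters: r1 and r2s in 1/s, pd dimensionless."""

    r1: float
    pd: float
    r2s: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.pd > 0 and self.r2s > 0):
            raise ValueError("tissue parameters must be positive")


class TissueParameterTable(dict):
    """Mapping tissue name -> :class:`TissueParams`.

    Must contain every non-background phantom class; CSF must carry the
    maximum proton density (it anchors the PD normalisation, free water = 1).
    """

    REQUIRED = ("wm", "cortical_gm", "sensorimotor_gm", "nucleus_gm", "csf")

    def __init__(self, values: Mapping[str, TissueParams]):
        super().__init__(values)
        missing = [k for k in self.REQUIRED if k not in self]
        if missing:
            raise ValueError(f"tissue table is missing classes: {missing}")
        pd_max = max(v.pd for v in self.values())
        if self["csf"].pd < pd_max:
            raise ValueError("CSF must have the maximum proton density")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: {"r1": t.r1, "pd": t.pd, "r2s": t.r2s} for name, t in self.items()}
        ).T.rename_axis("tissue")

    def to_dict(self) -> dict:
        return {name: {"r1": t.r1, "pd": t.pd, "r2s": t.r2s} for name, t in self.items()}

    @classmethod
    def from_dict(cls, raw: Mapping[str, Mapping[str, float]]) -> "TissueParameterTable":
        return cls({name: TissueParams(**vals) for name, vals in raw.items()})


#: 3 T order-of-magnitude tissue values giving the contrast regimes of
#: interest (early-myelinating cortex with high R1 and a PD ratio close to
#: 1; iron-rich nuclei with high R2*). Chosen constants, configurable.
DEFAULT_TISSUES = TissueParameterTable(
    {
        "wm": TissueParams(r1=1.05, pd=0.69, r2s=21.0),
        "cortical_gm": TissueParams(r1=0.72, pd=0.83, r2s=16.0),
        "sensorimotor_gm": TissueParams(r1=0.85, pd=0.78, r2s=16.0),
        "nucleus_gm": TissueParams(r1=0.95, pd=0.75, r2s=55.0),
        "csf": TissueParams(r1=0.24, pd=1.0, r2s=1.0),
    }
)


@dataclass(frozen=True)
class PhantomGeometry:
    """Voxel layout of the phantom regions.

    The gray-matter shell wraps the WM core on every face (as cortex wraps
    white matter — the phantom has no WM-CSF interface). Its top face is a
    flat slab whose GM-WM border lies in the plane ``z = slab_border_z``
    with normal +z (GM occupies z >= border); the lower-x part of that face
    is the sensorimotor-like subregion. Two spherical iron-rich nuclei are
    embedded in the WM core. A thin CSF rim surrounds the shell on the
    sides and bottom, and a deep CSF pool sits above the slab so the outer
    cortical boundary is measurable. Everything outside the CSF is
    unmasked background.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    wm_xy_margin: int = 14
    wm_z0: int = 14
    slab_border_z: int = 40
    gm_thickness: int = 8
    csf_rim: int = 3
    nucleus_radius: int = 5
    sensorimotor_fraction: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        if min(self.shape) < 24:
            raise ValueError("phantom grid must be at least 24 voxels per axis")
        inner = self.wm_xy_margin - self.gm_thickness - self.csf_rim
        if inner < 1:
            raise ValueError("GM shell + CSF rim do not fit inside the grid")
        if not (self.gm_thickness + self.csf_rim < self.wm_z0 < self.slab_border_z):
            raise ValueError("WM core z-extent inconsistent")
        if self.slab_border_z + self.gm_thickness + self.csf_rim >= nz:
            raise ValueError("slab + CSF pool do not fit above the WM core")
        for cx, cy, cz in self.nucleus_centers():
            r = self.nucleus_radius
            if not (
                self.wm_xy_margin < cx - r and cx + r < nx - self.wm_xy_margin
                and self.wm_xy_margin < cy - r and cy + r < ny - self.wm_xy_margin
                and self.wm_z0 < cz - r and cz + r < self.slab_border_z
            ):
                raise ValueError("nuclei do not fit inside the WM core (overlapping regions)")

    @classmethod
    def create(
        cls, shape: tuple[int, int, int] = (64, 64, 64), voxel_size_mm: float = 1.0, **kw
    ) -> "PhantomGeometry":
        """Geometry with region extents scaled proportionally to ``shape``."""
        nx, ny, nz = shape
        s = min(shape) / 64.0
        defaults = dict(
            wm_xy_margin=max(6, round(14 * s)),
            wm_z0=max(6, round(14 * nz / 64)),
            slab_border_z=round(40 * nz / 64),
            gm_thickness=max(3, round(8 * nz / 64)),
            csf_rim=max(2, round(3 * s)),
            nucleus_radius=max(2, round(5 * s)),
        )
        defaults.update(kw)
        return cls(shape=shape, voxel_size_mm=voxel_size_mm, **defaults)

    # ---- derived masks -------------------------------------------------

    @property
    def wm_label(self) -> int:
        return LABELS["wm"]

    @property
    def gm_label_codes(self) -> frozenset[int]:
        return frozenset({LABELS["cortical_gm"], LABELS["sensorimotor_gm"], LABELS["nucleus_gm"]})

    @property
    def slab_top_z(self) -> int:
        return self.slab_border_z + self.gm_thickness

    @property
    def sensorimotor_x_end(self) -> int:
        nx = self.shape[0]
        width = nx - 2 * self.wm_xy_margin
        return self.wm_xy_margin + round(self.sensorimotor_fraction * width)

    def nucleus_centers(self) -> list[tuple[int, int, int]]:
        nx, ny, _ = self.shape
        cz = (self.wm_z0 + self.slab_border_z) // 2
        off = max(self.nucleus_radius + 2, (nx - 2 * self.wm_xy_margin) // 4)
        return [(nx // 2 - off, ny // 2, cz), (nx // 2 + off, ny // 2, cz)]

    def label_volume(self) -> np.ndarray:
        nx, ny, nz = self.shape
        labels = np.zeros(self.shape, dtype=np.int16)
        g, c = self.gm_thickness, self.csf_rim
        m = self.wm_xy_margin
        # CSF box: thin rim at sides/bottom, deep pool above the slab
        labels[m - g - c:nx - (m - g - c), m - g - c:ny - (m - g - c),
               self.wm_z0 - g - c:nz - c] = LABELS["csf"]
        # GM shell around the WM core
        labels[m - g:nx - (m - g), m - g:ny - (m - g),
               self.wm_z0 - g:self.slab_top_z] = LABELS["cortical_gm"]
        labels[m - g:self.sensorimotor_x_end, m - g:ny - (m - g),
               self.slab_border_z:self.slab_top_z] = LABELS["sensorimotor_gm"]
        labels[m:nx - m, m:ny - m, self.wm_z0:self.slab_border_z] = LABELS["wm"]
        xx, yy, zz = np.meshgrid(*(np.arange(n) for n in self.shape), indexing="ij")
        for cx, cy, cz in self.nucleus_centers():
            sphere = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2 <= self.nucleus_radius ** 2
            if np.any(labels[sphere] != LABELS["wm"]):
                raise ValueError("nucleus overlaps a non-WM region")
            labels[sphere] = LABELS["nucleus_gm"]
        return labels

    def slab_columns(self) -> Iterator[tuple[int, int]]:
        """(x, y) indices of every column crossing the planar GM-WM border."""
        nx, ny, _ = self.shape
        m = self.wm_xy_margin
        for x in range(m, nx - m):
            for y in range(m, ny - m):
                yield (x, y)

    def column_is_sensorimotor(self, x: int, y: int) -> bool:
        return x < self.sensorimotor_x_end

    def region_mask(self, *names: str) -> np.ndarray:
        """Boolean mask of the union of the named label classes."""
        labels = self.label_volume()
        out = np.zeros(self.shape, dtype=bool)
        for name in names:
            out |= labels == LABELS[name]
        return out


def build_phantom(
    geometry: PhantomGeometry,
    tissues: TissueParameterTable = DEFAULT_TISSUES,
    rng_seed: int = 0,
    heterogeneity_sigma: float = 0.0,
) -> tuple[QuantitativeMaps, np.ndarray]:
    """Ground-truth quantitative maps and label volume.

    ``heterogeneity_sigma`` adds within-tissue Gaussian variability as a
    fraction of each tissue's parameter value (0 gives exactly piecewise-
    constant maps). Deterministic given ``rng_seed``.
    """
    labels = geometry.label_volume()
    mask = labels > 0
    rng = np.random.default_rng(rng_seed)

    maps = {}
    for param in ("r1", "pd", "r2s"):
        vol = np.full(geometry.shape, np.nan)
        for name, code in LABELS.items():
            if name == "background":
                continue
            base = getattr(tissues[name], param)
            region = labels == code
            values = np.full(int(region.sum()), float(base))
            if heterogeneity_sigma > 0:
                values *= 1.0 + heterogeneity_sigma * rng.standard_normal(values.size)
                values = np.clip(values, 0.05 * base, None)
            vol[region] = values
        maps[param] = vol
    qmaps = QuantitativeMaps(r1=maps["r1"], pd=maps["pd"], r2s=maps["r2s"], mask=mask)
    return qmaps, labels


def flash_signal(r1_per_s, pd, r2s_per_s, te_ms, tr_ms, flip_rad):
    """Spoiled gradient-echo steady-state signal (Ernst equation) at one echo."""
    e1 = np.exp(-np.asarray(tr_ms) * np.asarray(r1_per_s) / 1000.0)
    ernst = np.sin(flip_rad) * (1.0 - e1) / (1.0 - np.cos(flip_rad) * e1)
    return pd * ernst * np.exp(-np.asarray(te_ms) * np.asarray(r2s_per_s) / 1000.0)


def simulate_flash(
    maps: QuantitativeMaps,
    protocol: FlashProtocol,
    b1: Optional[B1Map] = None,
    noise_sigma: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Forward-simulate one multi-echo FLASH stack from quantitative maps.

    Returns a 4-D array (x, y, z, echo). The steady-state amplitude follows
    the Ernst equation at the local effective flip angle (nominal times the
    B1 factor when given) and each echo decays by ``exp(-TE * R2*)``.
    Additive Gaussian noise of standard deviation ``noise_sigma`` (signal
    units) is drawn independently per voxel and echo; voxels outside the
    mask carry pure noise. Deterministic given ``rng_seed``.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    shape = maps.shape
    factor = np.ones(shape) if b1 is None else b1.relative_flip_factor
    alpha = protocol.flip_rad * factor

    stack = np.zeros(shape + (protocol.n_echoes,))
    inside = maps.mask
    with np.errstate(invalid="ignore"):
        for j, te in enumerate(protocol.te_ms):
            sig = flash_signal(maps.r1, maps.pd, maps.r2s, te, protocol.tr_ms, alpha)
            stack[..., j] = np.where(inside, sig, 0.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(rng_seed)
        stack = stack + noise_sigma * rng.standard_normal(stack.shape)
    return stack


def make_b1_field(
    geometry: PhantomGeometry, amplitude: float, rng_seed: int = 0
) -> B1Map:
    """Smooth multiplicative transmit-bias field in [1 - amplitude, 1 + amplitude].

    A separable raised-cosine bump centred near the volume middle (centre
    jittered by up to 5 % of each extent, drawn from ``rng_seed``): the
    factor is 1 + amplitude at the bump centre and falls smoothly towards
    1 - amplitude at the corners.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    rng = np.random.default_rng(rng_seed)
    profile = []
    for n in geometry.shape:
        center = (n - 1) / 2.0 + rng.uniform(-0.05, 0.05) * n
        half_width = max(center, (n - 1) - center)  # keeps |arg| <= pi/2
        x = np.arange(n)
        profile.append(np.cos((x - center) / half_width * (np.pi / 2.0)))
    bump = profile[0][:, None, None] * profile[1][None, :, None] * profile[2][None, None, :]
    field = 1.0 - amplitude + 2.0 * amplitude * np.clip(bump, 0.0, 1.0)
    return B1Map(relative_flip_factor=field)


def three_class_labels(labels: np.ndarray) -> np.ndarray:
    """Collapse phantom labels to the classifier's scheme: 1=CSF, 2=GM, 3=WM.

    All gray-matter subclasses (cortical, sensorimotor, nucleus) map to 2;
    background stays 0.
    """
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int16)
    out[labels == LABELS["csf"]] = 1
    for name in ("cortical_gm", "sensorimotor_gm", "nucleus_gm"):
        out[labels == LABELS[name]] = 2
    out[labels == LABELS["wm"]] = 3
    return out


# Cohort ---------------------------------------------------------------

#: Default age slope of cortical/sensorimotor GM proton density, absolute
#: PD units per year: positive, because age-related density reduction of
#: myelinated fibres raises the free-water content (about +0.12 %/year of
#: the GM value, in the range of reported water-content ageing effects).
DEFAULT_GM_PD_AGE_SLOPE = 1.0e-3

#: Default age slope of cortical GM R1, 1/s per year (about -0.14 %/year).
DEFAULT_GM_R1_AGE_SLOPE = -1.0e-3


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated multi-subject cohort.

    ``linear_slopes`` / ``quadratic_slopes`` map tissue name -> parameter
    name -> absolute change per year (per year squared) applied around the
    cohort's mean age. ``between_subject_sigma`` is the relative standard
    deviation of per-subject parameter jitter. All draws are reproducible
    from ``rng_seed``.
    """

    n_subjects: int = 40
    age_range: tuple[float, float] = (18.0, 78.0)
    linear_slopes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    quadratic_slopes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    between_subject_sigma: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least two subjects")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        if self.between_subject_sigma < 0:
            raise ValueError("between_subject_sigma must be >= 0")


@dataclass(frozen=True)
class Subject:
    """One simulated participant with ground-truth maps and parameters."""

    subject_id: int
    age: float
    sex: str
    tissues: TissueParameterTable
    maps: QuantitativeMaps
    labels: np.ndarray


def generate_cohort(
    spec: CohortSpec,
    geometry: PhantomGeometry,
    tissues: TissueParameterTable = DEFAULT_TISSUES,
) -> tuple[list[Subject], pd.DataFrame]:
    """Draw a cohort of phantoms whose tissue parameters drift with age.

    Subject i's parameter is ``base + lin * (age - mean_age) +
    quad * (age - mean_age)^2 + base * sigma * eps`` with standard-normal
    eps; mean_age is the sample mean of the drawn ages. Returns the
    subjects and a tidy ground-truth table (one row per subject, tissue
    and parameter) for recovery tests.
    """
    rng = np.random.default_rng(spec.rng_seed)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    sexes = rng.choice(["F", "M"], size=spec.n_subjects)
    mean_age = float(ages.mean())
    map_seeds = rng.integers(0, 2**31 - 1, size=spec.n_subjects)

    subjects: list[Subject] = []
    truth_rows = []
    for i in range(spec.n_subjects):
        dev = ages[i] - mean_age
        subj_tissues = {}
        for name, base in tissues.items():
            vals = {}
            for param in ("r1", "pd", "r2s"):
                v = getattr(base, param)
                v += spec.linear_slopes.get(name, {}).get(param, 0.0) * dev
                v += spec.quadratic_slopes.get(name, {}).get(param, 0.0) * dev**2
                if spec.between_subject_sigma > 0:
                    v += getattr(base, param) * spec.between_subject_sigma * rng.standard_normal()
                vals[param] = max(v, 0.01 * getattr(base, param))
                truth_rows.append(
                    {"subject_id": i, "age": ages[i], "sex": sexes[i],
                     "tissue": name, "param": param, "value": vals[param]}
                )
            subj_tissues[name] = TissueParams(**vals)
        maps, labels = build_phantom(
            geometry, TissueParameterTable(subj_tissues), rng_seed=int(map_seeds[i])
        )
        subjects.append(
            Subject(subject_id=i, age=float(ages[i]), sex=str(sexes[i]),
                    tissues=TissueParameterTable(subj_tissues), maps=maps, labels=labels)
        )
    truth = pd.DataFrame(truth_rows)
    return subjects, truth
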