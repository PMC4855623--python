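"""Synthetic MPRAGE T1-weighted images from quantitative maps.

The steady-state signal of an inversion-prepared rapid gradient-echo cycle,
read at the centre of the excitation train, factorises into three
per-parameter contributions:

    S = sin(alpha) * f_R1(R1) * f_PD(PD) * f_R2s(R2*)

    f_PD  = PD
    f_R2s = exp(-TE * R2*)
    f_R1  = [E4 * (1 - 2 E1 + E1 E2)
             + T1* R1 * (1 + E1 E2 E3 - E4 - E4 E1 E2)] / (1 + E1 E2 E3)

with the apparent relaxation time during the train
``1/T1* = R1 - ln(cos alpha)/ES`` and the recovery factors
``E1 = exp(-TI*R1)`` (inversion to readout start), ``E2 = exp(-TD*R1)``,
``E3 = exp(-tau/T1*)``, ``E4 = exp(-tau/(2 T1*))``.

Each contribution can be removed from a synthetic image by literally
replacing its factor by 1, which yields four image types indexed by the
parameter subsets {R1}, {R1,PD}, {R1,R2*} and {R1,PD,R2*}. Comparing
morphometry across these images isolates how much apparent anatomy each
microstructural parameter contributes to T1-weighted contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .map_estimation import PER_SECOND_PER_MS, QuantitativeMaps
from .protocols import MprageProtocol

__all__ = [
    "Modality",
    "MODALITIES",
    "MprageSignalTerms",
    "SyntheticImage",
    "signal_terms",
    "synthesize",
    "synthesize_set",
]

#: The four image types, as frozen parameter subsets. R1 is always present.
MODALITIES: tuple[frozenset[str], ...] = (
    frozenset({"R1"}),
    frozenset({"R1", "PD"}),
    frozenset({"R1", "R2s"}),
    frozenset({"R1", "PD", "R2s"}),
)

Modality = frozenset


def modality_tag(modality: frozenset[str]) -> str:
    """Stable short name, e.g. ``r1pd`` for {R1, PD}."""
    order = {"R1": 0, "PD": 1, "R2s": 2}
    return "".join(p.lower() for p in sorted(modality, key=order.__getitem__))


def parse_modality(tag: str) -> frozenset[str]:
    """Inverse of :func:`modality_tag` (case-insensitive, accepts 'r2*')."""
    t = tag.lower().replace("*", "s").replace("_", "").replace(",", "")
    for m in MODALITIES:
        if modality_tag(m) == t:
            return m
    raise ValueError(f"unknown modality tag {tag!r}")


@dataclass(frozen=True)
class MprageSignalTerms:
    """Intermediate quantities of the signal equation (times in ms)."""

    t1_star_ms: np.ndarray | float
    e1: np.ndarray | float
    e2: np.ndarray | float
    e3: np.ndarray | float
    e4: np.ndarray | float
    f_r1: np.ndarray | float


@dataclass(frozen=True)
class SyntheticImage:
    """One synthetic T1w volume tagged with the parameter subset behind it."""

    intensity: np.ndarray
    modality: frozenset[str]
    protocol: MprageProtocol

    @property
    def tag(self) -> str:
        return modality_tag(self.modality)


def signal_terms(r1_per_s, protocol: MprageProtocol) -> MprageSignalTerms:
    """Evaluate T1*, the recovery factors E1..E4 and the R1 factor f_R1.

    ``r1_per_s`` is a scalar or array in 1/s; non-positive entries give NaN.
    """
    r1 = np.asarray(r1_per_s, dtype=float) / PER_SECOND_PER_MS  # 1/ms
    scalar = r1.ndim == 0
    r1 = np.atleast_1d(r1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r1 = np.where(r1 > 0, r1, np.nan)
        log_cos = math.log(math.cos(protocol.flip_rad))
        r1_star = r1 - log_cos / protocol.es_ms  # 1/T1*, always > R1 > 0
        t1_star = 1.0 / r1_star
        tau = protocol.tau_ms
        e1 = np.exp(-protocol.ti_start_ms * r1)
        e2 = np.exp(-protocol.td_ms * r1)
        e3 = np.exp(-tau * r1_star)
        e4 = np.exp(-(tau / 2.0) * r1_star)
        denom = 1.0 + e1 * e2 * e3
        f_r1 = (
            e4 * (1.0 - 2.0 * e1 + e1 * e2)
            + t1_star * r1 * (1.0 + e1 * e2 * e3 - e4 - e4 * e1 * e2)
        ) / denom
    if scalar:
        return MprageSignalTerms(
            float(t1_star[0]), float(e1[0]), float(e2[0]), float(e3[0]),
            float(e4[0]), float(f_r1[0]),
        )
    return MprageSignalTerms(t1_star, e1, e2, e3, e4, f_r1)


def synthesize(
    maps: QuantitativeMaps,
    protocol: MprageProtocol,
    modality: Iterable[str] | frozenset[str],
) -> SyntheticImage:
    """Compute one synthetic T1w image for a parameter subset.

    The excluded factors are replaced by exactly 1; R1 must be included
    (no image type exists without it). Non-finite map voxels propagate NaN.
    """
    modality = frozenset(modality)
    if modality not in MODALITIES:
        raise ValueError(
            f"modality must be one of {[set(m) for m in MODALITIES]}, got {set(modality)}"
        )
    terms = signal_terms(maps.r1, protocol)
    intensity = math.sin(protocol.flip_rad) * np.asarray(terms.f_r1, dtype=float)
    if "PD" in modality:
        intensity = intensity * maps.pd
    if "R2s" in modality:
        with np.errstate(invalid="ignore"):
            intensity = intensity * np.exp(-protocol.te_ms * maps.r2s / PER_SECOND_PER_MS)
    intensity = np.where(maps.mask, intensity, np.nan)
    return SyntheticImage(intensity=intensity, modality=modality, protocol=protocol)


def synthesize_set(
    maps: QuantitativeMaps, protocol: MprageProtocol
) -> dict[str, SyntheticImage]:
    """All four image types on a shared grid, keyed by modality tag."""
    return {modality_tag(m): synthesize(maps, protocol, m) for m in MODALITIES}
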