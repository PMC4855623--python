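"""Estimation of quantitative R1, PD and R2* maps from dual-flip-angle
multi-echo FLASH data.

The pipeline mirrors the standard multi-parameter-mapping recipe:

1. R2* from an ordinary least-squares fit of the log-signal of the
   PD-weighted echoes, ``ln S(TE) = ln S0 - TE * R2*``.
2. R1 and PD from the two flip angles via the exact two-point linearisation
   of the spoiled gradient-echo (Ernst) steady state,
   ``S/sin(a) = E1 * S/tan(a) + PD * (1 - E1)`` with ``E1 = exp(-TR*R1)``,
   so that the slope of the line through the two (x, y) points gives E1 and
   the intercept gives PD. An optional B1 map rescales the nominal flip
   angles voxelwise before the inversion.

Relaxation arithmetic is internal in 1/ms; the public maps are in 1/s
(conversion factor exactly 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .protocols import FlashProtocol

__all__ = [
    "B1Map",
    "MultiEchoFlashSet",
    "QuantitativeMaps",
    "QCReport",
    "fit_r2star",
    "fit_r1_pd",
    "estimate_maps",
    "PER_SECOND_PER_MS",
]

#: 1/ms -> 1/s conversion.
PER_SECOND_PER_MS = 1000.0


@dataclass(frozen=True)
class B1Map:
    """Relative transmit-field map: achieved / nominal flip angle, 1.0 = nominal."""

    relative_flip_factor: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.relative_flip_factor, dtype=float)
        if np.any(arr <= 0) or np.any(arr > 2):
            raise ValueError("B1 relative flip factors must lie in (0, 2]")
        object.__setattr__(self, "relative_flip_factor", arr)


@dataclass(frozen=True)
class MultiEchoFlashSet:
    """One subject's paired PD-weighted and T1-weighted multi-echo stacks.

    ``pdw_volumes`` and ``t1w_volumes`` are 4-D arrays (x, y, z, echo); the
    echo axis length must match the corresponding protocol's echo count and
    the spatial grids of all volumes and the mask must be identical.
    """

    pdw_volumes: np.ndarray
    t1w_volumes: np.ndarray
    pdw_protocol: FlashProtocol
    t1w_protocol: FlashProtocol
    mask: np.ndarray

    def __post_init__(self) -> None:
        pdw = np.asarray(self.pdw_volumes, dtype=float)
        t1w = np.asarray(self.t1w_volumes, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if pdw.ndim != 4 or t1w.ndim != 4:
            raise ValueError("echo stacks must be 4-D (x, y, z, echo)")
        if pdw.shape[-1] != self.pdw_protocol.n_echoes:
            raise ValueError("PDw echo axis does not match protocol echo count")
        if t1w.shape[-1] != self.t1w_protocol.n_echoes:
            raise ValueError("T1w echo axis does not match protocol echo count")
        if pdw.shape[:3] != t1w.shape[:3] or pdw.shape[:3] != mask.shape:
            raise ValueError("spatial grids of PDw, T1w and mask differ")
        object.__setattr__(self, "pdw_volumes", pdw)
        object.__setattr__(self, "t1w_volumes", t1w)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class QuantitativeMaps:
    """Co-registered quantitative maps of one subject.

    r1 and r2s are in 1/s, pd in arbitrary units (free water approximately 1).
    Inside the mask r1 > 0, r2s >= 0 and pd > 0; NaN marks voxels the
    estimators rejected, and everything outside the mask is NaN.
    """

    r1: np.ndarray
    pd: np.ndarray
    r2s: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        r1 = np.asarray(self.r1, dtype=float)
        pd = np.asarray(self.pd, dtype=float)
        r2s = np.asarray(self.r2s, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        if not (r1.shape == pd.shape == r2s.shape == mask.shape):
            raise ValueError("map shapes differ")
        for name, arr, low_ok in (("r1", r1, False), ("pd", pd, False), ("r2s", r2s, True)):
            inside = arr[mask]
            finite = inside[np.isfinite(inside)]
            if low_ok:
                if np.any(finite < 0):
                    raise ValueError(f"{name} must be >= 0 inside the mask")
            elif np.any(finite <= 0):
                raise ValueError(f"{name} must be > 0 inside the mask")
        object.__setattr__(self, "r1", r1)
        object.__setattr__(self, "pd", pd)
        object.__setattr__(self, "r2s", r2s)
        object.__setattr__(self, "mask", mask)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclass
class QCReport:
    """Counts of voxels the estimators clipped or rejected."""

    n_masked: int = 0
    n_nonpositive_signal: int = 0
    n_negative_r2s_clipped: int = 0
    n_nonphysical_e1: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_masked": self.n_masked,
            "n_nonpositive_signal": self.n_nonpositive_signal,
            "n_negative_r2s_clipped": self.n_negative_r2s_clipped,
            "n_nonphysical_e1": self.n_nonphysical_e1,
            "warnings": list(self.warnings),
        }


def fit_r2star(
    volumes_4d: np.ndarray,
    echo_times_ms: Sequence[float],
    mask: np.ndarray,
    qc: QCReport | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Log-linear least-squares R2* fit over the echo train.

    Parameters
    ----------
    volumes_4d:
        Signal stack of shape (x, y, z, n_echoes).
    echo_times_ms:
        Echo times in ms, one per echo, at least two.
    mask:
        Boolean volume; the fit is evaluated only inside it.

    Returns
    -------
    (r2s_map, s0_map):
        R2* in 1/s (negative fits clipped to zero and counted in the QC
        report) and the extrapolated TE=0 signal. Voxels with a non-positive
        signal at any echo are set to NaN and counted. Outside the mask both
        maps are NaN.
    """
    volumes_4d = np.asarray(volumes_4d, dtype=float)
    te = np.asarray(echo_times_ms, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if te.ndim != 1 or te.size < 2:
        raise ValueError("at least two echoes are required for an R2* fit")
    if volumes_4d.shape[-1] != te.size:
        raise ValueError("echo axis does not match the number of echo times")
    if volumes_4d.shape[:3] != mask.shape:
        raise ValueError("signal stack and mask grids differ")

    sig = volumes_4d[mask]  # (n_vox, n_echo)
    valid = np.all(sig > 0, axis=1)
    n_bad = int(np.count_nonzero(~valid))
    if qc is not None:
        qc.n_masked += int(sig.shape[0])
        qc.n_nonpositive_signal += n_bad

    slope = np.full(sig.shape[0], np.nan)
    intercept = np.full(sig.shape[0], np.nan)
    if np.any(valid):
        log_sig = np.log(sig[valid])
        # OLS of ln S on TE: slope = -R2* (in 1/ms), intercept = ln S0.
        te_c = te - te.mean()
        denom = float(np.dot(te_c, te_c))
        sl = log_sig @ te_c / denom
        ic = log_sig.mean(axis=1) - sl * te.mean()
        slope[valid] = sl
        intercept[valid] = ic

    r2s_ms = -slope
    neg = r2s_ms < 0
    if qc is not None:
        qc.n_negative_r2s_clipped += int(np.count_nonzero(neg & np.isfinite(r2s_ms)))
    r2s_ms = np.where(neg, 0.0, r2s_ms)

    r2s_map = np.full(mask.shape, np.nan)
    s0_map = np.full(mask.shape, np.nan)
    r2s_map[mask] = r2s_ms * PER_SECOND_PER_MS
    s0_map[mask] = np.exp(intercept)
    return r2s_map, s0_map


def fit_r1_pd(
    pdw_te0: np.ndarray,
    t1w_te0: np.ndarray,
    pdw_protocol: FlashProtocol,
    t1w_protocol: FlashProtocol,
    b1: Optional[B1Map],
    mask: np.ndarray,
    qc: QCReport | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point R1/PD estimate from dual-flip-angle TE=0 signals.

    Inverts the Ernst steady state exactly through the linearisation
    ``y = E1 * x + PD * (1 - E1)`` with ``y = S / sin(a_eff)`` and
    ``x = S / tan(a_eff)``: the slope of the line through the two
    acquisitions is E1, hence ``R1 = -ln(E1) / TR``, and the intercept
    gives PD.

    Voxels whose fitted slope falls outside (0, 1) are non-physical and
    returned as NaN (counted in the QC report). Outputs: r1 in 1/s, pd in
    the signal's arbitrary units.
    """
    pdw_te0 = np.asarray(pdw_te0, dtype=float)
    t1w_te0 = np.asarray(t1w_te0, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if pdw_te0.shape != t1w_te0.shape or pdw_te0.shape != mask.shape:
        raise ValueError("signal volumes and mask grids differ")
    if pdw_protocol.tr_ms != t1w_protocol.tr_ms:
        raise ValueError("the two-point inversion requires a common TR")
    if pdw_protocol.flip_deg == t1w_protocol.flip_deg:
        raise ValueError("flip angles must differ")

    tr = pdw_protocol.tr_ms
    if b1 is None:
        factor = np.ones(mask.shape)
    else:
        factor = b1.relative_flip_factor
        if factor.shape != mask.shape:
            raise ValueError("B1 map grid differs from the signal grid")

    a1 = pdw_protocol.flip_rad * factor[mask]
    a2 = t1w_protocol.flip_rad * factor[mask]
    s1 = pdw_te0[mask]
    s2 = t1w_te0[mask]

    with np.errstate(invalid="ignore", divide="ignore"):
        y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
        y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
        e1 = (y1 - y2) / (x1 - x2)
        physical = (e1 > 0) & (e1 < 1) & (s1 > 0) & (s2 > 0)
        r1_ms = np.where(physical, -np.log(np.where(physical, e1, 0.5)) / tr, np.nan)
        pd = np.where(physical, (y1 - e1 * x1) / (1.0 - e1), np.nan)
    pd = np.where(physical & (pd > 0), pd, np.nan)

    if qc is not None:
        qc.n_nonphysical_e1 += int(np.count_nonzero(~physical | ~(pd > 0)))

    r1_map = np.full(mask.shape, np.nan)
    pd_map = np.full(mask.shape, np.nan)
    r1_map[mask] = r1_ms * PER_SECOND_PER_MS
    pd_map[mask] = pd
    return r1_map, pd_map


def estimate_maps(
    data: MultiEchoFlashSet, b1: Optional[B1Map] = None
) -> tuple[QuantitativeMaps, QCReport]:
    """Full map-estimation pipeline for one subject.

    R2* comes from the PD-weighted echo train alone. R1 and PD come from
    the two first-echo (minimal-TE) images after removing their residual
    ``exp(-TE1 * R2*)`` decay with the fitted R2*, so the two-point
    inversion sees TE=0 signals and noise-free inputs round-trip exactly.
    """
    qc = QCReport()
    mask = data.mask
    if not mask.any():
        qc.warnings.append("empty mask: no voxels to fit")
        nanvol = np.full(mask.shape, np.nan)
        return (
            QuantitativeMaps(r1=nanvol, pd=nanvol.copy(), r2s=nanvol.copy(), mask=mask),
            qc,
        )

    r2s_map, s0_pdw = fit_r2star(data.pdw_volumes, data.pdw_protocol.te_ms, mask, qc=qc)

    te1 = data.t1w_protocol.te_ms[0]
    with np.errstate(invalid="ignore"):
        decay = np.exp(-te1 * r2s_map / PER_SECOND_PER_MS)
        t1w_te0 = data.t1w_volumes[..., 0] / decay
    r1_map, pd_map = fit_r1_pd(
        s0_pdw, t1w_te0, data.pdw_protocol, data.t1w_protocol, b1, mask, qc=qc
    )
    maps = QuantitativeMaps(r1=r1_map, pd=pd_map, r2s=r2s_map, mask=mask)
    return maps, qc
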