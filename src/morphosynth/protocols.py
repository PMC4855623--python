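"""Acquisition protocol descriptions for the simulated sequences.

Two sequences are described: the multi-echo spoiled gradient-echo (FLASH)
acquisitions from which the quantitative maps are estimated, and the MPRAGE
sequence whose T1-weighted contrast is synthesised from those maps.

All times are in milliseconds and all angles in degrees at the interface;
relaxation arithmetic elsewhere in the package is carried out in 1/ms and
converted to the conventional 1/s only on the public map surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "FlashProtocol",
    "MprageProtocol",
    "PDW_FLASH",
    "T1W_FLASH",
    "DEFAULT_MPRAGE",
    "load_flash_protocol",
    "load_mprage_protocol",
]


@dataclass(frozen=True)
class FlashProtocol:
    """Multi-echo spoiled gradient-echo (FLASH) acquisition parameters.

    Parameters
    ----------
    tr_ms:
        Repetition time in milliseconds.
    flip_deg:
        Nominal excitation flip angle in degrees, in (0, 90).
    te_ms:
        Echo times in milliseconds, strictly increasing.
    """

    tr_ms: float
    flip_deg: float
    te_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.tr_ms <= 0:
            raise ValueError(f"tr_ms must be positive, got {self.tr_ms}")
        if not 0.0 < self.flip_deg < 90.0:
            raise ValueError(f"flip_deg must be in (0, 90), got {self.flip_deg}")
        te = tuple(float(t) for t in self.te_ms)
        if any(t <= 0 for t in te):
            raise ValueError("all echo times must be positive")
        if any(b <= a for a, b in zip(te, te[1:])):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "te_ms", te)

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    def to_dict(self) -> dict:
        return {"tr_ms": self.tr_ms, "flip_deg": self.flip_deg, "te_ms": list(self.te_ms)}


def _equidistant_echoes(first: float, last: float, n: int) -> tuple[float, ...]:
    return tuple(np.linspace(first, last, n).tolist())


#: The dual-flip-angle, eight-echo protocol pair used throughout: a
#: predominantly PD-weighted acquisition at a small flip angle and a
#: T1-weighted acquisition at a larger one, sharing TR and echo train.
PDW_FLASH = FlashProtocol(tr_ms=24.5, flip_deg=6.0, te_ms=_equidistant_echoes(2.34, 18.72, 8))
T1W_FLASH = FlashProtocol(tr_ms=24.5, flip_deg=21.0, te_ms=_equidistant_echoes(2.34, 18.72, 8))


@dataclass(frozen=True)
class MprageProtocol:
    """Timing of one simulated MPRAGE cycle.

    The cycle is: adiabatic inversion, free recovery, a train of ``n_lines``
    low-angle excitations spaced ``es_ms`` apart (readout duration
    ``tau = n_lines * es_ms``), then free recovery for the delay time TD
    until the next inversion. The signal is read at the centre of the train
    (centric-ordered k-space).

    Two conventions for the inversion time are supported:

    - ``"center"`` (default): ``ti_ms`` runs from the inversion pulse to the
      *centre* of the readout train, so ``TD = TR - TI - tau/2``.
    - ``"start"``: ``ti_ms`` runs to the first excitation, ``TD = TR - TI - tau``.

    The default timing (alpha = 9 deg, ES = 9.9 ms, TI = 960 ms,
    tau = 176 x ES, TR = 2420 ms) only admits a non-negative recovery delay
    under the centre convention, which is therefore the default.
    """

    flip_deg: float = 9.0
    es_ms: float = 9.9
    ti_ms: float = 960.0
    n_lines: int = 176
    tr_ms: float = 2420.0
    te_ms: float = 3.0
    ti_convention: str = "center"

    def __post_init__(self) -> None:
        for name in ("flip_deg", "es_ms", "ti_ms", "tr_ms", "te_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if math.cos(math.radians(self.flip_deg)) <= 0:
            raise ValueError("flip angle must satisfy cos(alpha) > 0")
        if self.ti_convention not in ("center", "start"):
            raise ValueError(f"unknown ti_convention {self.ti_convention!r}")
        if self.ti_start_ms <= 0:
            raise ValueError(
                f"inversion-to-readout time is non-positive ({self.ti_start_ms:.1f} ms)"
            )
        if self.td_ms < 0:
            raise ValueError(
                f"recovery delay TD is negative ({self.td_ms:.1f} ms); "
                "check TR/TI/tau consistency or the TI convention"
            )

    @property
    def tau_ms(self) -> float:
        """Readout-train duration in ms."""
        return self.n_lines * self.es_ms

    @property
    def ti_start_ms(self) -> float:
        """Time from inversion to the first readout excitation, ms."""
        if self.ti_convention == "center":
            return self.ti_ms - self.tau_ms / 2.0
        return self.ti_ms

    @property
    def td_ms(self) -> float:
        """Recovery delay between end of readout and next inversion, ms."""
        return self.tr_ms - self.ti_start_ms - self.tau_ms

    @property
    def flip_rad(self) -> float:
        return math.radians(self.flip_deg)

    def to_dict(self) -> dict:
        return {
            "flip_deg": self.flip_deg,
            "es_ms": self.es_ms,
            "ti_ms": self.ti_ms,
            "n_lines": self.n_lines,
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "ti_convention": self.ti_convention,
        }


#: Protocol tuned for maximal gray-white contrast, used for all synthetic images.
DEFAULT_MPRAGE = MprageProtocol()


def load_flash_protocol(path: str | Path) -> FlashProtocol:
    """Read a FLASH protocol from a YAML/JSON file with keys tr_ms, flip_deg, te_ms."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        return FlashProtocol(
            tr_ms=float(raw["tr_ms"]),
            flip_deg=float(raw["flip_deg"]),
            te_ms=tuple(float(t) for t in raw["te_ms"]),
        )
    except KeyError as exc:
        raise KeyError(f"protocol file {path} is missing key {exc}") from exc


def load_mprage_protocol(path: str | Path) -> MprageProtocol:
    """Read an MPRAGE protocol from a YAML/JSON file.

    Recognised keys: flip_deg, es_ms, ti_ms, n_lines, tr_ms, te_ms,
    ti_convention; absent keys fall back to the defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {
        k: raw[k]
        for k in ("flip_deg", "es_ms", "ti_ms", "n_lines", "tr_ms", "te_ms", "ti_convention")
        if k in raw
    }
    return MprageProtocol(**known)
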