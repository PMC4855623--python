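"""Discrete Bloch-train simulator of the MPRAGE cycle.

Independent oracle for the closed-form signal equation in
:mod:`morphosynth.mprage`: instead of the continuous T1* approximation of
relaxation during the excitation train, every RF pulse is applied
discretely (longitudinal magnetisation scaled by cos(alpha)) with exact
mono-exponential recovery between pulses, and the cycle is iterated to its
periodic steady state. This is a test oracle, not the production synthesis
path.
"""

from __future__ import annotations

import math

from .protocols import MprageProtocol

__all__ = ["bloch_mprage_signal"]


def bloch_mprage_signal(
    r1_per_s: float,
    protocol: MprageProtocol,
    m0: float = 1.0,
    n_cycles: int = 50,
    tol: float = 1e-12,
) -> float:
    """Steady-state transverse signal at the centre of the readout train.

    Simulates repeated cycles of: perfect inversion, free recovery to the
    first excitation, ``n_lines`` pulses of angle alpha spaced ES apart
    with free recovery between them, then recovery for TD. The reported
    signal is ``sin(alpha) * Mz`` immediately before the centre pulse
    (index ``n_lines // 2``), i.e. the centre of k-space. R2*/TE decay is
    not applied (it multiplies oracle and closed form identically).

    Cycles are iterated until the pre-inversion magnetisation changes by
    less than ``tol`` or ``n_cycles`` is reached.
    """
    if r1_per_s <= 0:
        raise ValueError("r1 must be positive")
    r1 = r1_per_s / 1000.0  # 1/ms
    alpha = protocol.flip_rad
    cos_a, sin_a = math.cos(alpha), math.sin(alpha)
    e_ti = math.exp(-protocol.ti_start_ms * r1)
    e_es = math.exp(-protocol.es_ms * r1)
    e_td = math.exp(-protocol.td_ms * r1)
    n = protocol.n_lines
    center = n // 2

    mz = m0  # start from thermal equilibrium
    signal = 0.0
    for _ in range(n_cycles):
        mz_prev = mz
        mz = -mz  # inversion
        mz = m0 + (mz - m0) * e_ti
        for k in range(n):
            if k == center:
                signal = sin_a * mz
            mz *= cos_a
            mz = m0 + (mz - m0) * e_es
        mz = m0 + (mz - m0) * e_td
        if abs(mz - mz_prev) < tol * m0:
            break
    return signal
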