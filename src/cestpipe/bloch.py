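"""Continuous-wave Bloch–McConnell simulation of Z-spectra.

A Z-spectrum is the normalized water signal as a function of the
saturation-frequency offset (in ppm from water).  Each exchangeable
solute pool (e.g. the amide protons of iopamidol at 4.2 ppm) is coupled
to the water pool by two-site chemical exchange; saturating the solute
resonance transfers saturation to water and carves a dip into the
spectrum at the solute offset.

The solver propagates the coupled 3N-dimensional magnetization system
(x, y, z components per pool) under a constant RF field for the
saturation duration, starting from thermal equilibrium, using the
matrix-exponential solution of the inhomogeneous linear ODE
``dM/dt = A M + b``:

    M(t) = M_ss + expm(A t) (M_0 - M_ss),   M_ss = -A^{-1} b.

The reported signal is the longitudinal water magnetization at readout
divided by its thermal-equilibrium value, so an unsaturated reference
acquisition reads exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

__all__ = [
    "GAMMA_MHZ_PER_T",
    "PoolParams",
    "SaturationParams",
    "water_pool",
    "build_bm_matrix",
    "simulate_zspectrum",
]

#: Proton gyromagnetic ratio, MHz/T (equivalently Hz/uT).
GAMMA_MHZ_PER_T = 42.577


@dataclass(frozen=True)
class PoolParams:
    """One proton pool of the exchange model.

    Parameters
    ----------
    name:
        Label ("water", "amide", "iopamidol", ...).
    chemical_shift:
        Resonance offset from water, ppm.  Water is 0 by definition.
    proton_fraction:
        Pool size relative to water, in [0, 1).  Water uses 1.0 by
        convention (its magnetization is the normalization reference).
    exchange_rate:
        Solute-to-water exchange rate k, 1/s.  Ignored for water; the
        water-to-solute back-rate is ``proton_fraction * k`` (mass
        balance).
    T1, T2:
        Longitudinal / transverse relaxation times, s.
    """

    name: str
    chemical_shift: float
    proton_fraction: float
    exchange_rate: float
    T1: float
    T2: float

    def __post_init__(self) -> None:
        vals = (self.chemical_shift, self.proton_fraction,
                self.exchange_rate, self.T1, self.T2)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"pool {self.name!r}: non-finite parameter")
        if not (0.0 <= self.proton_fraction < 1.0) and self.name != "water":
            raise ValueError(f"pool {self.name!r}: proton_fraction must be in [0, 1)")
        if self.exchange_rate < 0:
            raise ValueError(f"pool {self.name!r}: exchange_rate must be >= 0")
        if self.T1 <= 0 or self.T2 <= 0:
            raise ValueError(f"pool {self.name!r}: T1 and T2 must be > 0")

    @property
    def is_water(self) -> bool:
        return self.name == "water"


def water_pool(T1: float = 1.8, T2: float = 0.05) -> PoolParams:
    """Bulk water pool (7 T brain-tissue defaults)."""
    return PoolParams("water", 0.0, 1.0, 0.0, T1, T2)


@dataclass(frozen=True)
class SaturationParams:
    """Continuous-wave presaturation block.

    ``b1_amplitude`` is in microtesla, ``duration`` in seconds,
    ``field_strength`` in tesla (default 7 T).
    """

    b1_amplitude: float = 3.0
    duration: float = 3.0
    field_strength: float = 7.0
    gamma: float = GAMMA_MHZ_PER_T

    def __post_init__(self) -> None:
        if self.b1_amplitude < 0:
            raise ValueError("b1_amplitude must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be > 0")

    @property
    def omega1(self) -> float:
        """RF nutation rate, rad/s."""
        return 2.0 * math.pi * self.gamma * self.b1_amplitude

    @property
    def hz_per_ppm(self) -> float:
        return self.gamma * self.field_strength


def _check_pools(pools: list[PoolParams]) -> tuple[PoolParams, list[PoolParams]]:
    waters = [p for p in pools if p.is_water]
    if len(waters) != 1:
        raise ValueError("pool list must contain exactly one water pool")
    solutes = [p for p in pools if not p.is_water]
    return waters[0], solutes


def build_bm_matrix(
    pools: list[PoolParams],
    sat: SaturationParams,
    offset_ppm: float,
    b0_shift: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble A, b and the equilibrium vector M0 for one offset.

    State ordering is (Mx, My, Mz) for water first, then each solute in
    list order.  A positive ``b0_shift`` moves the apparent water
    resonance to +b0_shift ppm, i.e. rigidly translates the spectrum.
    """
    water, solutes = _check_pools(pools)
    ordered = [water] + solutes
    n = len(ordered)
    dim = 3 * n
    w1 = sat.omega1
    two_pi_f0 = 2.0 * math.pi * sat.hz_per_ppm

    A = np.zeros((dim, dim))
    b = np.zeros(dim)
    M0 = np.zeros(dim)

    # water-to-solute rates, by mass balance
    k_out = [0.0] + [p.exchange_rate for p in solutes]          # solute -> water
    k_in = [sum(p.exchange_rate * p.proton_fraction for p in solutes)]
    k_in += [0.0] * len(solutes)                                # placeholder

    for i, p in enumerate(ordered):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        # offset of pool resonance relative to the applied saturation, rad/s
        dw = two_pi_f0 * (p.chemical_shift + b0_shift - offset_ppm)
        m0 = 1.0 if p.is_water else p.proton_fraction
        r1, r2 = 1.0 / p.T1, 1.0 / p.T2
        loss = k_in[0] if p.is_water else k_out[i]

        A[x, x] = -(r2 + loss)
        A[x, y] = -dw
        A[y, x] = dw
        A[y, y] = -(r2 + loss)
        A[y, z] = w1
        A[z, y] = -w1
        A[z, z] = -(r1 + loss)
        b[z] = r1 * m0
        M0[z] = m0

        if p.is_water:
            for j, q in enumerate(ordered[1:], start=1):
                qx = 3 * j
                A[x, qx] = A[y, qx + 1] = A[z, qx + 2] = q.exchange_rate
        else:
            wx = 0
            rate_in = p.exchange_rate * p.proton_fraction  # water -> this pool
            A[x, wx] = A[y, wx + 1] = A[z, wx + 2] = rate_in

    return A, b, M0


def simulate_zspectrum(
    pools: list[PoolParams],
    sat: SaturationParams,
    offsets_ppm: np.ndarray,
    b0_shift: float = 0.0,
) -> np.ndarray:
    """Noiseless Z-spectrum at the requested saturation offsets.

    Returns the water Mz after the saturation block, normalized to the
    thermal-equilibrium water magnetization, one value per offset.
    With ``b1_amplitude == 0`` every value is exactly 1.
    """
    offsets = np.atleast_1d(np.asarray(offsets_ppm, dtype=float))
    _check_pools(pools)
    if sat.b1_amplitude == 0.0:
        return np.ones_like(offsets)

    out = np.empty(offsets.shape)
    for i, off in enumerate(offsets):
        A, b, M0 = build_bm_matrix(pools, sat, float(off), b0_shift)
        Mss = -np.linalg.solve(A, b)
        Mt = Mss + expm(A * sat.duration) @ (M0 - Mss)
        out[i] = Mt[2]  # water Mz; equilibrium water Mz is 1
    return np.clip(out, 0.0, None) if np.any(out < 0) else out
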