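"""Independent brute-force oracles used by the test suite.

These deliberately do not reuse the package's matrix assembly or
solvers: the Bloch-McConnell oracle integrates the coupled
magnetization ODEs with explicit fixed-step RK4 from hand-written
derivative loops, and the ICC oracle evaluates the two-way ANOVA mean
squares by explicit summation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

GAMMA = 42.577  # MHz/T


@njit(cache=True)
def _bm_deriv(M, dM, n, dw, r1, r2, m0, k_to_water, k_from_water, w1):
    # pool 0 is water; every solute exchanges only with water
    for i in range(n):
        x, y, z = 3 * i, 3 * i + 1, 3 * i + 2
        if i == 0:
            loss = 0.0
            for j in range(1, n):
                loss += k_from_water[j]
        else:
            loss = k_to_water[i]
        dM[x] = -(r2[i] + loss) * M[x] - dw[i] * M[y]
        dM[y] = dw[i] * M[x] - (r2[i] + loss) * M[y] + w1 * M[z]
        dM[z] = -w1 * M[y] - (r1[i] + loss) * M[z] + r1[i] * m0[i]
        if i == 0:
            for j in range(1, n):
                dM[x] += k_to_water[j] * M[3 * j]
                dM[y] += k_to_water[j] * M[3 * j + 1]
                dM[z] += k_to_water[j] * M[3 * j + 2]
        else:
            dM[x] += k_from_water[i] * M[0]
            dM[y] += k_from_water[i] * M[1]
            dM[z] += k_from_water[i] * M[2]


@njit(cache=True)
def _rk4_integrate(n, dw, r1, r2, m0, k_to_water, k_from_water, w1, duration, dt):
    dim = 3 * n
    M = np.zeros(dim)
    for i in range(n):
        M[3 * i + 2] = m0[i]
    k1 = np.zeros(dim)
    k2 = np.zeros(dim)
    k3 = np.zeros(dim)
    k4 = np.zeros(dim)
    tmp = np.zeros(dim)
    nsteps = int(round(duration / dt))
    for _ in range(nsteps):
        _bm_deriv(M, k1, n, dw, r1, r2, m0, k_to_water, k_from_water, w1)
        for d in range(dim):
            tmp[d] = M[d] + 0.5 * dt * k1[d]
        _bm_deriv(tmp, k2, n, dw, r1, r2, m0, k_to_water, k_from_water, w1)
        for d in range(dim):
            tmp[d] = M[d] + 0.5 * dt * k2[d]
        _bm_deriv(tmp, k3, n, dw, r1, r2, m0, k_to_water, k_from_water, w1)
        for d in range(dim):
            tmp[d] = M[d] + dt * k3[d]
        _bm_deriv(tmp, k4, n, dw, r1, r2, m0, k_to_water, k_from_water, w1)
        for d in range(dim):
            M[d] += dt / 6.0 * (k1[d] + 2.0 * k2[d] + 2.0 * k3[d] + k4[d])
    return M[2]


def zspectrum_rk4(pools, sat, offsets_ppm, b0_shift=0.0, dt=5e-6):
    """Z-spectrum by explicit fine-step RK4 time integration.

    ``pools`` is a list of PoolParams-like objects (water first not
    required; identified by name); ``sat`` a SaturationParams-like
    object.  Returns water Mz(duration) normalized by equilibrium.
    """
    water = [p for p in pools if p.name == "water"]
    solutes = [p for p in pools if p.name != "water"]
    assert len(water) == 1
    ordered = water + solutes
    n = len(ordered)
    hz_per_ppm = GAMMA * sat.field_strength
    w1 = 2.0 * math.pi * GAMMA * sat.b1_amplitude
    r1 = np.array([1.0 / p.T1 for p in ordered])
    r2 = np.array([1.0 / p.T2 for p in ordered])
    m0 = np.array([1.0] + [p.proton_fraction for p in solutes])
    k_to_water = np.array([0.0] + [p.exchange_rate for p in solutes])
    k_from_water = np.array([0.0] + [p.exchange_rate * p.proton_fraction for p in solutes])
    shifts = np.array([p.chemical_shift for p in ordered])

    out = np.empty(len(offsets_ppm))
    for i, off in enumerate(np.asarray(offsets_ppm, dtype=float)):
        if sat.b1_amplitude == 0.0:
            out[i] = 1.0
            continue
        dw = 2.0 * math.pi * hz_per_ppm * (shifts + b0_shift - off)
        out[i] = _rk4_integrate(n, dw, r1, r2, m0, k_to_water, k_from_water,
                                w1, sat.duration, dt)
    return out


def icc2_anova(table) -> float:
    """ICC(2,1) from explicitly summed two-way ANOVA mean squares."""
    x = np.asarray(table, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    row_means = np.array([x[i, :].sum() / k for i in range(n)])
    col_means = np.array([x[:, j].sum() / n for j in range(k)])
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))
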