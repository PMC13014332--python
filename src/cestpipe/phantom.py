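"""Digital glioblastoma-bearing brain-slice phantom.

The phantom emulates a preclinical iodinated-CEST study at 7 T: an
ellipsoidal "brain" containing an ellipsoidal "tumor", imaged with a
46-offset CEST protocol before and after injection of an exogenous
amide-bearing agent (resonance at 4.2 ppm), plus pre/post T1-weighted
volumes with gadolinium-like tumor enhancement.  Ground truth (tumor
and brain masks, the per-voxel B0 field, the noiseless dST map) is
returned alongside the data so every downstream stage can be scored
against a known answer.

Signal model per voxel: a tissue class (brain parenchyma or tumor,
pre or post injection) defines the Bloch-McConnell pool system; the
smooth polynomial B0 field rigidly shifts each voxel's Z-spectrum.
Spectra are simulated once per (tissue class, B0 value quantized to
0.01 ppm) and reused across voxels, which is exact up to the
quantization and keeps the full phantom tractable.  Magnitude noise is
Rician: independent Gaussian noise on two quadrature channels before
the magnitude operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import PoolParams, SaturationParams, simulate_zspectrum, water_pool
from .schedule import OffsetSchedule, default_schedule
from .zspec import ZSpectrumStack

__all__ = [
    "PhantomSpec",
    "PhantomDataset",
    "ellipsoid_mask",
    "add_rician_noise",
    "generate_phantom",
    "region_spectrum",
    "region_truth_st",
]

#: B0 quantization used by the spectrum cache, ppm (equals the analysis grid step)
B0_QUANT = 0.01

#: exogenous agent amide pool at 4.2 ppm; proton fractions are set per region
AGENT_POOL = PoolParams("agent_amide", 4.2, 0.0005, 40.0, 1.0, 0.01)

#: calibrated post-injection agent proton fractions (see docs/methods.md):
#: tumor value yields a ground-truth tumor dST of 2.3% at 4.2 ppm, the brain
#: value a tumor/brain dST ratio of ~6.2, under the default saturation scheme
TUMOR_AGENT_FRACTION_POST = 4.898e-4
BRAIN_AGENT_FRACTION_POST = 7.772e-5


def _default_endogenous() -> tuple[PoolParams, ...]:
    # bulk water + a small endogenous amide pool at 3.5 ppm
    return (
        water_pool(T1=1.8, T2=0.05),
        PoolParams("endo_amide", 3.5, 9.0e-4, 30.0, 1.0, 0.01),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one phantom acquisition.

    Geometry is specified in 0-based voxel indices for exactness.
    ``agent_fraction_pre/post`` map region name ("tumor", "brain") to
    the exogenous pool's proton fraction in that region;
    ``t1w_enhancement`` maps region name to the multiplicative post/pre
    T1w signal ratio.  ``noise_sigma`` is the Rician channel sigma as a
    fraction of the reference signal.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 4)
    voxel_size_mm: tuple[float, float, float] = (0.156, 0.156, 1.5)
    brain_center: tuple[float, float, float] = (31.5, 31.5, 1.5)
    brain_semiaxes: tuple[float, float, float] = (26.0, 21.0, 12.0)
    tumor_center: tuple[float, float, float] = (22.0, 27.0, 1.5)
    tumor_semiaxes: tuple[float, float, float] = (7.0, 5.0, 1.8)
    agent_fraction_pre: dict = field(default_factory=lambda: {"tumor": 0.0, "brain": 0.0})
    agent_fraction_post: dict = field(
        default_factory=lambda: {
            "tumor": TUMOR_AGENT_FRACTION_POST,
            "brain": BRAIN_AGENT_FRACTION_POST,
        }
    )
    endogenous_pools: tuple[PoolParams, ...] = field(default_factory=_default_endogenous)
    saturation: SaturationParams = field(default_factory=SaturationParams)
    # b0(x, y) = c0 + c1 u + c2 v + c3 u^2 + c4 v^2 + c5 u v, with u, v the
    # in-plane coordinates rescaled to [-1, 1]; ppm
    b0_coeffs: tuple[float, ...] = (0.05, 0.10, -0.08, 0.08, -0.05, 0.04)
    noise_sigma: float = 0.0
    t1w_baseline: dict = field(default_factory=lambda: {"brain": 100.0, "tumor": 90.0})
    t1w_enhancement: dict = field(default_factory=lambda: {"brain": 1.0, "tumor": 2.0})
    analysis_offset: float = 4.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for region in ("tumor", "brain"):
            if self.agent_fraction_post[region] < self.agent_fraction_pre[region]:
                raise ValueError(f"post agent fraction < pre in {region!r}")

    def pools(self, phase: str, region: str) -> list[PoolParams]:
        """Pool system for one tissue class ('pre'/'post' x 'tumor'/'brain')."""
        frac = (self.agent_fraction_pre if phase == "pre" else self.agent_fraction_post)[region]
        pools = list(self.endogenous_pools)
        if frac > 0:
            pools.append(replace(AGENT_POOL, proton_fraction=frac))
        return pools


@dataclass
class PhantomDataset:
    """Generated phantom volumes with their ground truth."""

    cest_pre: ZSpectrumStack
    cest_post: ZSpectrumStack
    t1w_pre: np.ndarray
    t1w_post: np.ndarray
    truth_tumor_mask: np.ndarray
    truth_brain_mask: np.ndarray
    truth_b0: np.ndarray
    truth_delta_st: np.ndarray
    spec: PhantomSpec


def ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    """Binary mask of voxels inside the axis-aligned ellipsoid.

    A voxel (i, j, k) is inside when
    sum(((idx - center)/semiaxis)^2) <= 1.
    """
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def add_rician_noise(volume: np.ndarray, sigma: float, seed) -> np.ndarray:
    """Magnitude-MRI (Rician) noise: |signal + complex Gaussian|.

    ``sigma`` is the per-channel Gaussian standard deviation in the
    volume's units; ``seed`` is an int or a ``numpy.random.Generator``.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    volume = np.asarray(volume, dtype=float)
    if sigma == 0:
        return volume.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    re = volume + rng.normal(0.0, sigma, volume.shape)
    im = rng.normal(0.0, sigma, volume.shape)
    return np.hypot(re, im)


def _b0_field(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.grid_shape
    u = np.linspace(-1.0, 1.0, nx)[:, None]
    v = np.linspace(-1.0, 1.0, ny)[None, :]
    c = spec.b0_coeffs
    plane = c[0] + c[1] * u + c[2] * v + c[3] * u**2 + c[4] * v**2 + c[5] * u * v
    field3d = np.repeat(plane[:, :, None], nz, axis=2)
    if np.abs(field3d).max() > 0.5:
        raise ValueError("B0 field exceeds 0.5 ppm")
    return np.round(field3d / B0_QUANT) * B0_QUANT


def region_spectrum(
    spec: PhantomSpec, phase: str, region: str, offsets, b0: float = 0.0
) -> np.ndarray:
    """Noiseless Z-spectrum of one tissue class at the given offsets."""
    return simulate_zspectrum(spec.pools(phase, region), spec.saturation,
                              np.asarray(offsets, dtype=float), b0)


def region_truth_st(spec: PhantomSpec, phase: str, region: str) -> float:
    """Ground-truth ST% of a tissue class at the analysis offset (B0 = 0)."""
    dw = spec.analysis_offset
    z_neg, z_pos = region_spectrum(spec, phase, region, [-dw, +dw])
    return float((z_neg - z_pos) / z_neg * 100.0)


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Simulate the full pre/post CEST + T1w phantom with ground truth.

    Deterministic for a given spec (seed included); raises when the
    tumor ellipsoid is not contained in the brain ellipsoid.
    """
    shape = spec.grid_shape
    brain = ellipsoid_mask(shape, spec.brain_center, spec.brain_semiaxes)
    tumor = ellipsoid_mask(shape, spec.tumor_center, spec.tumor_semiaxes)
    if not (tumor <= brain).all():
        raise ValueError("tumor ellipsoid is not contained in the brain ellipsoid")

    b0 = _b0_field(spec)
    schedule = default_schedule()
    sat_offsets = schedule.saturation_offsets
    region_of = np.where(tumor, "tumor", np.where(brain, "brain", "none"))

    stacks = {}
    rng = np.random.default_rng(spec.seed)
    for phase in ("pre", "post"):
        intens = np.zeros(shape + (sat_offsets.size,))
        cache: dict[tuple[str, float], np.ndarray] = {}
        for idx in zip(*np.nonzero(brain)):
            region = region_of[idx]
            key = (region, round(float(b0[idx]) / B0_QUANT) * B0_QUANT)
            if key not in cache:
                cache[key] = region_spectrum(spec, phase, region, sat_offsets, key[1])
            intens[idx] = cache[key]
        ref = brain.astype(float)  # unit reference signal inside the brain
        sigma = spec.noise_sigma  # fraction of the unit reference
        if sigma > 0:
            intens = add_rician_noise(intens, sigma, rng)
            ref = add_rician_noise(ref, sigma, rng)
        stacks[phase] = ZSpectrumStack(intens, schedule, ref)

    # T1-weighted volumes: piecewise-constant baseline times enhancement
    t1w_pre = np.zeros(shape)
    t1w_pre[brain] = spec.t1w_baseline["brain"]
    t1w_pre[tumor] = spec.t1w_baseline["tumor"]
    t1w_post = t1w_pre.copy()
    t1w_post[brain & ~tumor] *= spec.t1w_enhancement["brain"]
    t1w_post[tumor] *= spec.t1w_enhancement["tumor"]
    if spec.noise_sigma > 0:
        s = spec.noise_sigma * spec.t1w_baseline["brain"]
        t1w_pre = add_rician_noise(t1w_pre, s, rng)
        t1w_post = add_rician_noise(t1w_post, s, rng)

    # ground-truth dST from the noiseless tissue-class spectra (B0-free)
    delta = np.zeros(shape)
    for region in ("brain", "tumor"):
        d = region_truth_st(spec, "post", region) - region_truth_st(spec, "pre", region)
        delta[(region_of == region)] = d

    return PhantomDataset(
        cest_pre=stacks["pre"],
        cest_post=stacks["post"],
        t1w_pre=t1w_pre,
        t1w_post=t1w_post,
        truth_tumor_mask=tumor,
        truth_brain_mask=brain,
        truth_b0=b0,
        truth_delta_st=delta,
        spec=spec,
    )
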