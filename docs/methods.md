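# Methods

## Saturation-transfer model

Each voxel is a system of proton pools: bulk water (T1 = 1.8 s,
T2 = 50 ms at 7 T), a small endogenous amide pool at +3.5 ppm
(proton fraction 9×10⁻⁴, exchange rate 30 s⁻¹), and, where the
exogenous iodinated agent is present, an amide pool at +4.2 ppm
(exchange rate 40 s⁻¹, T1 = 1 s, T2 = 10 ms). Solute pools exchange
two-site with water only; the water→solute back-rate is f·k (mass
balance), with f the solute proton fraction relative to water.

Continuous-wave saturation (B1 = 3 μT, 3 s, γ = 42.577 MHz/T) is the
constant-coefficient Bloch–McConnell system dM/dt = A M + b over the
3N magnetization components. The solver uses the exact
matrix-exponential solution M(t) = M_ss + e^{At}(M₀ − M_ss) with
M_ss = −A⁻¹b, from thermal equilibrium, reading out the water Mz
normalized by its equilibrium value; an unsaturated reference
acquisition therefore reads exactly 1. The acquisition's "3 s + 1 s"
saturation timing is modeled as a single 3 s block: at these exchange
rates the system is within ~1% of steady state at 3 s, so the extra
second changes nothing material. A per-voxel B0 offset enters as a
rigid translation of the spectrum along the offset axis.

The test suite checks this propagator against an independent explicit
RK4 integration of hand-written Bloch–McConnell derivatives at
dt = 5 μs (`tests/oracles.py`); agreement is ~10⁻¹³ on the full
46-offset schedule, far inside the 10⁻⁶ acceptance band.

## Offset schedule

46 saturation offsets within ±10 ppm plus one unsaturated reference:
mirror-symmetric, dense near water (±0.125 to ±1 ppm) for B0
estimation, 0.2 ppm steps across ±(3.4–6.0) ppm so both +4.2 and
−4.2 ppm are well supported, coarse points at ±1.5, ±2.5, ±7, ±10.
The schedule is deliberately uneven (the acquisition it emulates was)
and mirror-symmetric so that asymmetry is not biased by sampling. The
reference is one far-off-resonance unsaturated entry; which volume
normalizes the stack is a declared convention, not something the
emulated protocol specifies.

## Digital phantom

A 64×64×4 voxel grid holds an ellipsoidal brain (unit reference
signal) containing an ellipsoidal tumor (264 voxels by default),
geometry specified in 0-based voxel indices for exactness. The agent
pool appears post-injection with proton fraction 4.898×10⁻⁴ in tumor
and 7.772×10⁻⁵ in brain. These two numbers were calibrated once, by
bisection on the noiseless two-pool model, so that the ground-truth
tumor ΔST at 4.2 ppm is 2.30% — the in vivo iopamidol scale — and the
tumor/brain ΔST ratio is ≈6.2, mirroring the reported in vivo LBR;
they are frozen defaults, not fitted quantities. T1w volumes are
piecewise constant (brain 100, tumor 90) with a 2× post-injection
tumor enhancement factor, giving ground-truth Enh% = 100.

B0 is a smooth in-plane quadratic polynomial (max ≈0.4 ppm),
quantized to 0.01 ppm — the same step as the analysis grid — because
spectra are simulated once per (tissue class, quantized B0) and
reused across voxels; `truth_b0` stores the quantized field actually
used, so B0-recovery scoring is exact. Noise is Rician (independent
Gaussian channels before the magnitude), with per-channel sigma as a
fraction of the unit reference; Gaussian channels make the zero-signal
background Rayleigh, which the tests verify analytically.

What the phantom deliberately omits: magnetization-transfer and NOE
lineshapes (the ΔST subtraction is the mechanism that removes
endogenous contributions, and a single endogenous amide pool suffices
to exercise it), intra-region biological heterogeneity, perfusion
kinetics, motion, and coil/k-space effects. Two consequences to keep
in mind when reading results: phantom ROI standard deviations are
thermal-noise-only, so phantom CNR values are much larger than in vivo
ones and the in vivo CNR/LBR folds are reproduced from the published
group means, not from the phantom; and passing recovery tests shows
the chain is correct and well-conditioned, not that it is robust to
physiology the phantom does not contain.

## Voxelwise analysis chain

1. **Normalization** by the reference volume; voxels with
   non-positive reference, or fewer than 10 finite samples, are
   excluded rather than imputed.
2. **Smoothing-spline fit** (cubic, scipy). Penalty λ = 0
   interpolates; the default selects λ per voxel by generalized
   cross-validation. Because all voxels share one offset grid, the
   smoother hat matrices S(λ) for a fixed log-spaced λ grid
   (10⁻⁸–10², 21 values) are precomputed once per stack and the GCV
   score n‖y − Sy‖²/(n − tr S)² costs a few matrix-vector products
   per voxel; only the final fit at the selected λ is a spline solve.
3. **B0 estimation** within a ±1 ppm window on a 0.01 ppm grid. The
   default estimator is the symmetry centre of the water dip
   (argmin over s of mean_d [Z(s+d) − Z(s−d)]², d ∈ [0.1, 1] ppm):
   at 3 μT the dip bottom is nearly fully saturated
   (Z(0) ≈ 2×10⁻⁵ vs Z(±0.25) ≈ 0.009), so the raw spectrum minimum
   is ill-conditioned under noise and can jitter by ~0.2 ppm, while
   the symmetry centre uses the whole dip shape and recovers shifts
   to ≤0.03 ppm at noise sigma 0.005. `method="argmin"` is retained;
   the two agree to one grid step on clean spectra. Voxels whose
   optimum hits the window boundary are flagged unreliable and
   excluded.
4. **Asymmetry** at Δω = 4.2 ppm on the recentred curve. The default
   normalization is Z(−Δω) (common for iodinated-agent CEST); the
   S0-normalized MTRasym variant is available as `formula="s0"`. The
   choice is echoed into every report sidecar.

ΔST is the voxelwise post − pre difference on the intersected valid
masks; Enh% requires SIpre > 0. Grids must already align: no
registration is performed.

## ROI metrics and conventions

Standard deviations are sample (n−1) throughout — a declared
convention. The LBR denominator has a positivity floor: a brain-ROI
mean ΔST ≤ 0.05% yields NaN with a warning rather than an exploding
ratio. Fold ratios are oriented so both exceed 1 in the regime of
interest (CNR: Gd/iodine; LBR: iodine/Gd) and reported to one decimal
with round-half-even.

## Overlap and agreement

Tanimoto is the Jaccard index as a percentage; volume similarity is
min/max of the two volumes (an alternative 1 − |VA−VB|/(VA+VB) form
is available behind a flag); both are computed voxelwise on a shared
grid without resampling. The pipeline's demonstration segmentations
mimic a reader outlining the coherent enhancing lesion: 1-voxel
in-plane Gaussian smoothing, threshold midway between the brain- and
tumor-ROI means, largest connected component within the tissue
support (voxels above 10% of the brain baseline T1w signal — pure
Rician background would otherwise seed spurious components).

ICC is ICC(2,1): two-way random effects, absolute agreement, single
measurement, computed via pingouin and cross-checked in the tests
against an explicitly summed ANOVA mean-squares oracle to 10⁻¹⁰.
Categories use right-closed intervals (0.8 is "good", not
"excellent"). Degenerate tables (zero total variance) are rejected.

## Problem sizes and seeds

The default phantom (64×64×4, 46 offsets, pre+post) processes in
about a minute per injection phase on one CPU; the unit-test phantom
is 24×24×2 with the same physics. Recovery tests run noise sigma
∈ {0, 0.005, 0.01} with fixed seeds; every random draw in the package
flows through a `numpy` Generator seeded from an explicit integer,
and repeated runs of the same configuration are byte-identical
(gzip members are written with a zeroed timestamp; reports are
canonical sorted-key JSON).

## Known limitations

- Exchange rates are fixed parameters; the pH dependence of amide
  exchange is not modeled (no ratiometric/pH mapping).
- No Lorentzian multi-pool decomposition of Z-spectra; asymmetry only.
- No motion, no registration, no DICOM ingestion.
- The GCV λ grid spans 10⁻⁸–10²; spectra needing penalties outside
  that range would be fit at the grid edge.
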