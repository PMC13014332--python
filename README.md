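# cestpipe

Tumor-enhancement analysis for CEST MRI with an iodinated contrast
agent, built around a fully verifiable digital phantom.

## The problem

Gadolinium-based contrast agents (GBCAs) are the clinical standard for
contrast-enhanced brain-tumor MRI, but concerns about gadolinium
retention motivate alternatives. Iodinated agents such as iopamidol
carry amide protons that resonate 4.2 ppm from water and exchange with
it, so a saturation pulse placed at +4.2 ppm transfers saturation to
the water pool and darkens it — chemical exchange saturation transfer
(CEST). Comparing the CEST read-out of an iodinated agent against the
T1w read-out of a GBCA in a glioblastoma model requires a processing
chain whose every stage (spectral fitting, field-inhomogeneity
correction, asymmetry contrast, ROI metrics, segmentation agreement)
can be validated. In vivo there is no ground truth for any of these;
this package therefore pairs the analysis chain with a Bloch–McConnell
digital phantom in which the true contrast, field map and tumor mask
are known exactly.

## What it computes

**Z-spectrum analysis (per voxel).** The normalized water signal
Z(Δω) = S(Δω)/S₀ is sampled at 46 unevenly spaced offsets within
±10 ppm, fitted with a cubic smoothing spline (penalty chosen by
generalized cross-validation), recentred by the per-voxel B0 shift
(estimated from the symmetry centre of the water dip), and reduced to
the asymmetry contrast

    ST% = [Z(−Δω) − Z(+Δω)] / Z(−Δω) × 100,   Δω = 4.2 ppm.

Post- minus pre-injection maps give ΔST, cancelling endogenous CEST;
T1w enhancement is Enh% = (SIpost − SIpre)/SIpre × 100.

**ROI metrics.** CNR = (m_tumor − m_brain)/√(sd²_tumor + sd²_brain),
on T1w signal and on ST% alike; LBR = tumor/brain ratio of ROI means
(SIpost for T1w, ΔST for CEST); agent fold ratios CNR_Gd/CNR_iodine
and LBR_iodine/LBR_Gd, rounded to one decimal.

**Segmentation agreement.** Tanimoto (intersection over union, %),
Dice 2|A∩B|/(|A|+|B|), volume similarity min/max; the identity
D = 2T/(1+T) is enforced in tests. Reader agreement on measurement
tables uses ICC(2,1) (two-way random, absolute agreement) bucketed as
poor ≤ 0.2 < fair ≤ 0.4 < moderate ≤ 0.6 < good ≤ 0.8 < excellent.

**Phantom.** Multi-pool continuous-wave Bloch–McConnell simulation
(matrix-exponential propagation; water + endogenous 3.5 ppm amide +
exogenous 4.2 ppm agent pool), 7 T, 3 μT / 3 s saturation, a smooth
polynomial B0 field, Rician noise, and 2× post-injection T1w tumor
enhancement. Defaults are calibrated so the ground-truth tumor ΔST is
2.3% — the scale reported in vivo for iopamidol in glioblastoma.

## Worked example

```python
import numpy as np
from cestpipe import (PhantomSpec, generate_phantom, compute_st_map,
                      compute_delta_st, compare_agents, MapKind)

ds = generate_phantom(PhantomSpec(noise_sigma=0.005, seed=7))
st_pre, _  = compute_st_map(ds.cest_pre,  kind=MapKind.ST_PRE)
st_post, _ = compute_st_map(ds.cest_post, kind=MapKind.ST_POST)
delta = compute_delta_st(st_post, st_pre)
sel = ds.truth_tumor_mask & delta.valid_mask
print(f"tumor dST {delta.values[sel].mean():.2f}% "
      f"(truth {ds.truth_delta_st[ds.truth_tumor_mask].mean():.2f}%)")

cmp_ = compare_agents(cnr_iop=3.3, cnr_gd=6.8, lbr_iop=6.2, lbr_gd=2.3)
print(f"CNR fold {cmp_.cnr_fold_rounded}, LBR fold {cmp_.lbr_fold_rounded}")
```

prints

```
tumor dST 2.19% (truth 2.30%)
CNR fold 2.1, LBR fold 2.7
```

The recovered tumor ΔST agrees with the simulated ground truth to ~5%
at this noise level, and the fold ratios computed from the published
in vivo group means (CNR 6.8 vs 3.3, LBR 6.2 vs 2.3) round to the
reported 2.1-fold GBCA advantage in CNR and 2.7-fold iodinated-agent
advantage in LBR.

The same stages are scripted as a narrative under `analysis/`
(01 simulate → 02 maps → 03 metrics → 04 overlap/agreement), writing
tables to `results/` and volumes to `scratch/`. A `cest` CLI exposes
each stage (`cest simulate`, `cest st-map`, `cest delta-st`,
`cest enh-map`, `cest metrics`, `cest overlap`, `cest agreement`,
`cest run-all --config run.yaml`).

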