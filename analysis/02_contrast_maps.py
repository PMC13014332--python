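#!/usr/bin/env python
"""Compute ST/dST/Enh contrast maps from the simulated acquisition.

Runs the voxelwise chain (reference normalization, GCV smoothing
spline, B0 correction via the dip symmetry centre, asymmetry at
4.2 ppm) on the phantom written by 01_simulate_phantom.py, then scores
the recovered maps against the known ground truth.  Maps are written
next to the simulation under scratch/run/maps; the recovery table goes
to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from cestpipe import run_analysis
from cestpipe import io as cio

sys.path.insert(0, str(Path(__file__).parent))
from importlib import import_module

sim = import_module("01_simulate_phantom")


def main():
    report = run_analysis(sim.CONFIG)
    out = sim.OUT
    truth_delta = cio.load_nifti(out / "sim" / "truth_delta_st.nii.gz")
    truth_b0 = cio.load_nifti(out / "sim" / "truth_b0.nii.gz")
    tumor = cio.load_mask(out / "sim" / "truth_tumor_mask.nii.gz")
    brain = cio.load_mask(out / "sim" / "truth_brain_mask.nii.gz")
    delta = cio.load_contrast_map(out / "maps" / "delta_st.nii.gz")
    b0 = cio.load_nifti(out / "maps" / "b0.nii.gz")

    rows = []
    for name, mask in (("tumor", tumor), ("brain", brain & ~tumor)):
        sel = mask & delta.valid_mask
        est = float(delta.values[sel].mean())
        tru = float(truth_delta[mask].mean())
        rows.append({
            "region": name,
            "delta_st_estimated_pct": round(est, 4),
            "delta_st_truth_pct": round(tru, 4),
            "relative_error_pct": round(abs(est - tru) / abs(tru) * 100, 2),
        })
    sel = brain & np.isfinite(b0)
    b0_err = np.abs(b0 - truth_b0)[sel]
    table = pd.DataFrame(rows)
    table.to_csv(sim.RESULTS / "02_map_recovery.csv", index=False)

    print(table.to_string(index=False))
    print(f"B0 recovery: max |error| = {b0_err.max():.3f} ppm, "
          f"mean = {b0_err.mean():.4f} ppm (noise sigma 0.005)")
    print(f"tumor-mean Enh% = {report['roi_stats']['enh.tumor']['mean']:.1f} "
          "(ground truth 100, 2x T1w enhancement)")


if __name__ == "__main__":
    sys.exit(main())
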