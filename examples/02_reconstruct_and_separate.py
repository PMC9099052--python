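"""Reconstruct undersampled k-t data and separate water from fat.

Solves the low-rank + total-variation regularized SENSE problem on the
8-fold undersampled phantom acquisition, then applies two-point Dixon to
the dual-echo images.  The printed errors compare against the phantom's
ground truth: the regularized solution should clearly beat the zero-filled
baseline.
"""

import numpy as np

from fosters import dixon, metrics, phantom, recon, sampling
from fosters.config import PhantomConfig, ReconConfig

cfg = PhantomConfig(seed=7)
pattern = sampling.generate_kt_mask(*cfg.grid_size, cfg.n_frames, R=8,
                                    center_fraction=0.04, seed=7)
truth, kt = phantom.simulate_acquisition(cfg, pattern)
composite = np.abs(phantom.simulate_dual_echo(truth, cfg.acquisition).data)

zf = recon.zero_filled(kt)
series = recon.solve_lrs(kt, ReconConfig(alpha=1.0, beta=0.005, n_iter=50))
pair = dixon.separate_water_fat(series, kt.acq)

print(f"zero-filled NRMSE:      {metrics.nrmse(zf.data, composite):.4f}")
print(f"low-rank + TV NRMSE:    {metrics.nrmse(series.data, composite):.4f} "
      "(vs truth echo images; lower is better)")
print(f"objective decreased monotonically: "
      f"{bool(np.all(np.diff(series.objective_log) <= 1e-3))}")
ff = dixon.fat_fraction(pair)
band = truth.masks == 4
print(f"fat fraction in the fat layer: {np.nanmean(ff[band]):.2f} "
      "(water-dominant tissue reads ~0, fat ~1)")
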