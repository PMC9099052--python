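# fosters

Motion-corrected, spatio-temporally accelerated, dual-echo Dixon
**quantitative first-pass myocardial perfusion** — a complete, tested
pipeline exercised end-to-end on a digital cardiac phantom with known
ground-truth motion and myocardial blood flow.

First-pass perfusion cardiac MR images a gadolinium bolus transiting the
heart, one frame per heartbeat, and converts myocardial enhancement into
blood flow (MBF, mL/min/g). Two things make this hard: the first pass does
not fit in a breath-hold (respiratory motion), and high in-plane resolution
requires heavy undersampling. This package implements a free-breathing
answer to both and the quantification chain behind it, for researchers who
want a reproducible, inspectable reference implementation of every stage:

- **Digital phantom** — short-axis slice with RV/LV blood pools, a
  myocardial annulus (with an optional hypoperfused sector at
  Fp = 0.5 mL/min/g), epicardial/subcutaneous fat, a gamma-variate bolus,
  two-compartment-exchange tissue kinetics, dual-saturation dual-echo
  saturation-recovery signal formation with concentration-dependent T2*
  loss, translational breathing, multi-coil encoding and 8× dynamically
  varying Cartesian ky undersampling.
- **Reconstruction** — solves

  `x̂ = argmin_x ½‖Ex − k‖² + α‖x‖_* + β‖Ψx‖₁`

  with `E` the SENSE encoding operator, `‖·‖_*` the nuclear norm of the
  space×time Casorati matrix (temporal low rank) and `Ψ` spatial
  anisotropic total variation (α = 1, β = 0.005 after normalization), by a
  monotone proximal-gradient scheme; a wavelet-only compressed-sensing
  comparator is included.
- **Water–fat separation** — flexible-TE two-point Dixon (the 1.1/1.9 ms
  echoes at 3 T are ~125° apart in fat phase) with region-growing phasor
  disambiguation.
- **Motion correction** — translation estimated on the contrast-stable
  fat-only images (normalized gradient fields) and applied to the raw
  k-space as exact linear phase shifts; 10-iteration reconstruction for the
  estimation pass, 50 for the final images; non-rigid refinement against a
  PCA-based motionless surrogate series.
- **Quantification** — T2*-corrected AIF from the low-resolution
  short-saturation image, saturation-recovery signal-to-concentration
  conversion, Bayesian two-compartment-exchange (2CXM) fitting
  (`C_t = Fp·(h ⊛ C_a)`, bi-exponential impulse response from the
  compartmental rate matrix), pixel-wise MBF maps and AHA segment tables.

## Worked example

`examples/04_quantify_mbf.py` runs the whole chain on the default phantom
(96×96, 40 frames, R = 8, 5 px breathing, 60° defect sector at
0.5 mL/min/g centered on segment 4):

```
per-segment MBF (mL/min/g), estimated vs programmed:
 segment  mbf_mean  mbf_truth  n_pixels
       1      0.85       1.00        97
       2      0.80       1.00       100
       3      1.06       1.00        95
       4      0.52       0.51        97
       5      0.80       0.99       100
       6      0.87       1.00        95

motion residual: 0.26 px RMS
defect sector mean: 0.50 vs remote 0.88 mL/min/g (the hypoperfused sector must read lower)
estimated AIF peak: 5.36 mM (programmed 5.0 mM)
```

The 5 px programmed breathing is recovered to a quarter pixel, the
arterial input function to a few percent, and the hypoperfused segment
reads at its programmed flow while remote segments cluster around the
programmed 1.0 mL/min/g (their residual scatter is dominated by temporal
crosstalk of the k-t reconstruction; see `docs/methods.md`). The other
examples exercise the stages separately:

```bash
python examples/01_simulate_phantom.py      # acquisition simulation
python examples/02_reconstruct_and_separate.py  # recon + Dixon
python examples/03_motion_correction.py     # rigid motion estimation
python examples/04_quantify_mbf.py          # full pipeline
```

A thin CLI mirrors the library (`fosters simulate|mask|recon|dixon|moco|
quantify|sharpness|run|evaluate`); run `fosters --help`.

## Layout

```
src/fosters/
  config.py      dataclass configs (YAML round-trip, protocol defaults)
  containers.py  k-space, image-series, curve and map containers
  phantom.py     digital perfusion phantom + acquisition simulation
  sampling.py    variable-density k-t undersampling masks
  fourier.py     centered orthonormal FFTs, sub-pixel shifts
  recon.py       low-rank+TV and wavelet-CS SENSE reconstruction
  dixon.py       flexible-TE two-point water-fat separation
  motion.py      NGF translation estimation, k-space phase correction,
                 PCA-surrogate non-rigid refinement
  quant.py       T2*, signal<->concentration, 2CXM, MBF maps, AHA segments
  metrics.py     edge sharpness, NRMSE
  io.py          HDF5 / NIfTI / CSV containers
  pipeline.py    two-pass orchestration + evaluation reports
  cli.py         command-line front end
```

`docs/methods.md` documents the models, defaults, numerical choices and
known limitations in detail.
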