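# jmoct

Analysis tools for Jones-matrix (polarization-sensitive) and
spectral-domain optical coherence tomography, built for quantitative
tissue characterization in small-animal imaging — e.g. distinguishing
tumor from healthy tissue in adult zebrafish by their scattering and
polarization signatures.

The package covers the full processing chain from raw measurement to
statistics, and ships a first-class synthetic-data module so that every
stage can be validated against known ground truth without any external
data:

* **Phantom generation** (`jmoct.synthetic`) — layered speckled media with
  prescribed attenuation, birefringence, polarization scrambling and
  detector noise; raw spectral fringes; two-region tumor/control datasets
  with per-B-scan masks.
* **JM-OCT contrasts** (`jmoct.contrasts`) — scatter intensity, the
  depth-resolved attenuation coefficient, local birefringence with a
  per-pixel reliability (naive and maximum-a-posteriori estimators), and
  the degree of polarization uniformity (DOPU).
* **SD-OCT reconstruction** (`jmoct.recon`) — k-linearization, Gaussian
  spectral shaping, numerical dispersion compensation, average-spectrum
  subtraction, Fourier transformation.
* **Mosaicking** (`jmoct.mosaic`) — phase-correlation registration of
  laterally overlapping volume tiles (5% default overlap) and feather
  blending into a large field-of-view canvas.
* **Region statistics** (`jmoct.stats`) — mask application, per-B-scan
  region means, box-whisker summaries, Mann–Whitney U and Levene tests.
* **Rendering** (`jmoct.render`) — reliability-gated pseudo-color
  birefringence tomograms, intensity/DOPU composites, en-face projections.

## The core quantities

For a measured round-trip Jones matrix J(z) per voxel:

* **Scatter intensity** — the four polarization channels averaged,
  `I = (|J00|² + |J01|² + |J10|² + |J11|²) / 4`.
* **Attenuation coefficient** (depth-resolved, tail-normalized) —
  `µ(i) = I(i) / (2Δ Σ_{j>i} I(j))` with Δ the axial pitch in mm,
  assuming full attenuation within the recorded depth.  On a discrete
  exponential this converges to `(e^{2µΔ} − 1)/(2Δ)`; the exact inversion
  of that discretization bias is available as `debias=True`.
* **Local birefringence** — the eigen-phase difference
  `δ = |arg λ₁ − arg λ₂| ∈ [0, π]` of the local matrix
  `L(z) = J(z+d) J(z)⁻¹`, converted to a refractive-index difference
  `Δn = δ λ₀ / (4π d Δz)`.  Only the eigenvalue phases are used, so the
  estimate is invariant to the unknown unitary system birefringence.  The
  MAP variant replaces the raw eigen-phase with the posterior mode under
  a Monte-Carlo tabulated noise model at the measured local SNR, removing
  most of the positive noise bias near δ = 0.
* **DOPU** — per incident channel, normalized Stokes vectors
  `(Q, U, V)/I` are averaged over a small (z, x) kernel and
  `DOPU = √(Q̄² + Ū² + V̄²)`; 1 means polarization preserving, values
  near 0 mean scrambling.

## Worked example

Generate a synthetic two-region dataset in which the tumor-like region
has lowered birefringence, lowered scrambling and raised attenuation
relative to a muscle-like control region, then quantify it:

```python
import numpy as np
from jmoct import generate_tumor_control_dataset, analyze_tumor_control

jones, masks, truth = generate_tumor_control_dataset(n_bscans=32, seed=5)
report = analyze_tumor_control(jones, masks, noise_power=10**-2.5)
for name in ("attenuation", "birefringence", "dopu"):
    cs = report.contrasts[name]
    t = np.median(cs.means["tumor"]); c = np.median(cs.means["control"])
    print(f"{name:14s} tumor median {t:.4g}  control median {c:.4g}  "
          f"MW p {cs.p_mann_whitney:.3g}  Levene p {cs.p_levene:.3g}  ({cs.direction})")
```

prints

```
attenuation    tumor median 2.824  control median 2.279  MW p 6.51e-12  Levene p 0.285  (tumor > control)
birefringence  tumor median 0.004884  control median 0.00729  MW p 6.51e-12  Levene p 0.891  (tumor < control)
dopu           tumor median 0.8103  control median 0.7735  MW p 6.51e-12  Levene p 0.3  (tumor > control)
```

Each data point entering the tests is the mean of one contrast over the
annotated region of one B-scan (32 per group here).  The tumor region is
reported with significantly lower birefringence and higher DOPU, and
higher attenuation — the expected direction for each contrast.  Note the
absolute birefringence medians exceed the generating ground truth
(0.8·10⁻³ / 1.8·10⁻³): at finite SNR the naive eigen-phase estimator is
positively biased and polarization scrambling adds apparent retardation;
see `docs/methods.md`.

`report.to_json(...)`, `report.to_csv(...)` and
`jmoct.stats.plot_boxes(report, "boxes.png")` export the numbers and the
box-whisker figure.  The mosaicking and rendering stages are also
available from the shell: `jmoct stitch --tiles a.tiff --tiles b.tiff
--overlap 0.05 --out mosaic.tiff` and `jmoct render --jones vol.h5
--contrast birefringence --out biref.png`.

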