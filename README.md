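# retfdc

Zone-specific **circular fractal dimension (FDC)** of optic-disc-centred
retinal fundus images, with spectral and box-counting comparators and
rank-based case/control statistics.

## The problem

The complexity of the retinal microvasculature is a window onto the state of
small vessels elsewhere in the body: rarefaction — loss of branching density —
has been associated with cardiovascular disease, including future stroke.
Classical fractal measures of fundus images (box-counting on a segmented
vessel mask, or the spectral slope of the whole image) summarise the entire
photograph with a single number and cannot target a specific region, yet
vascular change is known to be most informative in particular annuli around
the optic disc (OD).

`retfdc` implements a zone-specific estimator.  The fundus image is reduced
to its inverted green channel, cropped to a region of interest of 4 OD
diameters centred on the disc and downsampled to 400×400.  A bank of 2D
Gabor wavelets (5 scales × 18 orientations, elongation ε = 4, wave vector
k₀ = (0, 3)) acts as a directional matched filter; the per-scale
orientation-maxima are z-normalised and combined by a two-component Gaussian
mixture into a 0–255 *posterior vessel image*.  That image is then scanned
along concentric circles of integer radii, from one pixel outside the OD
boundary out to 2 OD diameters from the centre.  Each circle's 1D intensity
profile gets a **Higuchi fractal dimension**: with curve length at delay *k*

```
L_m(k) = [ Σ_{i=1..M} |X(m+ik) − X(m+(i−1)k)| · (N−1)/(M·k) ] / k ,   M = ⌊(N−m)/k⌋,
```

FD = −slope of log L(k) vs log k (delays 1..k_max, k_max = 8).  Circles are
grouped into three concentric zones by their offset from the OD margin in
units of the OD diameter D_OD — A: (0, 0.5], B: (0.5, 1.0], C: (1.0, 1.5] —
and the FDC of a zone (or any of the seven combinations A, B, C, AB, AC, BC,
ABC) is the mean per-circle FD over its circles.  Because the scan circles
cut the predominantly radial vessels across their cross-section, the profile
roughness — and hence FDC — rises with branching complexity.

Case/control FD tables are compared with the tie-corrected Kruskal–Wallis
*H* test (per-group medians, average ranks and z-scores) and a Mann–Whitney
confidence interval for the difference in medians (Hodges–Lehmann shift
estimate, exact-rank endpoints).

No clinical images ship with the package: a synthetic-data module generates
OD-centred phantoms with radially growing, stochastically bifurcating
vessel trees whose branching probability is the controllable complexity
parameter, plus 1D/2D fixtures of analytically known fractal dimension
(fractional Brownian motion, Sierpinski rasters, power-law-spectrum images)
used to validate every estimator.

## Worked example

```python
import numpy as np
from retfdc import (FundusSynthParams, RunConfig, default_case_control_params,
                    gen_cohort, gen_synthetic_fundus, gen_fbm_series,
                    higuchi_fd, run_single, run_cohort)

# 1. the 1D estimator on a signal of known dimension
x = gen_fbm_series(hurst=0.5, n=2000, seed=1)
print(f"Higuchi FD of an fBm path (H=0.5): {higuchi_fd(x):.3f}")

# 2. full pipeline on one synthetic fundus image
img, od = gen_synthetic_fundus(FundusSynthParams(seed=0))
rec = run_single(img, od, RunConfig(methods=("fdc",)), subject_id="demo")
print(f"FDC_A={rec['fdc_A']:.3f}  FDC_B={rec['fdc_B']:.3f}  "
      f"FDC_C={rec['fdc_C']:.3f}  FDC_ABC={rec['fdc_ABC']:.3f}")

# 3. a small case/control cohort (cases have halved branching probability)
case_p, control_p = default_case_control_params()
cohort = gen_cohort(10, 10, case_p, control_p, seed=42)
table, report = run_cohort(cohort, RunConfig(methods=("fdc",)))
row = report[report["zone"] == "ABC"].iloc[0]
print(f"cohort FDC_ABC: median(case)={row['median_case']:.3f} "
      f"median(control)={row['median_control']:.3f}  H={row['H']:.2f}  p={row['p']:.4f}")
print(f"95% CI for median(case) - median(control): ({row['ci_low']:.4f}, {row['ci_high']:.4f})")
```

Output:

```
Higuchi FD of an fBm path (H=0.5): 1.510
FDC_A=1.350  FDC_B=1.308  FDC_C=1.445  FDC_ABC=1.368
cohort FDC_ABC: median(case)=1.262 median(control)=1.333  H=11.57  p=0.0007
95% CI for median(case) - median(control): (-0.0930, -0.0351)
```

The fBm path's estimate sits at its theoretical dimension 2 − H = 1.5.  In
the cohort, cases (branching probability halved, modelling rarefaction) have
a lower median FDC than controls; the Kruskal–Wallis test rejects equality of
medians and the Mann–Whitney interval for the median difference excludes
zero.  Positive FDC differences track branching complexity; absolute FDC
values on these phantoms are lower than on real fundus photographs, whose
posterior images carry much more fine-grained texture.

A command-line interface mirrors the stages:

```sh
retfdc simulate --n-case 5 --n-control 5 --seed 1 --out data/
retfdc enhance data/case_000.png post.png --annotations data/annotations.csv --image-id case_000
retfdc fd data/case_000.png --method fdc,sfd,bc --annotations data/annotations.csv \
       --image-id case_000 -o fd.csv
retfdc run-all --manifest data/manifest.csv --out results/
```

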