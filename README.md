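# bcdquant

Quantitative analysis of the *Drosophila* Bicoid (Bcd) morphogen system on
synthetic data with known ground truth: single-molecule FISH-style particle
detection in 3D confocal stacks, nuclear protein-gradient extraction, and an
extended synthesis–diffusion–degradation (SDD) reaction–diffusion model fit
by exhaustive χ² grid search.

The package is aimed at quantitative developmental biologists and
biophysicists who want a tested, seedable re-implementation of this analysis
chain — every stage can be scored against the generating truth, because the
package ships its own forward models of the microscopy.

## What it computes

**mRNA particles.** *bcd* mRNA is packaged into diffraction-limited RNP
particles forming a steep anterior gradient (density peaking near 7% egg
length, essentially zero beyond 40% EL). The detector reproduces the
standard spot-calling chain: per-slice balanced difference-of-Gaussians
filtering (center σ 1.5 px, surround 2.5 px; zero response to constant
background), thresholded strict local maxima, "shadow" linking of the same
particle across neighboring z-slices (the axial PSF makes each true particle
appear on 2–5 slices), elliptical-Gaussian fitting on 9×9 patches
(`I(x, y) = offset + amplitude · G(x−x_c, y−y_c, r_x, r_y, θ)`), joint
fitting of overlapping candidates, and acceptance filters
(0.7 px < r_x, r_y < 2.5 px; amplitude > offset; ≥1 shadow). Particle
intensity is `amplitude · r_x · r_y`.

**Nuclear gradients.** Nuclear Bcd-GFP follows `C(x) = A · exp(−(x/L)/λ)`
with λ ≈ 0.15 EL in fixed tissue. The pipeline segments nuclei, corrects
depth attenuation with the uniform Histone-RFP channel, subtracts the
autofluorescence background measured from 85–95% EL nuclei, and fits (A, λ)
per nuclear cycle by weighted log-linear regression over x/L ∈ [0.1, 0.7].

**SDD model.** Protein dynamics obey `∂c/∂t = D∇²c − c/τ + ρ(r)` on an
ellipsoidal embryo (10 µm grid, no-flux boundaries), with the source ρ built
from mRNA particle tables and the "extended" model allowing D, τ and the
source to switch at specified nuclear cycles. Model profiles are compared to
measurements through a scale-optimized χ² (single global scale fit on
n.c. 7–12, χ² summed over n.c. 7–14) and parameters are found by exhaustive
grid search over (D, τ, T_src_on, T_src_off, T_diff_off).

## Worked example

```python
from bcdquant import workflows

r = workflows.detection_run("cup", seed=1, n_particles=600)
print(f"truth particles: {r['n_truth']}")
print(f"accepted particles: {r['n_accepted']}")
print(f"detected intensity fraction at x/L<=0.2: {r['detected_cum_02']:.3f}")
print(f"posterior (x/L>0.4) intensity share: {r['detected_posterior_share']:.4f}")

dyn = workflows.best_fit_dynamics(seed=1)
print(f"amplitude(nc12)/amplitude(nc8): {dyn['amp_ratio_12_8']:.2f}")
print(f"amplitude(nc14)/peak: {dyn['amp_14_over_peak']:.2f}")
```

prints

```
truth particles: 600
accepted particles: 419
detected intensity fraction at x/L<=0.2: 0.950
posterior (x/L>0.4) intensity share: 0.0064
amplitude(nc12)/amplitude(nc8): 2.69
amplitude(nc14)/peak: 0.82
```

The first block renders a blastoderm-stage half-embryo stack (cortical
"cup" mRNA geometry), detects particles after gain normalization, and
projects them onto the anterior–posterior axis: 95% of detected fluorescence
sits in the anterior 20% of the egg and well under 1% in the posterior 60%.
Detection recovers ~70% of particles at this reduced scale (the rest are
unresolvable overlaps); the *intensity fractions* are the robust readout.
The second block runs the best-fit extended SDD scenario (D = 3.1 µm²/s,
τ = 100 min, source on n.c. 7–13, diffusion shut off at n.c. 11): the
gradient amplitude roughly triples from n.c. 8 to n.c. 12 and decays to
~3/4–0.8 of its peak by n.c. 14.

A CLI wraps the same stages:

```bash
bcdquant simulate-images --seed 1 --out sim/
bcdquant detect --stack sim/stack.tiff --out det/
bcdquant full-demo --seed 1 --out demo/
```

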