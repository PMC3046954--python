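# Methods

This note documents the models behind `bcdquant`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic mRNA particle fields (`synthgen`)

The generator encodes the measured large-scale facts of the *bcd* mRNA
distribution rather than any mechanistic model of RNP transport.

**AP marginal.** The main component is a Gamma density on x/L truncated at
0.4 EL (particle density is essentially zero beyond 40% egg length):

| configuration | shape | scale | mode | geometry |
|---|---|---|---|---|
| early cleavage (pre-n.c. 7) | 3.5 | 0.028 | 0.07 EL | wedge (interior) |
| blastoderm | 2.8 | 0.045 | 0.08 EL | cup (cortical shell) |

Both peak near 7% EL, with the blastoderm mode slightly posterior (the mild
posterior shift seen during cortical relocalization). A further 2% of
particles are single-mRNA "strays" scattered uniformly along the whole
axis, emulating the sparse dim particles detectable even near the posterior
pole; they carry well under 1% of total intensity.

**Intensity model.** Each particle carries `n_mrna` transcripts drawn from
a rounded lognormal (σ_log = 0.55, clipped to [1, 60]) whose median decays
with position as `exp(−(x/L)/0.12)` — brighter particles sit anterior.
Medians are 8.0 (early) and 5.8 (blastoderm): the blastoderm value is set so
that 110,000 blastoderm particles carry the same total intensity as 70,000
early particles (particle disassembly conserves mRNA). The medians were
calibrated by Monte Carlo so that, after integer rounding, the
intensity-weighted anterior-20% share is ≈0.98 (early) and ≈0.93
(blastoderm), and the posterior-60% share stays below 1%. Peak photon
amplitude is `1500 · n_mrna`.

**Geometry.** Stacks represent one embryo half: x spans the egg length L
(default 500 µm), y the width (180 µm), z the depth from the midsagittal
plane to the surface. Wedge mode draws the radial position from Beta(1.5, 2)
(interior-enriched anterior cone); cup mode places particles within a
half-normal shell (σ = 12 µm, max 25 µm) below the surface. Ground truth
records position, x/L, cortical distance d/L, `n_mrna` and amplitude.

**Rendering.** Particles are 3D Gaussians (lateral σ 1.1 px ≈ 200 nm FWHM at
75.7 nm pixels; axial σ 1.0 slice at 420 nm z-steps), added to a background
of 100 photons modulated by a smooth low-frequency autofluorescence field
(±30%), passed through Poisson noise, per-slice gain, and optional Gaussian
read noise. The smooth field matters: without spatial variation of the mean
the patch mean–variance gain estimate is degenerate. The absolute photon
budget is a package choice (real photon counts are instrument-specific); it
was fixed once so that, in gain-normalized units, a single-mRNA particle has
a DoG response of ≈280 with its z±1 shadows above the detection threshold of
150 — giving the characteristic 1–2 shadows per dim particle and up to 5
occupied slices for ~10× brighter ones.

**Desk scale.** Default stacks are 512×512×20 (2048×2048 is supported).
Because this compresses the acquisition ~12× axially and ~13× laterally,
using the full-embryo counts (70k/110k per embryo) would produce overlap
densities the imaging never has. The desk defaults are 955 (early) and 1500
(blastoderm) particles per half-stack — preserving the 70:110 count ratio
and the constant-intensity budget while keeping nearest-neighbor distances
detectable. The intensity *fractions* along the AP axis are insensitive to
the count; absolute recall at desk scale is ~70% (the remainder are genuine
sub-resolution overlaps).

**Nuclear stacks.** Spherical nuclei on a jittered grid with random depth;
GFP per nucleus `A·exp(−(x/L)/λ) + background` (defaults A = 400, λ = 0.15,
background 40), RFP uniform (200); both attenuated as `exp(−depth/50 µm)`;
3% multiplicative Gaussian noise. Nuclei at 85–95% EL carry effectively
background-only GFP, by the exponential itself.

## Stack conditioning (`preprocess`)

**Realignment.** Stage drift is undone by maximizing the cross-correlation
between successive z-slices over integer shifts in a ±5 px window; per-step
shifts accumulate outward from slice 0. Slices are lightly smoothed (σ 2 px)
and mean-subtracted before correlating so that pixel noise cannot dominate;
ties prefer the smaller shift. Subpixel alignment is not attempted because
detection refits positions anyway.

**Gain normalization.** For Poisson-dominated data the variance of a small
patch grows linearly with its mean, with slope equal to the raw-units-per-
photon conversion. Patches (5×5, up to 2×10⁴ per slice) are sampled from the
posterior part of each slice — anterior particles are structured signal, not
shot noise — and the line is fit with iterative outlier rejection for the
same reason. Per-slice slopes are smoothed with a moving median (the optical
path changes slowly with depth) and each slice divided by its gain, making
the detection threshold acquisition-independent. Whether one factor per
slice or per stack is used is configurable; per-slice is the default.

## Particle detection (`spotdetect`)

Conventions that the data do not fix by themselves:

* The Gaussian "radii" r_x, r_y are **σ** parameters. The reported diameter
  is the mean FWHM, `2.355·(r_x+r_y)/2`, which makes the default PSF read
  ~2.6–3 px, matching the observed ~3 px particle extent.
* Shadow linking uses xy radius 2 px and z window ±2 slices (axial σ ≈ 1
  slice), iterating brightest-first; brightness ties break lexicographically
  by (z, y, x). The surviving central candidate carries `n_shadows`; the
  acceptance filter requires at least one (i.e. detection on ≥2 slices).
* Local-maxima plateaus contribute one candidate at their lexicographically
  smallest coordinate.
* Joint fits trigger when candidates share a prospective 9×9 patch
  (union-find over same-slice candidates within 8 px); the joint patch is
  the candidates' bounding box plus a 4 px margin, capped at 6 components
  (excess candidates fall back to single fits). Components that collapse
  onto each other within 0.6 px are merged. A failed joint optimization
  falls back to independent single fits.
* Fit initialization: candidate position, r = 1.3 px, offset = patch
  median, amplitude = peak − median; bounds r ∈ [0.3, 5] px, amplitude ≥ 0.
  Non-converged fits are flagged and rejected.

A note on resolution: with the balanced DoG at center σ 1.5 / surround σ
2.5 px, two equal spots 3 px apart produce a *single* filter maximum (the
midpoint response exceeds the peaks); 4 px is the closest equal pair the
filter resolves. Overlaps below that are handled — if at all — by the joint
fit once at least two candidates exist.

## Spatial statistics (`spatialstats`)

x/L is the normalized projection onto the AP axis (extracted from an
overview mask via the principal axis of the pixel covariance, or supplied
directly for synthetic stacks where the transform is known); bins are 50
equal intervals, half-open with the last bin closed. The cortical distance d
is measured along the ray from the embryo center to the elliptical outline —
exact for circular cross-sections and consistent between projection and the
shell-area normalization of the depth-density profile, which integrates
`½[(r_b−d₀)² − (r_b−d₁)²] dφ` over the boundary radius. Half-embryo counts
carry an explicit ×2 column for whole-embryo totals.

## Nuclear gradients (`nucgrad`)

Segmentation is Gaussian smoothing (σ 1.5 lateral, 0.75 axial), a global
Otsu threshold, 3D labeling, and — at blastoderm stages (n.c. ≥ 10) — a
distance-transform watershed to split touching nuclei; objects below 30% of
the median volume are discarded. Masks are eroded by one voxel before
measuring so that threshold halos do not dilute the channel means; residual
partial-volume averaging still scales absolute intensities by an
O(10–20%) factor, which cancels in the decay length and in any
attenuation- or background-relative quantity.

Attenuation correction fits an exponential to mean RFP versus depth
(log-linear least squares), falling back to monotone binned medians when the
exponential describes the binned medians poorly; the correction factor is
normalized at the mean depth of the shallowest decile, so surface nuclei are
essentially untouched. Background is the mean corrected GFP of 85–95% EL
nuclei. The exponential profile fit runs on binned means over
x/L ∈ [0.1, 0.7] (avoiding anterior saturation and the background window),
weighted by the squared bin mean — the natural weights for log-transformed
relative errors. Recovery from the default synthetic stack returns
λ = 0.15 ± 0.02; a λ = 0.20 generator (live-tissue-style gradient) is
recovered distinguishably, with a small downward bias because the
85–95% EL background window still contains a little true signal at that
decay length.

## SDD model (`sddsim`)

Forward Euler on an ellipsoidal voxel mask (default 500×180×180 µm at
10 µm), masked 6-neighbor Laplacian with no-flux boundaries implemented by
dropping out-of-mask links — this conserves mass exactly, and the suite
verifies the discrete balance to 1e-6 and the 1D steady-state decay length
√(Dτ) to 5%. The time step respects dt ≤ 0.8·Δx²/(6D) plus caps from τ and
the maturation rate. Developmental time maps nuclear cycles to interphase
durations (8 min for n.c. 1–9; 9, 10, 12, 20, 20 min for n.c. 10–14);
snapshots are taken at the end of each cycle and projected to AP-slab means.
Sources are volumetric rate densities normalized to a constant total
strength (grid-resolution independent); realistic sources spread each AP
slab's particle intensity uniformly over the slab cross-section, and the
nearest measured cycle's geometry is reused for unmeasured cycles. The
optional maturation variant integrates an immature species carrying the
source and a mature species fed at rate k (default 1/20 min⁻¹, a ~20 min
fluorophore maturation delay); k → large reproduces the single-species
solution.

**Best-fit configuration.** The package default is D = 3.1 µm²/s, τ = 100
min, source active n.c. 7–13, diffusion shut off (to 0; 0.3 µm²/s optional)
at n.c. 11. The plausible best-fit ranges (source on 6–7, off 12–13,
shutoff 11–12, τ 100–140) were scanned exhaustively; the combination above
is the one whose simulated dynamics best reproduce the documented gradient
behavior — a ~3-fold amplitude rise from n.c. 8 to n.c. 12 and a late
decline to ~3/4 of peak. With the shutoff at n.c. 12 instead, the amplitude
ratio collapses to ~1.5 because continued spreading dilutes the anterior
rise.

**A real limitation.** The measured nuclear gradients keep a nearly
constant decay length (~0.15 EL, <10% drift) from n.c. 8 onward. The
simulated profiles do not: at n.c. 8 the profile is still spreading
diffusively (fitted λ ≈ 0.08 EL, en route toward the steady-state
√(Dτ) ≈ 0.27 EL) until the diffusion shutoff freezes it near 0.11–0.13 EL.
Under *every* configuration in the ranges above the maximal relative drift
over n.c. 8–14 is ≥34% (≈46% for the default). This is transient physics of
a compact source under the extended SDD model, not a solver artifact; the
acceptance script reports the computed drift as is, and the corresponding
suite check is expected to fail until the model itself is extended (e.g.
time-graded diffusivity or a pre-spread initial condition).

## χ² fitting (`fitmodel`)

Because simulation units are arbitrary, a single global scale α is fit in
closed form (σ-weighted least squares) against the n.c. 7–12 measurements;
χ² then sums `((measured − α·model)/σ)²` over n.c. 7–14. σ is the per-bin
SD where replicates exist, with a floor of 10% of the bin mean (and 1% of
the global peak for empty bins) — the weighting convention is an explicit
package assumption. The α formula is verified against a dense 1D scan on
every suite run. Grid search is plain exhaustion over
D ∈ {0.3, 1, 2, 3, 4, 6, 8, 10} µm²/s, τ ∈ {30, 60, 100, 140, 200, 400,
800, ∞} min, T_src_on ∈ {1, 5, 6, 7}, T_src_off ∈ {12, 13, 14},
T_diff_off ∈ {11, 12, 13, never}; ties break toward the smallest
(τ, D, T_src_on); failed simulations record infinite χ². Recovery tests run
the D×τ plane at fixed timing (the same reduction used when mapping the
timing parameters separately): a noisy forward-simulated series generated at
D = 3.1, τ = 100 lands on the nearest grid points (3, 100). The
point-source comparison repeats the search with the whole source in the
anterior-pole voxel; on realistic-source data the point model fits worse
(ratio > 1), with its anterior bins overshooting the gradient's steepness.

## What passing tests do and do not show

The synthetic data reproduce the *statistical* structure the analysis
relies on (graded particle density and brightness, PSF extent, shot noise,
depth attenuation, background offsets). They do not emulate autofluorescent
texture beyond a smooth field, refractive-index aberrations, chromatic
offsets, nuclear-shape irregularity, or segmentation confounds like yolk
nuclei — so passing tests certify the algorithms against their own forward
models, not performance on any particular microscope's data. Embryo
geometry is a configurable ellipsoid; no atlas-derived shape is used.
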