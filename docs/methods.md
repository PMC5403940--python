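# Methods

`spidock` asks a concrete question: given a small set of single-particle
X-ray scattering snapshots of a protein complex taken at unknown random
orientations, how well can those data re-rank candidate complex structures
("decoys") produced by a rigid-body docking sampler?  The package contains a
forward simulator for the scattering data, three scoring functions, an
orientation-matching engine, and a ranking-power evaluation layer.

## Forward model

The scattered amplitude of an atomic model at momentum transfer **q** is the
direct sum of atomic wavelets

    F(q) = Σ_j f_j(|q|) · exp(i q · r_j),

with `f_j` the International-Tables 4-Gaussian + constant atomic form factor
(taken from gemmi's IT92 tables, indexed by (sin θ / λ)² = (q/4π)²).
A detector pixel seen from the sample along the unit vector k̂₀ records

    q = (2π/λ)(k̂₀ − k̂ᵢ),     |q| = 4π sin θ / λ,

with the incident beam k̂ᵢ along +z — the full Ewald-sphere mapping, no
flat-detector approximation.  Intensity is |F|².  Resolution uses the
crystallographic convention d = 2π/q, so the 4 Å cutoff sits at
q = π/2 ≈ 1.5708 Å⁻¹.

Orientations are intrinsic z-y′-z″ Euler triples (α, β, γ), degrees, applied
actively to the model: R = R_z(α)·R_y(β)·R_z(γ).  Two consequences used
throughout:

* the *first* angle α is a lab-frame rotation about the beam and therefore
  only rotates the pattern in-plane;
* the beam direction seen from the model frame, Rᵀẑ, depends only on (β, γ).

Azimuth-invariant reductions (radial profile, angular auto-correlation) are
thus blind to α, and reduced reference banks sample only (β, γ) — n² entries
instead of n³.

### Photon budget and noise

Instead of modelling the incident fluence explicitly, one global scale factor
is applied to a pattern set so that the mean noise-free count over all pixels
in the target resolution shell (default d = 4 Å, shell half-width 5% of the
target q) is exactly one photon — the regime where the highest-resolution
shell is just measurable.  Per-pixel σ is set at scaling time to √I of the
noise-free scaled intensity, floored at one photon (the Poisson σ of the
smallest countable signal); `add_noise` draws Poisson counts and, optionally,
adds a Gaussian background with variance Var(signal)/SNR, clipping at zero.
σ is deliberately *not* re-estimated from the noisy draw: it represents the
photon statistics of the underlying signal, keeps the noise-free chi-score
identities exact, and makes the per-pixel Poisson residual (X−λ)²/λ average
to one wherever the floor is inactive.  Shot-to-shot fluence jitter,
polarization, solid-angle and detector corrections are out of scope.

## Reductions

Patterns are resampled onto polar rings (ring radii at bin midpoints, φ = 0
along the fast axis, counter-clockwise) by cubic-spline interpolation
(`scipy.ndimage.map_coordinates`).  Bilinear resampling was tried first and
rejected: its O(Δ²) smoothing bias (0.1–0.7% relative) exceeds the sampling
error of aggregated profiles in low-q bins where the orientation-to-
orientation variance vanishes, visibly breaking the Debye-limit convergence
check.  Cubic splines reduce the bias below sampling error; the validity
mask is eroded by the spline half-support so no sample's stencil touches
masked-out pixels, and the default ring range stays 3 pixels inside the
resolution cutoff for the same reason.  Residual effects of the hard mask
edge are ~1e-4 relative on the outermost rings.

* **Radial profile**: per-ring azimuthal mean (and pattern mean for a set);
  σ propagated as √(mean intensity / effective sample count).  Interpolated
  azimuthal samples are correlated at the pixel scale, so the effective count
  slightly overstates independence; the profile σ is used only for relative
  chi weighting.
* **Angular auto-correlation**: AC(q, Δφ) = Σ_φ I(q,φ) I(q,φ+Δφ)·Δφ per
  ring, computed by FFT circular correlation (identical to the direct O(B²)
  sum to 1e-10).  Rings not fully inside the mask are dropped.  A first-order
  σ propagation (ignoring cross terms) supplies the chi denominator; it is
  floored at 2√B·Δφ·σ_floor², the AC-scale image of the per-pixel floor.

## Orientation matching

A reference bank simulates the (noise-free, photon-scaled with the *data's*
factor) model pattern at every grid orientation; each experimental pattern
takes the χ² minimum over the bank, with the experimental σ in the
denominator and ties broken to the lowest flat grid index.  Comparison
counters are exact: M·n³ for raw banks, M·n² for reduced ones.

The proof-of-principle confined subspace (all three angles in ±22.5°, 3°
step) reproduces a known pathology worth stating plainly: the subspace is
centered on the β = 0 pole of the Euler chart, where R_z(α)R_y(β)R_z(γ)
degenerates to R_z(α+γ).  Near the pole the chi-minimizing grid point is the
one closest in SO(3), and that point routinely trades α against γ — its
per-angle labels can sit several grid steps from the truth while the
*rotation* is closer than the per-angle-nearest grid point's.  Empirically
(noise-free native patterns, 3° step): the per-angle within-one-step rate
saturates near ~50%, while β alone and the geodesic rotation error recover
within the discretization in ~100% of cases.  The polar angle β being the
best-recovered angle is exactly what one expects from this chart, and the
package therefore reports per-angle, β-only and geodesic recovery rates.
The same degeneracy makes the azimuth of the beam direction (γ here)
ill-determined near β = 0 for the reduced representations; their agreement
with raw matching is assessed on the beam direction itself.

## Scoring

* **SPI matched** (known orientations): mean over patterns of the mean over
  masked pixels of ((I_model − I_data)/σ_data)².  Zero for the native model
  on its own noise-free patterns.
* **SPI matching** (unknown orientations): per-pattern minimum over a bank;
  by construction never exceeds the matched score under any fixed
  orientation assignment, and equals it when the true orientations lie on
  the grid.
* **SAXS**: chi between the data's aggregated radial profile and the model's
  rotational average.  The model side uses the Debye formula
  I(q) = Σ_ij f_i f_j sin(q r_ij)/(q r_ij) — the exact, noise-free rotational
  average — with pattern-averaging over Haar-random orientations retained as
  a cross-validated alternative (`method="patterns"`).
* **s-score**: 1 − max_R cc, where cc is the Pearson correlation of the two
  COM-centered electron density maps over a relative-rotation grid (no
  translational search).  Maps deposit one Gaussian per atom, σ = 1.5 Å for
  every element, amplitude ∝ atomic number, on a common cubic grid sized to
  hold either model in any orientation.  The default 10° full-SO(3) search
  is exhaustive and slow; tests and the acceptance script use coarser grids
  or confined bounds, which the refinement inequality (coarse max cc ≤ fine
  max cc) makes safe to interpret.
* **Z-combination**: standardized sum of two lower-is-better score columns;
  labelled experimental — no reweighting is attempted.

## Ranking evaluation

For a score column, the n best decoys are selected and their structural
difference (RMSD to native, or s-score) is histogrammed in 25 equal bins
over [0, max difference of the whole set]; the cumulative curve — with
endpoints (0, CDF(0)) and (1, 1) on the difference axis normalized by that
maximum — is integrated by trapezoid to give an AUC in [0, 1].  An
all-identical decoy set gives exactly 1.  RMSD is all-atom without
re-superposition (the fixed subunit defines the frame); no Cα subsetting.
Correlations are Pearson by default with Spearman exposed.

## Synthetic data generator

`make_toy_complex` draws atoms uniformly inside two tangent spheres at
protein-like packing density (~0.1 atom/Å³) with bulk C/N/O composition,
re-centered so subunit centers of mass sit exactly at the documented
placement.  Two decoy samplers are provided.  `generate_decoys` perturbs the
mobile subunit by a uniform axis/angle rotation (≤ rot_max) about its center
of mass plus a uniform random translation (≤ trans_max) — an unstructured
cloud.  `generate_decoy_ladder` ramps the perturbation deterministically so
decoy k has an *exact* all-atom RMSD of rmsd_max·k/(n−1): rotation about the
mobile COM and translation displace disjoint degrees of freedom, so the
translation length solves the quadrature identity
RMSD² = RMSD²_rot + w·|t|² (w the mobile atom fraction).  The ladder is the
instrument for ranking-power experiments, where a monotone, well-covered
RMSD axis is the controlled variable.  Neither sampler is a physical docking
engine: no clash-free guarantees, no interface chemistry, and a decoy
population unconditioned on docking scores.

Ranking experiments spanning RMSD up to 15 Å use a protein-sized toy complex
(420 atoms, subunit radii ~8 Å).  For the small 80-atom smoke-test complex
(subunit radii ~5 Å) a 15 Å RMSD corresponds to displacing the mobile
subunit by several subunit diameters — a fully dissociated regime in which
the score–difference relation is known to invert (density overlap and
interference terms saturate), and which real docking decoys do not occupy.
Keeping the perturbation-to-size ratio comparable to real complexes is what
makes the 0–15 Å ladder meaningful.
Consequently the tests demonstrate the *scoring machinery's* discrimination
under controlled structural differences; they do not certify performance on
real docking decoy distributions, real detector artifacts, or conformational
(non-rigid) differences.

Default study conditions mirror the method's operating point: 1,000
experimental patterns (the budget at which the SPI score converges), 4 Å
resolution cutoff with one photon per shell pixel, ±22.5° confined
orientation subspace with per-angle-uniform sampling (a Haar-uniform SO(3)
sampler is provided and used wherever a true rotational average is needed —
per-angle uniformity is *not* SO(3)-uniform).  The detector default is
128×128 pixels, λ = 1 Å, 100 mm distance, 0.45 mm pixels, reaching d = 4 Å
at the edge midpoints; tests and the acceptance script use 64×64 or 32×32
detectors with proportionally larger pixels (same q range) to keep runtimes
at desk scale — pixel counts only set the sampling density of the same
physics.

## Numerical choices and degenerate inputs

* σ floor: 1 photon per pixel; profile and AC floors are its images under
  the reductions.
* Matching ties: lowest flat grid index (deterministic).
* Grids: explicit bounds include both endpoints; full SO(3) uses [0,360)
  half-open azimuths and closed [0,180] in β.  Steps must divide intervals.
* Zero-photon pixels, empty rings, all-zero maps, zero-variance score
  columns: explicit errors or NaN flags, never silent zeros.
* All randomness flows from named integer seeds (`numpy.random.default_rng`);
  pattern-set noise derives per-pattern sub-seeds from one master seed.

## Known limitations

* The decoy generator's RMSD ladder is rigid-body only.
* The confined-subspace experiments inherit the Euler-pole degeneracy
  discussed above; full-SO(3) banks at fine steps are exhaustive and costly
  (no coarse-to-fine or FFT rotational alignment is implemented).
* The SAXS σ is propagated photon statistics, not profile spread across
  patterns; with heavy aggregation it is small, making the SAXS chi scale
  sensitive to any model-side bias.
* No solvent/hydration term, no incoherent scattering, single-particle hits
  only.
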