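# Methods

## Model

The package treats the molecular polarizability as the integral of a spatial
polarizability density, α = ∫ ρ^(α)(r) dr, and the Raman activity of mode k
as the integral of its derivative along the normal coordinate,
δρ^(α) = ∂ρ^(α)/∂Q_k.  In a tip junction the confined near field F(r − R)
(unit peak at the tip position R) multiplies the density once for the
incident and once for the scattered photon:

    α′_k(R) = ∫ F(r − R) δρ^(α)(r) F(r − R) dr,     I_k(R) ∝ |α′_k(R)|².

This is a *local approximation*: the density is the free-molecule response,
assumed tip-independent, and the tip enters only through the scalar weight
F².  The approximation is what makes scanning cheap — one density, many field
samplings — and it is exact in the uniform-field limit, where α′ reduces to
the far-field polarizability ∫ δρ dr.  Only the zz tensor component (z = tip
axis) is computed by default; fields carry a component label so other
channels are additive extensions, not a rewrite.  Complex densities
(resonant excitation) are first-class: α′ is complex and intensities use the
squared modulus.

Assumptions worth keeping in mind: the field is a scalar amplitude (no
position-dependent polarization), the grid is axis-aligned and rectilinear,
the molecular plane is at z = 0 and tip "height" is measured from that plane,
and no semi-local (field-gradient / quadrupole) correction is included.

## Near-field profiles

Two profiles with identical per-axis FWHM semantics:

* `lorentzian3d`: F(r) = 1 / (1 + Σ_a (2Δ_a/w_a)²),
* `gaussian3d`:  F(r) = exp(−4 ln 2 Σ_a (Δ_a/w_a)²),

with Δ = r − R.  Both are 1 at the center and exactly ½ at a single-axis
offset of w_a/2; the Lorentzian has heavier tails (strictly larger beyond one
FWHM), representing the residual background field on the substrate.  The
additive-quadratic Lorentzian is one of several possible 3D generalizations;
we chose the minimal one reproducing the per-axis FWHM, and since imaging
patterns are insensitive to the profile shape (both profiles are exposed and
property-tested against each other), nothing downstream depends on the
choice.  The amplitude is pinned to 1: absolute enhancement is a constant
prefactor that cancels out of image contrast, so images are absolute only up
to that factor.

Reference field settings shipped as presets (FWHM per axis / tip height):
benzene 1.3 Å / 1.0 Å; porphyrin 2 Å / 1.5 Å; H₂TBPP (12, 12, 6) Å / 2.7 Å;
porphycene 5 Å / 2 Å.

## Numerics

**Quadrature.** All integrals are midpoint Riemann sums, Σ values × voxel
volume.  This matches the grid-sum framing of density data, keeps the
integral exactly linear in the field values (several invariants rely on
that), and is second-order accurate; tests verify convergence under grid
refinement against closed forms and use 4×-refined grids and higher-density
sampling as independent oracles.  Higher-order quadrature is deliberately not
the default.

**Units.** Lengths are Å everywhere internally; the Gaussian-cube Bohr
convention (positive voxel counts) is converted at the I/O boundary with
1 Bohr = 0.52917721092 Å.  Cubes written by the package use the Å convention
(negative counts) so round trips involve no unit conversion.  Complex
densities are stored as paired real cubes (`_re`/`_im` suffixes) because the
cube format has no complex dialect.

**Grid discipline.** Grid mismatch anywhere (finite differencing, pointwise
weighting, multi-mode scans) is a hard error; nothing is ever silently
resampled, because interpolation would corrupt the finite differences the
densities are built from.  Grid equality tolerance is 10⁻⁸ Å.

**Finite differencing.** δρ is the central ("three-point") first-derivative
stencil (ρ₊ − ρ₋)/(2ΔQ); the midpoint geometry cancels for first
derivatives.  The displacement step and the normal-coordinate normalization
are upstream conventions surfaced as configuration (default ΔQ = 0.01 for
the synthetic path); the synthetic densities are exactly linear in Q, making
the recovered derivative step-independent by construction.

**Scans.** Tip positions are independent pixels — no interpolation between
them.  The Gaussian profile factorizes per axis, so Gaussian scans are two
small matrix contractions per mode; the Lorentzian does not factorize and is
evaluated per tip with per-axis quadratic terms precomputed.  Both paths are
checked against a plain triple-loop oracle to 10⁻¹⁰ relative (with an
absolute floor of 10⁻¹² of the image maximum for pixels that are exact
symmetry cancellations, i.e. pure rounding noise).  The integration domain is
always the full grid; the decay of F performs the localization.

**Cross sections.**
dσ/dΩ = (π²/ε₀²)(ν̃_in − ν̃_k)⁴ · h/(8π²c ν̃_k) · |α′_k|²/(1 − e^(−hcν̃_k/k_BT)),
with wavenumbers converted to m⁻¹, α′ converted from Å³ (the natural unit of
Å-gridded density integrals) to SI via 4πε₀·10⁻³⁰, and CODATA constants from
scipy.  The absolute scale inherits the (unstated) normal-coordinate
normalization of the upstream densities; ratios — the ν⁴ law, the thermal
factor, relative mode strengths — are normalization-independent and are what
the tests pin down.  Defaults: T = 298 K, incident line 18797 cm⁻¹ (532 nm).
Stokes kinematics are enforced (ν̃_in > ν̃_k > 0).

**Band combination** is incoherent: distinct normal modes scatter at
distinct vibrational frequencies, so their images add as intensities.  The
window is symmetric, center ± width/2, width 20 cm⁻¹ by default.

**Tip spectra** use an area-normalized Lorentzian line per mode
(default FWHM 10 cm⁻¹) purely for display; zero broadening yields a stick
spectrum.  The integrated spectrum equals the sum of cross sections.

**Display normalization** (peak-scaled densities for isosurface plots) is
quarantined from the physics path; intensities never see it.

## Synthetic densities

The generator produces analytic stand-ins with the structural features that
drive the imaging mechanism, not real electron structure:

    δρ(r) = Σ_i c_i d_i (z − z_i)/σ_z · exp(−ρ_i²/2σ_xy² − (z − z_i)²/2σ_z²)

for out-of-plane modes (odd in z − z_i, hence opposite signs across the
molecular plane and a vanishing far field on a symmetric grid); in-plane
modes use an odd in-plane factor along the per-atom displacement direction.
Ring builders provide the canonical sign patterns: all-equal (symmetric
out-of-plane bend), alternating ±1 with opposite para pairs (anti-symmetric
bend, requires even atom count), and tangential in-plane.  Resonant fixtures
add an imaginary part as a scaled (default 0.2×) lobe centered σ_z *below*
each atom — asymmetric about the plane, concentrated under the molecule,
preserving the mode's in-plane symmetry.

Defaults: ring of 6 lobes at radius 2.5 Å (hydrogen-ring scale), lobe widths
σ_xy = 0.5 Å and σ_z = 0.4 Å (arbitrary, chosen to resolve on the default
steps), grid margin 3 Å, steps 0.4 Å laterally and 0.1 Å vertically, mode
frequencies 664 / 835 cm⁻¹ for the symmetric / anti-symmetric out-of-plane
patterns.  Default grids have even voxel counts with centers at
±(k + ½)·step about the molecular center, so odd integrands cancel exactly
rather than to truncation error.  Fixtures are fully deterministic.

What passing tests on these fixtures shows: the operator algebra (weighting,
integration, squaring, scanning, band summation) and the symmetry mechanism
(far-field silence, near-field activation, dark centers, off-atom hotspots)
are implemented correctly.  What it does not show: agreement with any real
molecule's densities, coupled tip–molecule response beyond the local
approximation, or field-gradient corrections — those require upstream
quantum-chemistry data.

## Design choices and limitations

* The mode table / cube bundle format (`<mode>_<plus|minus>_<re|im>.cube`,
  whitespace mode table, JSON manifest) is the package's own plumbing
  convention, chosen to be diff-able plain text.
* Scan image sizes in tests and the acceptance script are kept at
  10⁴–10⁵ voxel grids and ≤ 71×71 tip grids — the package's own choice of
  demonstration scale; the engine itself is O(modes × tips × voxels) and has
  no intrinsic size limit.
* Triclinic grids, multi-field cube extensions and per-pixel field
  polarization are out of scope; the field is scalar and the grid
  axis-aligned.
* An optional truncation radius for the integration domain exists nowhere:
  profiling showed full-grid integration is cheap at these sizes, so the
  simpler exact-domain rule won.
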