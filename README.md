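# tersim

Simulation of high-resolution tip-enhanced Raman spectroscopy (TERS) images
and spectra by **local integration of Raman polarizability densities**.

## The problem

TERS places a molecule in the sub-nanometer gap under a sharp plasmonic tip.
The tip confines the optical near field to a few Ångström, which (i) breaks
the conventional Raman selection rules and (ii) makes the Raman signal depend
on the lateral tip position — scanning the tip yields an image of the
molecule, mode by mode. `tersim` implements the local-integration picture of
this effect for people who have volumetric polarizability densities from a
quantum-chemistry response calculation (or want controllable analytic
stand-ins) and need per-mode TERS images, band-combined images and
differential cross sections without re-running a full coupled
tip–molecule response at every tip position.

## The model

The molecular polarizability is the spatial integral of a polarizability
density, α = ∫ ρ^(α)(r) dr.  Differentiating along a vibrational normal
coordinate Q_k gives the *Raman polarizability density*
δρ^(α) = ∂ρ^(α)/∂Q_k, computed by central finite differences of densities at
geometries displaced by ±ΔQ.  Under a confined near field F(r − R) of unit
peak centered at the tip position R (the field enters once for the incident
and once for the scattered photon):

    δρ_loc(r, R) = F(r − R) · δρ^(α)(r) · F(r − R)
    α′_k(R)      = ∫ δρ_loc(r, R) dr
    I_k(R)       ∝ |α′_k(R)|²

A TERS image is I_k(R) on a lateral grid of tip positions at fixed height.
With F ≡ 1 the integral is the far-field Raman polarizability, which obeys
the usual selection rules; a confined F breaks the cancellation of
opposite-signed density lobes and activates far-field-silent modes.  Only the
zz tensor component (tip axis) is carried by default.  The near field is a
3D Lorentzian (or Gaussian) with per-axis FWHMs; the differential cross
section per mode is

    dσ/dΩ = (π²/ε₀²)(ν̃_in − ν̃_k)⁴ · h/(8π²c ν̃_k) · |α′_k|² / (1 − e^(−hcν̃_k/k_BT))

Near-degenerate modes inside a spectral window (default 20 cm⁻¹) are combined
by pixelwise intensity summation, which is how the characteristic four-lobe
patterns of porphyrin-derivative images arise from degenerate side-group
modes.

## Worked example

```python
import tersim as ts

# analytic benzene-like fixture: 6 lobes, alternating out-of-plane signs
mol = ts.build_ring(6, 2.5, "antisymmetric_oop")   # 835 cm-1 pattern
rd  = ts.rasterize(mol)                            # 0.4/0.1 Å grid, 3 Å margin

print(abs(ts.far_field(rd)))                       # 2.33e-17  — far-field silent

profile, fwhm, height = ts.preset("benzene")       # Lorentzian, 1.3 Å, 1.0 Å up
plan = ts.ScanPlan(x_range=(-4, 4), y_range=(-4, 4), height=height,
                   fwhm=fwhm, profile=profile, step=0.2)
img = ts.scan(rd, plan)
print(img.max)                                     # 1.0725e-02 — activated by the tip
print(img.pixel_nearest(0, 0) / img.max)           # 4.6e-36   — dark scan center

nf = ts.NearField(profile, fwhm, (2.5, 0.0, height))   # tip over a lobe
alpha = ts.local_polarizability(rd, nf)
print(abs(alpha))                                  # 1.0391e-01 Å^3
print(ts.cross_section(alpha, 18797.0, rd.mode.frequency))  # 5.98e-83 m^2/sr
```

The far field integrates to zero (opposite-signed lobes cancel over all
space), yet the confined field yields a strictly positive image — the
symmetry-breaking mechanism — with a dark pixel at the ring center where the
local lobes still cancel.  Absolute intensities are arbitrary (unit-amplitude
analytic lobes); contrast and ratios are the physics.

The same pipeline from the shell:

```sh
tersim synth ring --mode antisymmetric --out-dir fixture
tersim image --density-dir fixture --field-preset benzene --out-dir out
tersim spectrum --density-dir fixture --tip 2.5 0.0 --out-dir out
```

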