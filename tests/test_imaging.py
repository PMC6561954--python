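"""The local-integration operator, the far-field limit, and tip scans."""

import warnings

import numpy as np
import pytest

import tersim as ts


def _uniform_field(center=(0, 0, 1.0)):
    return ts.NearField("lorentzian3d", (1e6, 1e6, 1e6), center)


class TestEffectiveDensity:
    def test_uniform_field_is_identity(self, rd_sym):
        out = ts.effective_density(rd_sym, _uniform_field())
        np.testing.assert_allclose(
            out.values, rd_sym.field.values, rtol=1e-8, atol=0
        )

    def test_field_enters_squared(self, rd_sym):
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (0, 0, 1.0))
        f = nf.sample_on_grid(rd_sym.field.grid)
        out = ts.effective_density(rd_sym, nf)
        np.testing.assert_allclose(out.values, rd_sym.field.values * f**2, rtol=1e-12)

    def test_voxel_sum_oracle(self, rd_sym):
        # ∫ F² δρ equals the exhaustive voxel sum of F² δρ ΔV exactly.
        nf = ts.NearField("lorentzian3d", (0.8, 0.8, 0.8), (1.0, 0.5, 0.8))
        alpha = ts.local_polarizability(rd_sym, nf)
        f = nf.sample_on_grid(rd_sym.field.grid)
        brute = 0.0 + 0.0j
        vol = rd_sym.field.grid.voxel_volume
        for fv, dv in zip(f.ravel(), rd_sym.field.values.ravel()):
            brute += fv * fv * dv * vol
        assert abs(alpha - brute) <= 1e-12 * max(abs(brute), 1e-30)


class TestLocalPolarizability:
    def test_symmetry_cancellation_on_plane(self, rd_antisym):
        # Symmetric field on the symmetry axis of an anti-symmetric density:
        # opposite-signed lobes cancel under integration.
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (0, 0, 1.0))
        alpha = ts.local_polarizability(rd_antisym, nf)
        scale = ts.integrate(
            rd_antisym.field.copy_with(np.abs(rd_antisym.field.values))
        ).real
        assert abs(alpha) <= 1e-10 * scale

    def test_off_center_field_breaks_cancellation(self, rd_antisym):
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (2.5, 0.0, 1.0))
        assert abs(ts.local_polarizability(rd_antisym, nf)) > 0

    def test_uniform_field_equals_far_field(self, blob_density):
        alpha = ts.local_polarizability(blob_density, _uniform_field())
        ff = ts.far_field(blob_density)
        assert abs(alpha - ff) <= 1e-4 * abs(ff)

    def test_off_center_matches_refined_grid_oracle(self, ring_antisym):
        grid = ts.default_grid(ring_antisym, lateral_step=0.4, vertical_step=0.2)
        rd = ts.rasterize(ring_antisym, grid)
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (2.5, 0.3, 1.0))
        alpha = ts.local_polarizability(rd, nf)
        fine = ts.GridSpec(
            grid.origin - 0.375 * grid.step, grid.step / 4,
            tuple(4 * c for c in grid.counts),
        )
        vals = ts.analytic_density(ring_antisym, fine.points())
        wf = nf.sample_on_grid(fine)
        oracle = ts.integrate(ts.VolumetricField(fine, vals * wf * wf))
        assert abs(alpha - oracle) <= 0.01 * abs(oracle)


class TestIntensity:
    def test_zero_density(self):
        grid = ts.GridSpec((0, 0, 0), (0.5, 0.5, 0.5), (4, 4, 4))
        rd = ts.RamanDensity(ts.VolumetricField(grid, np.zeros((4, 4, 4))))
        nf = ts.NearField("lorentzian3d", (1, 1, 1), (0, 0, 1))
        assert ts.intensity(rd, nf) == 0.0

    def test_quadratic_homogeneity(self, rd_sym):
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (2.5, 0, 1.0))
        base = ts.intensity(rd_sym, nf)
        for c in (2.0, -3.0, 1j, 2 - 1j):
            scaled = ts.RamanDensity(rd_sym.field.copy_with(c * rd_sym.field.values))
            assert ts.intensity(scaled, nf) == pytest.approx(abs(c) ** 2 * base)

    def test_purely_imaginary_polarizability(self, rd_sym):
        # alpha' = i·a must give intensity a² (squared modulus).
        nf = ts.NearField("lorentzian3d", (1.3, 1.3, 1.3), (2.5, 0, 1.0))
        a = ts.local_polarizability(rd_sym, nf)
        rot = ts.RamanDensity(rd_sym.field.copy_with(1j * rd_sym.field.values))
        assert ts.intensity(rot, nf) == pytest.approx(abs(a) ** 2)


class TestFarField:
    def test_antisymmetric_fixture_is_silent(self, rd_antisym, rd_sym):
        for rd in (rd_antisym, rd_sym):  # both odd in z => zz far field zero
            scale = ts.integrate(
                rd.field.copy_with(np.abs(rd.field.values))
            ).real
            assert abs(ts.far_field(rd)) <= 1e-10 * scale

    def test_positive_lobe_is_positive_real(self, blob_density):
        ff = ts.far_field(blob_density)
        assert ff.real > 0 and ff.imag == 0

    def test_equals_uniform_local_polarizability(self, blob_density):
        # operator identity at machine precision with F exactly 1
        grid = blob_density.field.grid
        ones = np.ones(grid.shape)
        alpha = ts.integrate(ts.pointwise_scale(blob_density.field, ones))
        assert alpha == ts.far_field(blob_density)


class TestScan:
    plan_kwargs = dict(x_range=(-4, 4), y_range=(-4, 4), height=1.0,
                       fwhm=(1.3, 1.3, 1.3), step=0.4)

    def test_image_shape_and_nonnegativity(self, rd_sym):
        plan = ts.ScanPlan(**self.plan_kwargs)
        img = ts.scan(rd_sym, plan)
        assert img.intensities.shape == (plan.x_values.size, plan.y_values.size)
        assert np.all(img.intensities >= 0)

    def test_symmetric_mode_accumulation_dominates(self, rd_sym):
        # tip over the ring >> tip 3 FWHM outside the ring
        plan = ts.ScanPlan(x_range=(-7, 7), y_range=(0, 0), height=1.0,
                           fwhm=(1.3, 1.3, 1.3), step=0.1)
        img = ts.scan(rd_sym, plan)
        on_ring = img.pixel_nearest(2.5, 0.0)
        outside = img.pixel_nearest(2.5 + 3 * 1.3, 0.0)
        assert on_ring > outside

    def test_antisymmetric_mode_dark_center(self, rd_antisym):
        plan = ts.ScanPlan(**self.plan_kwargs)
        img = ts.scan(rd_antisym, plan)
        assert img.pixel_nearest(0.0, 0.0) < 0.05 * img.max

    def test_translation_equivariance(self, ring_antisym):
        plan = ts.ScanPlan(**self.plan_kwargs)
        img = ts.scan(ts.rasterize(ring_antisym), plan)

        import dataclasses

        shifted_mol = dataclasses.replace(
            ring_antisym, positions=ring_antisym.positions + np.array([1.0, 1.0, 0.0])
        )
        shifted_plan = ts.ScanPlan(x_range=(-3, 5), y_range=(-3, 5), height=1.0,
                                   fwhm=(1.3, 1.3, 1.3), step=0.4)
        shifted_img = ts.scan(ts.rasterize(shifted_mol), shifted_plan)
        ref = img.intensities
        np.testing.assert_allclose(
            shifted_img.intensities, ref, rtol=0, atol=1e-10 * ref.max()
        )

    def test_c2_symmetry_inherited(self, rd_antisym):
        # density maps to ±itself under 180° about z; intensities are C2
        plan = ts.ScanPlan(**self.plan_kwargs)
        img = ts.scan(rd_antisym, plan)
        rot = img.intensities[::-1, ::-1]
        np.testing.assert_allclose(
            img.intensities, rot, rtol=0, atol=1e-8 * img.max
        )

    @pytest.mark.parametrize("profile", ["lorentzian3d", "gaussian3d"])
    def test_matches_brute_force_oracle(self, brute_force, profile):
        mol = ts.build_ring(4, 1.2, "antisymmetric_oop")
        grid = ts.GridSpec((-2.2, -2.2, -1.4), (0.4, 0.4, 0.35), (12, 12, 9))
        rd = ts.rasterize(mol, grid)
        plan = ts.ScanPlan(x_range=(-2, 2), y_range=(-2, 2), height=1.0,
                           fwhm=(1.3, 1.3, 1.3), step=1.0, profile=profile)
        img = ts.scan(rd, plan)
        ref = brute_force(rd, plan)
        # atol floor: symmetry-cancelled pixels are pure rounding noise
        np.testing.assert_allclose(
            img.intensities, ref, rtol=1e-10, atol=1e-12 * ref.max()
        )

    def test_multi_density_scan(self, rd_sym, rd_antisym):
        plan = ts.ScanPlan(**self.plan_kwargs)
        images = ts.scan([rd_sym, rd_antisym], plan)
        assert len(images) == 2
        np.testing.assert_array_equal(
            images[0].intensities, ts.scan(rd_sym, plan).intensities
        )

    def test_far_field_consistency_per_pixel(self, blob_density):
        # FWHM -> 1e6 Å: every pixel approaches |far field|²
        ff2 = abs(ts.far_field(blob_density)) ** 2
        for profile in ("lorentzian3d", "gaussian3d"):
            plan = ts.ScanPlan(x_range=(-1, 1), y_range=(-1, 1), height=1.0,
                               fwhm=(1e6, 1e6, 1e6), step=0.5, profile=profile)
            img = ts.scan(blob_density, plan)
            assert np.max(np.abs(img.intensities - ff2)) <= 1e-4 * ff2

    def test_sharper_field_lowers_image_entropy(self, rd_sym):
        def entropy(img):
            p = img.intensities.ravel()
            p = p / p.sum()
            p = p[p > 0]
            return float(-(p * np.log(p)).sum())

        ents = []
        for w in (4.0, 2.0, 1.0):
            plan = ts.ScanPlan(x_range=(-4, 4), y_range=(-4, 4), height=1.0,
                               fwhm=(w, w, w), step=0.4)
            ents.append(entropy(ts.scan(rd_sym, plan)))
        assert ents[0] > ents[1] > ents[2]

    def test_window_outside_support_warns(self, rd_sym):
        plan = ts.ScanPlan(x_range=(50, 52), y_range=(50, 52), height=1.0,
                           fwhm=(1.3, 1.3, 1.3), step=1.0)
        with pytest.warns(UserWarning, match="outside"):
            img = ts.scan(rd_sym, plan)
        near = ts.scan(rd_sym, ts.ScanPlan(**self.plan_kwargs))
        assert img.max < 1e-10 * near.max

    def test_invalid_plans_rejected(self):
        with pytest.raises(ValueError):
            ts.ScanPlan(x_range=(1, -1), y_range=(0, 1), height=1.0, fwhm=(1, 1, 1))
        with pytest.raises(ValueError):
            ts.ScanPlan(x_range=(-1, 1), y_range=(0, 1), height=1.0,
                        fwhm=(1, 1, 1), step=0.0)

    def test_mismatched_grids_rejected(self, rd_sym):
        other = ts.rasterize(ts.build_ring(4, 1.0, "symmetric_oop"))
        plan = ts.ScanPlan(**self.plan_kwargs)
        with pytest.raises(ValueError, match="share a grid"):
            ts.scan([rd_sym, other], plan)


class TestTERSImage:
    def test_negative_intensities_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ts.TERSImage(np.array([[-1.0]]), [0.0], [0.0])

    def test_save_text_round_trip(self, tmp_path, rd_sym):
        plan = ts.ScanPlan(x_range=(-2, 2), y_range=(-2, 2), height=1.0,
                           fwhm=(1.3, 1.3, 1.3), step=0.5)
        img = ts.scan(rd_sym, plan)
        path = tmp_path / "img.txt"
        img.save_text(path)
        back = np.loadtxt(path)
        np.testing.assert_allclose(back, img.intensities, rtol=1e-10)
        assert (tmp_path / "img.txt.json").exists()
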