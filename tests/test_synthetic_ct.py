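"""Simulator physics: spectra, attenuation, phantoms, scans, corrections."""

import math

import numpy as np
import pytest

from protonct import bha_analysis as bha
from protonct import synthetic_ct as sct
from protonct.constants import ME_C2_MEV, MU_WATER_60KEV_CM, R_ELECTRON_CM
from protonct.materials import water_material

from conftest import ANGLES, GRID, center_edge_means, streak_delta


class TestSpectrum:
    def test_endpoint_below_kvp(self):
        sp = sct.make_kvp_spectrum(80.0)
        assert max(sp.energies) <= 80.0
        assert sum(sp.weights) == pytest.approx(1.0)

    def test_filtration_hardens(self):
        soft = sct.make_kvp_spectrum(120.0, filtration_mm_al=1.0)
        hard = sct.make_kvp_spectrum(120.0, filtration_mm_al=6.0)
        assert hard.mean_energy > soft.mean_energy

    def test_default_spectra_mean_energies_increase(self, spectra):
        means = [spectra[t].mean_energy for t in ("80kVp", "120kVp", "140kVp")]
        assert means[0] < means[1] < means[2]
        effs = [sct.effective_energy(spectra[t]) for t in ("80kVp", "120kVp", "140kVp")]
        assert effs[0] < effs[1] < effs[2]

    def test_kvp_bounds(self):
        with pytest.raises(ValueError):
            sct.make_kvp_spectrum(30.0)
        with pytest.raises(ValueError):
            sct.make_kvp_spectrum(80.0, filtration_mm_al=-1.0)


class TestAttenuation:
    def test_water_anchor_at_60kev(self):
        assert sct.attenuation_mu(water_material(), 60.0) == pytest.approx(
            MU_WATER_60KEV_CM, rel=1e-12
        )

    def test_monotonically_decreasing(self, plugs):
        es = np.linspace(20.0, 150.0, 40)
        for mat in [water_material()] + plugs[-3:]:
            mu = sct.attenuation_mu(mat, es)
            assert np.all(np.diff(mu) < 0)

    def test_bone_photoelectric_excess(self, plugs):
        sb3 = next(p for p in plugs if p.name.startswith("SB3"))
        ratio = sct.attenuation_mu(sb3, 50.0) / sct.attenuation_mu(water_material(), 50.0)
        assert ratio > sb3.rho_e

    def test_klein_nishina_matches_independent_formula(self):
        # independent evaluation via the alternative algebraic arrangement
        for e in (60.0, 100.0):
            k = e / (ME_C2_MEV * 1e3)
            term = (
                (1 + k) / k**2 * (2 * (1 + k) / (1 + 2 * k) - math.log(1 + 2 * k) / k)
                + math.log(1 + 2 * k) / (2 * k)
                - (1 + 3 * k) / (1 + 2 * k) ** 2
            )
            expect = 2 * math.pi * R_ELECTRON_CM**2 * term
            assert sct.klein_nishina_cross_section(e) == pytest.approx(expect, rel=1e-12)

    def test_energy_validity_range(self):
        with pytest.raises(ValueError):
            sct.attenuation_mu(water_material(), 5.0)


class TestPhantomGeometry:
    def test_cupping_series_dimensions(self):
        phs = sct.make_cupping_phantoms(grid_n=96, nz=1)
        assert (phs[0].ap_mm, phs[0].lat_mm) == (135.0, 135.0)
        deffs = [bha.effective_diameter(p.ap_mm / 10, p.lat_mm / 10) for p in phs]
        assert deffs == pytest.approx([13.5, 17.8, 26.9, 30.2])
        # extended variant inverts d_eff = sqrt(AP*LAT)
        assert phs[-1].lat_mm == pytest.approx(302.0**2 / 269.0)

    def test_insert_occupies_28mm_circle(self):
        ph = sct.make_cupping_phantoms(grid_n=128, nz=1)[0]
        px = ph.voxel_size[1]
        n_vox = int((ph.labels[0] == 2).sum())
        area = n_vox * px * px
        assert area == pytest.approx(math.pi * 14.0**2, rel=0.05)

    def test_insert_larger_than_phantom_rejected(self):
        with pytest.raises(ValueError):
            sct.make_cupping_phantoms(diameters_cm=(2.0,), extended_deff_cm=None, grid_n=64)

    def test_streak_plug_spacing_and_collinearity(self, streak_phantom):
        assert streak_phantom.meta["plug_spacing_mm"] == pytest.approx(43.0)  # 28 + 15
        z2 = streak_phantom.meta["region2_slices"][0]
        sl = streak_phantom.labels[z2]
        rows = np.where((sl == 3).any(axis=1))[0]
        crow = np.where((sl == 2).any(axis=1))[0]
        # all three holes centered on the same row band
        assert abs(rows.mean() - crow.mean()) < 1.5

    def test_streak_regions_share_central_material(self, streak_phantom):
        z1 = streak_phantom.meta["region1_slices"][0]
        z2 = streak_phantom.meta["region2_slices"][0]
        sl1, sl2 = streak_phantom.labels[z1], streak_phantom.labels[z2]
        assert (sl1 == 2).sum() == (sl2 == 2).sum()
        assert np.array_equal(sl1 == 2, sl2 == 2)
        assert streak_phantom.materials[2].name == "CT solid water"

    def test_head_dimensions_and_structure(self):
        head = sct.make_head_phantom(grid_n=96, nz=2)
        assert (head.ap_mm, head.lat_mm) == (190.0, 150.0)
        sl = head.labels[0]
        r0, r1 = head.meta["petrous_row_range"]
        mid = (r0 + r1) // 2
        row = sl[mid]
        left_bone = np.where(row == 4)[0]
        brain = np.where(row == 3)[0]
        # brain bounded by petrous bone along the lateral path
        assert left_bone.min() < brain.mean() < left_bone.max()


class TestSimulateScan:
    def test_determinism_same_seed(self, water_cylinder, spectra):
        a = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=60, noise_seed=5, noise_level=0.01)
        b = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=60, noise_seed=5, noise_level=0.01)
        assert np.array_equal(a.hu, b.hu)
        c = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=60, noise_seed=6, noise_level=0.01)
        assert not np.array_equal(a.hu, c.hu)

    def test_air_background_near_minus_1000(self, water_cylinder, spectra):
        img = sct.simulate_scan(water_cylinder, spectra["120kVp"], n_angles=ANGLES)
        assert img.hu[0, 2, 2] == pytest.approx(-1000.0, abs=2.0)

    def test_fov_bound_enforced(self):
        px = sct._pixel_size_for(600.0, 64)
        labels = np.ones((1, 64, 64), dtype=np.int8)
        ph = sct.VoxelPhantom(
            labels=labels,
            materials={1: water_material()},
            voxel_size=(1.0, px, px),
            ap_mm=600.0,
            lat_mm=600.0,
        )
        with pytest.raises(sct.FieldOfViewError):
            sct.simulate_scan(ph, sct.Spectrum.monochromatic(60.0))

    def test_truncation_detected(self):
        # body touching the grid corners exceeds the reconstruction circle
        labels = np.ones((1, 64, 64), dtype=np.int8)
        ph = sct.VoxelPhantom(
            labels=labels,
            materials={1: water_material()},
            voxel_size=(1.0, 2.0, 2.0),
            ap_mm=128.0,
            lat_mm=128.0,
        )
        with pytest.raises(sct.FieldOfViewError):
            sct.simulate_scan(ph, sct.Spectrum.monochromatic(60.0))

    def test_monochromatic_limit_matches_analytic_hu(self):
        """Single-bin spectrum: reconstructed plug HU agree with the analytic
        mu-based HU of each material within reconstruction error."""
        ph = sct.make_cupping_phantoms(grid_n=256, nz=1)[0]
        e = 60.0
        img = sct.simulate_scan(ph, sct.Spectrum.monochromatic(e), n_angles=360)
        muw = sct.mu_water(e)
        for label, radius, center in ((2, 12.0, (0.0, 0.0)), (1, 15.0, (0.0, 45.0))):
            mat = ph.materials[label]
            expect = 1000.0 * (sct.attenuation_mu(mat, e) / muw - 1.0)
            roi = bha.cylinder_roi(img, center, radius, contraction_mm=0.0)
            mean, _, _ = bha.roi_stats(img, roi)
            assert abs(mean - expect) < 10.0


class TestWaterLinearization:
    def test_monochromatic_identity(self):
        sp = sct.Spectrum.monochromatic(70.0)
        p = np.linspace(0.0, 8.0, 50)
        assert sct.water_linearization(p, sp) == pytest.approx(p, abs=1e-9)

    def test_beyond_table_extrapolates(self, spectra):
        lengths, p_tab, mu_ref, _ = sct._wl_table(spectra["80kVp"])
        out = sct.water_linearization(np.array([p_tab[-1] * 1.05]), spectra["80kVp"])
        assert out[0] > mu_ref * lengths[-1]

    def test_removes_water_cupping(self, water_cylinder, spectra):
        raw = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=ANGLES, linearize=False)
        lin = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=ANGLES, linearize=True)
        mc_r, me_r, _, _ = center_edge_means(raw)
        mc_l, me_l, _, _ = center_edge_means(lin)
        assert mc_r < me_r  # cupping: center depressed
        assert abs(mc_l - me_l) * 5.0 <= abs(mc_r - me_r)


class TestIBHC:
    def test_no_bone_is_identity(self, water_cylinder, spectra):
        img = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=60)
        out = sct.ibhc_emulate(img)
        assert out is img

    def test_reduces_streak_at_every_technique(self, streak_scans, streak_rois):
        for tech in ("80kVp", "120kVp", "140kVp"):
            d_raw = streak_delta(streak_scans[(tech, False)], streak_rois)
            d_cor = streak_delta(streak_scans[(tech, True)], streak_rois)
            assert 0 < d_cor < d_raw

    def test_requires_simulation_context(self):
        img = sct.CTImage(hu=np.zeros((1, 8, 8)), voxel_size=(1, 1, 1), technique_id="x")
        with pytest.raises(ValueError):
            sct.ibhc_emulate(img)


@pytest.fixture(scope="module")
def mono_pair():
    ph = sct.make_cupping_phantoms(grid_n=GRID, nz=1)[0]
    lo = sct.simulate_scan(ph, sct.Spectrum.monochromatic(60.0), n_angles=ANGLES)
    hi = sct.simulate_scan(ph, sct.Spectrum.monochromatic(100.0), n_angles=ANGLES)
    return ph, lo, hi


class TestDualEnergy:
    def test_fixed_point_identity(self, mono_pair):
        _, lo, _ = mono_pair
        out = sct.pseudo_mono_image(lo, lo, 60.0)
        assert np.array_equal(out.hu, lo.hu)

    def test_identical_spectra_cannot_extrapolate(self, mono_pair):
        _, lo, _ = mono_pair
        with pytest.raises(sct.ConditioningError):
            sct.pseudo_mono_image(lo, lo, 80.0)

    def test_water_region_near_zero_at_any_target(self, water_cylinder, spectra):
        lo = sct.simulate_scan(water_cylinder, spectra["80kVp"], n_angles=ANGLES)
        hi = sct.simulate_scan(water_cylinder, spectra["140kVp"], n_angles=ANGLES)
        for kev in (60.0, 100.0):
            out = sct.pseudo_mono_image(lo, hi, kev)
            mc, _, _, _ = center_edge_means(out)
            assert abs(mc) < 5.0

    def test_rho_z_water_recovery(self, water_cylinder):
        lo = sct.simulate_scan(water_cylinder, sct.Spectrum.monochromatic(60.0), n_angles=ANGLES)
        hi = sct.simulate_scan(water_cylinder, sct.Spectrum.monochromatic(100.0), n_angles=ANGLES)
        rho, zeff = sct.rho_z_decompose(lo, hi)
        core = bha.cylinder_roi(lo, (0.0, 0.0), 40.0, contraction_mm=0.0).mask
        assert np.nanmean(rho[core]) == pytest.approx(1.0, rel=0.01)
        assert np.nanmean(zeff[core]) == pytest.approx(sct.ZEFF_WATER, rel=0.01)

    def test_rho_z_bone_recovery_closed_loop(self, mono_pair):
        ph, lo, hi = mono_pair
        rho, zeff = sct.rho_z_decompose(lo, hi)
        sb3 = ph.materials[2]
        roi = bha.cylinder_roi(lo, (0.0, 0.0), 12.0, contraction_mm=0.0).mask
        assert np.nanmean(rho[roi]) == pytest.approx(sb3.rho_e, rel=0.02)
        assert np.nanmean(zeff[roi]) == pytest.approx(sb3.z_eff, rel=0.02)

    def test_rho_z_symmetric_in_input_order(self, mono_pair):
        _, lo, hi = mono_pair
        r1, z1 = sct.rho_z_decompose(lo, hi)
        r2, z2 = sct.rho_z_decompose(hi, lo)
        assert np.allclose(r1, r2, equal_nan=True)
        assert np.allclose(z1, z2, equal_nan=True)

    def test_rho_z_to_rsp_water(self):
        rsp = sct.rho_z_to_rsp(np.array([1.0]), np.array([sct.ZEFF_WATER]))
        assert rsp[0] == pytest.approx(1.0, abs=0.02)


def test_write_nifti_round_trip(tmp_path, water_cylinder):
    import nibabel as nib

    img = sct.CTImage(
        hu=np.random.default_rng(0).normal(size=(2, 8, 8)),
        voxel_size=(2.0, 1.5, 1.5),
        technique_id="t",
    )
    path = tmp_path / "vol.nii"
    sct.write_nifti(img, path)
    back = nib.load(path)
    assert np.allclose(np.transpose(back.get_fdata(), (2, 1, 0)), img.hu, atol=1e-4)
    assert back.header.get_zooms()[:3] == pytest.approx((1.5, 1.5, 2.0))
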