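"""Phantom geometry, conductivity table and dipole-source tests."""

from __future__ import annotations

import numpy as np
import pytest

from durasim import (
    ConfigurationError,
    Corrugation,
    GeometryError,
    SourceConfig,
    Tissue,
    ValidationError,
    VoxelModel,
    build_shell_phantom,
    builtin_conductivity_table,
    compute_cortical_normals,
    conductivity_from_table,
    realize_conductivity,
    replace_tissue,
    sample_dipole_field,
)
from durasim.phantom import TABLE1_RESISTIVITIES, default_head_radii

from conftest import SMALL_RADII


def brute_force_shell_labels(model, radii):
    """Independent distance-threshold classification of every voxel."""
    ctr = model.center_mm()
    labels = np.full(model.shape, int(Tissue.AIR_EXTERNAL), dtype=int)
    thresholds = [r for _, r in radii]
    tissues = [int(t) for t, _ in radii]
    for idx in np.ndindex(model.shape):
        pos = model.origin + model.voxel_size * np.array(idx)
        d = float(np.sqrt(((pos - ctr) ** 2).sum()))
        for t, thr in zip(tissues, thresholds):
            if d <= thr:
                labels[idx] = t
                break
    return labels


class TestShellPhantom:
    def test_counts_match_bruteforce_scan(self, small_phantom):
        expected = brute_force_shell_labels(small_phantom, SMALL_RADII)
        assert np.array_equal(small_phantom.labels, expected)

    def test_spherical_symmetry_of_labels(self, small_phantom):
        # with the phantom centered on the grid, labels are mirror-symmetric
        lab = small_phantom.labels
        for axis in range(3):
            assert np.array_equal(lab, np.flip(lab, axis=axis))

    def test_outer_boundary_is_external_air(self, small_phantom):
        lab = small_phantom.labels
        for face in (lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[:, :, 0], lab[:, :, -1]):
            assert np.all(face == int(Tissue.AIR_EXTERNAL))

    def test_corrugation_only_perturbs_cortical_interface(self):
        flat = build_shell_phantom(SMALL_RADII, (34, 34, 34), 2.0)
        wavy = build_shell_phantom(
            SMALL_RADII, (34, 34, 34), 2.0, corrugation=Corrugation(2.0, 4)
        )
        ctr = flat.center_mm()
        xx, yy, zz = flat.voxel_centers_mm()
        r = np.sqrt((xx - ctr[0]) ** 2 + (yy - ctr[1]) ** 2 + (zz - ctr[2]) ** 2)
        outside_band = (r < 12.0 - 2.0) | (r > 12.0 + 2.0)
        assert np.array_equal(flat.labels[outside_band], wavy.labels[outside_band])
        assert not np.array_equal(flat.labels, wavy.labels)

    def test_nesting_along_rays(self, small_phantom):
        # walking outward from the center, tissues appear in anatomical order
        order = {int(t): i for i, (t, _) in enumerate(SMALL_RADII)}
        order[int(Tissue.AIR_EXTERNAL)] = len(SMALL_RADII)
        ctr = small_phantom.center_mm()
        rng = np.random.default_rng(0)
        for _ in range(50):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ranks = []
            for t in np.linspace(0.0, 32.0, 200):
                pos = ctr + t * d
                idx = np.round((pos - small_phantom.origin) / small_phantom.voxel_size)
                idx = idx.astype(int)
                if np.any(idx < 0) or np.any(idx >= np.array(small_phantom.shape)):
                    break
                ranks.append(order[int(small_phantom.labels[tuple(idx)])])
            assert ranks == sorted(ranks)

    def test_non_increasing_radii_rejected(self):
        bad = [(Tissue.WHITE, 12.0), (Tissue.GRAY, 12.0), (Tissue.CSF, 18.0)]
        with pytest.raises(ConfigurationError):
            build_shell_phantom(bad, (34, 34, 34), 2.0)

    def test_phantom_touching_grid_boundary_rejected(self):
        with pytest.raises(GeometryError):
            build_shell_phantom(SMALL_RADII, (16, 16, 16), 2.0)

    def test_corrugation_breaking_nesting_rejected(self):
        with pytest.raises(ConfigurationError):
            build_shell_phantom(
                SMALL_RADII, (34, 34, 34), 2.0, corrugation=Corrugation(4.5, 4)
            )

    def test_default_head_radii_strictly_increasing(self):
        for h in (1.0, 1.5, 2.0, 4.0):
            radii = [r for _, r in default_head_radii(h)]
            assert all(b - a > 0 for a, b in zip(radii, radii[1:]))


class TestConductivityTable:
    def test_paper_rows_convert_to_printed_conductivities(self):
        table = builtin_conductivity_table()
        dura = table[Tissue.DURA]
        assert dura.mean_resistivity_ohm_cm == 1667
        assert dura.mean_conductivity_s_cm == pytest.approx(6e-4, rel=1e-3)
        assert dura.conductivity_s_m == pytest.approx(0.06, rel=1e-3)
        csf = table[Tissue.CSF]
        assert csf.mean_conductivity_s_cm == pytest.approx(1.54e-2, rel=1e-3)
        assert csf.conductivity_s_m == pytest.approx(1.54, rel=1e-3)

    def test_reciprocal_conversion(self):
        table = conductivity_from_table({Tissue.MUSCLE: (100.0, 50.0, 150.0)})
        assert table[Tissue.MUSCLE].mean_conductivity_s_cm == pytest.approx(0.01)
        assert table[Tissue.MUSCLE].conductivity_s_m == pytest.approx(1.0)

    def test_dura_to_csf_ratio_rounds_to_004(self):
        table = builtin_conductivity_table()
        ratio = table.conductivity_s_m(Tissue.DURA) / table.conductivity_s_m(Tissue.CSF)
        assert round(ratio, 2) == 0.04

    def test_bounds_bracket_means(self):
        table = builtin_conductivity_table()
        for e in table.entries.values():
            assert e.lower_resistivity_ohm_cm <= e.mean_resistivity_ohm_cm
            assert e.mean_resistivity_ohm_cm <= e.upper_resistivity_ohm_cm

    @pytest.mark.parametrize(
        "row",
        [
            {Tissue.MUSCLE: (-5.0, 1.0, 10.0)},
            {Tissue.MUSCLE: (0.0, 0.0, 0.0)},
            {Tissue.MUSCLE: (100.0, 150.0, 200.0)},  # lower > mean
        ],
    )
    def test_invalid_rows_rejected(self, row):
        with pytest.raises(ValidationError):
            conductivity_from_table(row)


class TestRealizeConductivity:
    def test_values_match_table_for_present_labels(self, small_phantom):
        table = builtin_conductivity_table()
        vol = realize_conductivity(small_phantom, table)
        present = [Tissue(v) for v in np.unique(small_phantom.labels)]
        expected = {table.conductivity_s_m(t) for t in present}
        assert set(np.unique(vol.sigma)) == expected

    def test_override_is_local(self, small_phantom):
        table = builtin_conductivity_table()
        base = realize_conductivity(small_phantom, table)
        halved = realize_conductivity(
            small_phantom, table,
            {Tissue.SKULL_HARD: 0.5 * table.conductivity_s_m(Tissue.SKULL_HARD)},
        )
        hard = small_phantom.mask(Tissue.SKULL_HARD)
        assert np.allclose(halved.sigma[hard], 0.5 * base.sigma[hard])
        assert np.array_equal(halved.sigma[~hard], base.sigma[~hard])

    def test_discussion_resistivity_override(self, small_phantom):
        # a hard skull of 24,000 Ohm*cm corresponds to 4.167e-5 S/cm
        table = builtin_conductivity_table()
        sigma_s_m = 100.0 / 24_000.0
        assert sigma_s_m / 100.0 == pytest.approx(4.167e-5, rel=1e-3)
        vol = realize_conductivity(small_phantom, table, {Tissue.SKULL_HARD: sigma_s_m})
        assert np.allclose(vol.sigma[small_phantom.mask(Tissue.SKULL_HARD)], sigma_s_m)

    def test_unmapped_label_rejected(self, small_phantom):
        table = conductivity_from_table({Tissue.WHITE: (700.0, 350.0, 1050.0)})
        with pytest.raises(ValidationError, match="GRAY"):
            realize_conductivity(small_phantom, table)


class TestReplaceTissue:
    def test_replacement_conserves_counts(self, small_phantom):
        n_dura = small_phantom.count(Tissue.DURA)
        n_csf = small_phantom.count(Tissue.CSF)
        out = replace_tissue(small_phantom, Tissue.DURA, Tissue.CSF)
        assert out.count(Tissue.DURA) == 0
        assert out.count(Tissue.CSF) == n_csf + n_dura
        assert out.labels.size == small_phantom.labels.size

    def test_identity_replacement(self, small_phantom):
        out = replace_tissue(small_phantom, Tissue.CSF, Tissue.CSF)
        assert np.array_equal(out.labels, small_phantom.labels)

    def test_absent_tissue_is_noop(self, small_phantom):
        out = replace_tissue(small_phantom, Tissue.EYE, Tissue.CSF)
        assert np.array_equal(out.labels, small_phantom.labels)

    def test_original_model_untouched(self, small_phantom):
        before = small_phantom.labels.copy()
        replace_tissue(small_phantom, Tissue.DURA, Tissue.CSF)
        assert np.array_equal(small_phantom.labels, before)


def angle_deg(a, b):
    cosang = np.clip(np.sum(a * b, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


class TestCorticalNormals:
    def test_sphere_normals_are_radial(self, small_phantom):
        normals = compute_cortical_normals(small_phantom)
        ctr = small_phantom.center_mm()
        pos = small_phantom.positions_mm(normals.voxels)
        radial = pos - ctr[None, :]
        radial /= np.linalg.norm(radial, axis=1)[:, None]
        assert np.all(angle_deg(normals.vectors, radial) < 5.0)
        assert np.allclose(np.linalg.norm(normals.vectors, axis=1), 1.0, atol=1e-9)

    def test_flat_slab_normals_point_up(self):
        labels = np.full((12, 12, 12), int(Tissue.CSF), dtype=np.int16)
        labels[:, :, :5] = int(Tissue.WHITE)
        labels[:, :, 5:8] = int(Tissue.GRAY)
        model = VoxelModel(labels, voxel_size=1.0)
        normals = compute_cortical_normals(model)
        inner = ~normals.radial_fallback
        assert np.all(angle_deg(normals.vectors[inner], np.array([0.0, 0.0, 1.0])) < 1e-6)

    def test_corrugated_normals_follow_analytic_gradient(self):
        corr = Corrugation(2.0, 4)
        model = build_shell_phantom(SMALL_RADII, (42, 42, 42), 1.5, corrugation=corr)
        # one-voxel smoothing keeps the corrugation wavelength sharp enough
        # for a meaningful comparison with the exact surface normal
        normals = compute_cortical_normals(model, smoothing_width_mm=1.5)
        ctr = model.center_mm()
        pos = model.positions_mm(normals.voxels) - ctr[None, :]
        r = np.linalg.norm(pos, axis=1)
        # restrict to gray voxels close to the corrugated white/gray interface
        near = np.abs(r - 12.0) < 3.0
        theta = np.arccos(np.clip(pos[near, 2] / r[near], -1, 1))
        phi = np.arctan2(pos[near, 1], pos[near, 0])
        r_surf = 12.0 + corr.radial_offset(theta, phi)
        analytic = np.array(
            [corr.analytic_normal(t, p, rr) for t, p, rr in zip(theta, phi, r_surf)]
        )
        angles = angle_deg(normals.vectors[near], analytic)
        # smoothing attenuates the corrugation slope, so a cone-style bound
        # (not exact agreement) is the right check on a 1.5 mm grid
        assert np.median(angles) < 12.0
        assert np.mean(angles) < 15.0

    def test_zero_gradient_falls_back_to_radial(self, small_phantom):
        # with almost no smoothing, gray voxels away from the white surface
        # see a numerically zero gradient and are flagged
        normals = compute_cortical_normals(small_phantom, smoothing_width_mm=0.4)
        assert normals.n_fallback > 0
        assert np.allclose(np.linalg.norm(normals.vectors, axis=1), 1.0, atol=1e-9)

    def test_missing_tissues_rejected(self):
        labels = np.full((10, 10, 10), int(Tissue.CSF), dtype=np.int16)
        with pytest.raises(ValidationError):
            compute_cortical_normals(VoxelModel(labels, 1.0))


class TestDipoleField:
    def test_magnitudes_uniform_within_range(self, small_phantom):
        normals = compute_cortical_normals(small_phantom)
        field = sample_dipole_field(small_phantom, normals, SourceConfig(seed=3))
        m = field.magnitudes_a_m
        assert len(field) == small_phantom.count(Tissue.GRAY)
        assert np.all((m >= 0) & (m <= 4e-4))
        se = (4e-4 / np.sqrt(12)) / np.sqrt(len(m))
        assert abs(m.mean() - 2e-4) < 3 * se

    def test_same_seed_is_bit_identical(self, small_phantom):
        normals = compute_cortical_normals(small_phantom)
        a = sample_dipole_field(small_phantom, normals, SourceConfig(seed=11))
        b = sample_dipole_field(small_phantom, normals, SourceConfig(seed=11))
        assert np.array_equal(a.magnitudes_a_m, b.magnitudes_a_m)
        assert np.array_equal(a.positions_mm, b.positions_mm)

    def test_degenerate_amplitude_interval(self, small_phantom):
        normals = compute_cortical_normals(small_phantom)
        cfg = SourceConfig(amplitude_min=1e-4, amplitude_max=1e-4, seed=0)
        field = sample_dipole_field(small_phantom, normals, cfg)
        assert np.all(field.magnitudes_a_m == 1e-4)

    def test_invalid_amplitude_range_rejected(self):
        with pytest.raises(ConfigurationError):
            SourceConfig(amplitude_min=2e-4, amplitude_max=1e-4)

    def test_empty_cortex_rejected(self):
        from durasim.phantom import CorticalNormals

        labels = np.full((10, 10, 10), int(Tissue.WHITE), dtype=np.int16)
        model = VoxelModel(labels, 1.0)
        empty = CorticalNormals(
            voxels=np.empty((0, 3), dtype=int),
            vectors=np.empty((0, 3)),
            radial_fallback=np.empty(0, dtype=bool),
        )
        with pytest.raises(ValidationError):
            sample_dipole_field(model, empty, SourceConfig(seed=0))
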