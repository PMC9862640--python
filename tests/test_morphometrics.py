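import numpy as np
import pytest
from skimage.draw import disk, ellipse

from cocoonsort import (
    AlignmentError,
    DigitizationError,
    EFADescriptor,
    ValidationError,
    align_to,
    digitize_outline,
    efa_decompose,
    efa_reconstruct,
    harmonic_increment_power,
    increment_power,
    procrustes_align,
    procrustes_distance,
    truncation_order,
)


def ellipse_outline(a=3.0, b=2.0, n=180, phase=0.0, center=(0.0, 0.0)):
    """Band-limited ellipse: pure harmonic-1 samples."""
    t = 2 * np.pi * np.arange(n) / n + phase
    return np.column_stack([center[0] + a * np.cos(t), center[1] + b * np.sin(t)])


def random_band_limited_outline(rng, n_harmonics=8, n_points=180, scale=40.0):
    """A closed random outline whose spectrum stops well below Nyquist."""
    coeff = rng.normal(0.0, 1.0, (n_harmonics, 4))
    coeff *= scale * 0.5 ** np.arange(n_harmonics)[:, None]
    coeff[0] = [scale, 0.0, 0.0, 0.7 * scale]
    desc = EFADescriptor(coefficients=coeff, a0=0.0, c0=0.0, n_points=n_points)
    return efa_reconstruct(desc, n_points=n_points).points


class TestDigitizeOutline:
    def test_disc_radii_constant(self):
        mask = np.zeros((201, 201), dtype=bool)
        rr, cc = disk((100, 100), 50.0)
        mask[rr, cc] = True
        outline = digitize_outline(mask)
        assert len(outline) == 180
        radii = np.hypot(outline.points[:, 0] - 100, outline.points[:, 1] - 100)
        assert np.all(np.abs(radii - 50.0) <= 0.5)

    def test_ellipse_matches_polar_form(self):
        mask = np.zeros((301, 301), dtype=bool)
        rr, cc = ellipse(150, 150, 60, 90)  # y semi-axis 60, x semi-axis 90
        mask[rr, cc] = True
        outline = digitize_outline(mask)
        theta = 2 * np.pi * np.arange(180) / 180
        a, b = 90.0, 60.0
        r_true = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        r_meas = np.hypot(outline.points[:, 0] - 150, outline.points[:, 1] - 150)
        assert np.abs(r_meas - r_true).max() <= 1.0

    def test_point_count_parameter(self):
        mask = np.zeros((101, 101), dtype=bool)
        rr, cc = disk((50, 50), 20.0)
        mask[rr, cc] = True
        assert len(digitize_outline(mask, n_points=90)) == 90

    def test_centroid_outside_region_rejected(self):
        # crescent: its center of mass falls in the carved-out hollow
        mask = np.zeros((201, 201), dtype=bool)
        rr, cc = disk((100, 100), 50.0)
        mask[rr, cc] = True
        rr, cc = disk((100, 118), 44.0, shape=mask.shape)
        mask[rr, cc] = False
        with pytest.raises(DigitizationError):
            digitize_outline(mask)

    def test_empty_mask_rejected(self):
        with pytest.raises(DigitizationError):
            digitize_outline(np.zeros((10, 10), dtype=bool))


class TestProcrustes:
    def test_rotated_translated_copy_aligns_exactly(self, rng):
        base = random_band_limited_outline(rng)
        ang = np.pi / 6
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        copy = base @ rot.T + np.array([17.0, -4.0])
        result = procrustes_align([base, copy])
        assert np.linalg.norm(result.outlines[0] - result.outlines[1]) < 1e-6

    def test_scaled_copy_aligns_under_full_gpa(self, rng):
        base = random_band_limited_outline(rng)
        result = procrustes_align([base, 2.0 * base])
        assert np.linalg.norm(result.outlines[0] - result.outlines[1]) < 1e-6
        assert procrustes_distance(base, 2.0 * base) < 1e-6

    def test_mean_shape_centered(self, rng):
        outlines = [random_band_limited_outline(rng) for _ in range(5)]
        result = procrustes_align(outlines)
        assert np.abs(result.mean_shape.mean(axis=0)).max() < 1e-9

    def test_idempotence(self, rng):
        outlines = [random_band_limited_outline(rng) for _ in range(6)]
        first = procrustes_align(outlines)
        second = procrustes_align(first.outlines)
        assert abs(second.residual_ss - first.residual_ss) < 1e-8 * max(
            first.residual_ss, 1.0
        )

    def test_align_to_reference_removes_pose(self, rng):
        base = random_band_limited_outline(rng)
        ang = 0.8
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        moved = 1.7 * (base @ rot.T) + np.array([3.0, 9.0])
        aligned = align_to(moved, base)
        reference = align_to(base, base)
        assert np.linalg.norm(aligned - reference) < 1e-9

    def test_degenerate_outline_rejected(self):
        flat = np.zeros((180, 2))
        with pytest.raises(AlignmentError):
            procrustes_align([flat, flat.copy()])


class TestEFA:
    def test_ellipse_concentrates_power_in_first_harmonic(self):
        desc = efa_decompose(ellipse_outline(a=50.0, b=30.0, phase=0.3), n=90)
        power = desc.harmonic_power
        assert power[0] / power.sum() > 0.9999

    def test_coefficient_count_is_4n(self, rng):
        pts = random_band_limited_outline(rng)
        for n in (1, 5, 90):
            desc = efa_decompose(pts, n)
            assert desc.coefficients.shape == (n, 4)
            assert desc.flat_coefficients().size == 4 * n

    def test_full_round_trip_recovers_points(self, rng):
        pts = random_band_limited_outline(rng)
        desc = efa_decompose(pts, 90)
        rec = efa_reconstruct(desc, k=90, n_points=180)
        rms = np.sqrt(np.mean((rec.points - pts) ** 2))
        assert rms < 1e-3

    def test_single_harmonic_reconstruction_is_ellipse(self, rng):
        pts = random_band_limited_outline(rng)
        desc = efa_decompose(pts, 90)
        rec = efa_reconstruct(desc, k=1, n_points=360).points
        # general conic through the points: algebraic residual ~ 0
        x, y = rec[:, 0], rec[:, 1]
        design = np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])
        _, sv, _ = np.linalg.svd(design, full_matrices=False)
        assert sv[-1] / sv[0] < 1e-6

    def test_dc_only_descriptor_is_constant_point(self):
        desc = EFADescriptor(
            coefficients=np.zeros((3, 4)), a0=4.0, c0=-2.0, n_points=180
        )
        rec = efa_reconstruct(desc, n_points=50).points
        assert np.allclose(rec, [4.0, -2.0])

    def test_harmonic_count_above_nyquist_rejected(self, rng):
        pts = random_band_limited_outline(rng)
        with pytest.raises(ValidationError):
            efa_decompose(pts, 91)
        desc = efa_decompose(pts, 10)
        with pytest.raises(ValidationError):
            efa_reconstruct(desc, k=11)

    def test_power_conserved_against_increment_series(self, rng):
        for _ in range(5):
            pts = random_band_limited_outline(rng)
            desc = efa_decompose(pts, 90)
            direct = increment_power(pts)
            spectral = harmonic_increment_power(desc)
            assert abs(direct - spectral) <= 1e-9 * direct

    def test_rotation_leaves_harmonic_power_invariant(self, rng):
        pts = random_band_limited_outline(rng)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        p0 = efa_decompose(pts, 20).harmonic_power
        p1 = efa_decompose(pts @ rot.T, 20).harmonic_power
        assert np.allclose(p0, p1, rtol=1e-9, atol=1e-12)

    def test_generator_analyzer_closure(self, rng):
        coeff = rng.normal(0.0, 1.0, (6, 4)) * 10.0
        desc = EFADescriptor(coefficients=coeff, a0=1.0, c0=2.0, n_points=180)
        pts = efa_reconstruct(desc, n_points=180).points
        back = efa_decompose(pts, 6)
        assert np.abs(back.coefficients - coeff).max() < 1e-6
        assert back.a0 == pytest.approx(1.0, abs=1e-9)

    def test_chord_method_agrees_on_near_uniform_outline(self):
        # near-circular outline: chord spacing is almost uniform, so the
        # chord-length and discrete formulations coincide to ~1% of scale
        t = 2 * np.pi * np.arange(360) / 360
        pts = np.column_stack(
            [40 * np.cos(t) + 0.5 * np.cos(3 * t), 40 * np.sin(t) + 0.5 * np.sin(3 * t)]
        )
        d_dft = efa_decompose(pts, 5, method="dft")
        d_chord = efa_decompose(pts, 5, method="chord")
        assert np.abs(d_dft.coefficients - d_chord.coefficients).max() < 0.015 * 40


class TestTruncation:
    def test_pure_ellipses_truncate_at_one(self, rng):
        descs = [
            efa_decompose(ellipse_outline(a=30 + i, b=20 + i, phase=0.1 * i), 90)
            for i in range(5)
        ]
        assert truncation_order(descs) == 1

    def test_full_fraction_keeps_all_harmonics(self, rng):
        pts = random_band_limited_outline(rng, n_harmonics=30)
        # add broadband content so every harmonic carries some power
        pts += rng.normal(0, 0.05, pts.shape)
        descs = [efa_decompose(pts, 90)]
        assert truncation_order(descs, fraction=1.0) == 90

    def test_default_fraction_value(self):
        from cocoonsort.morphometrics import DEFAULT_POWER_FRACTION

        assert DEFAULT_POWER_FRACTION == 0.99999

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            truncation_order([])
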