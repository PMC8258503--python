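"""Sector anisotropy and the mitochondrial damage index."""

import numpy as np
import pytest

from simquant import (
    GrayImage,
    SectorProfile,
    damage_batch,
    damage_index,
    fit_ellipse_axes,
    mann_whitney,
    radar_axes,
    sector_means,
)
from simquant.fourier import centered_frequencies, circular_window, forward_spectrum
from simquant.mitochondria import _sector_labels
from simquant.phantoms import (
    PlaneWaveSpec,
    RodFieldSpec,
    make_plane_wave,
    make_ring_phantom,
    make_rod_field,
)


def brute_force_sector_means(img: GrayImage) -> np.ndarray:
    """Per-bin angle classification oracle, independent of the
    vectorized label grid."""
    windowed = circular_window(img)
    n = windowed.pixels.shape[0]
    mags = np.abs(forward_spectrum(windowed).coeffs)
    sub = mags[1:, 1:]
    sub = 0.5 * (sub + sub[::-1, ::-1])
    sums = np.zeros(8)
    counts = np.zeros(8)
    for i in range(1, n):
        for j in range(1, n):
            v, u = i - n // 2, j - n // 2
            if u == 0 and v == 0:
                continue
            ang = np.degrees(np.arctan2(v, u))
            s = int(np.floor((ang + 22.5) / 45.0)) % 8
            sums[s] += sub[i - 1, j - 1]
            counts[s] += 1
    return sums / counts


class TestSectorMeans:
    def test_agrees_with_per_bin_angle_oracle(self, rng):
        for n in (8, 16, 32):
            img = GrayImage(rng.standard_normal((n, n)) + 5)
            profile = sector_means(img)
            oracle = brute_force_sector_means(img)
            assert np.allclose(profile.means, oracle, rtol=1e-12)

    def test_opposite_sectors_identical(self, rng):
        for _ in range(10):
            img = GrayImage(rng.standard_normal((32, 32)) + 3)
            p = sector_means(img)
            assert np.array_equal(p.means[:4], p.means[4:])
            assert np.array_equal(p.n_bins[:4], p.n_bins[4:])

    def test_vertical_stripes_peak_on_u_axis(self):
        img = make_plane_wave(PlaneWaveSpec(omega_x=0.4, omega_y=0.0))
        p = sector_means(img)
        assert int(np.argmax(p.means)) in (0, 4)

    def test_ring_phantom_axis_pairs_agree(self):
        p = sector_means(make_ring_phantom())
        assert p.means[0] == pytest.approx(p.means[2], rel=1e-9)
        assert p.means[1] == pytest.approx(p.means[3], rel=1e-9)

    def test_diagonal_bins_fall_in_odd_sectors(self):
        labels = _sector_labels(16)
        u, v = centered_frequencies(16)
        diag = (u == v) & (u > 0)
        assert set(labels[diag]) == {1}

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            sector_means(GrayImage(np.ones((4, 4)) + np.eye(4)))


class TestRadarAxes:
    @pytest.mark.parametrize(
        "means, major, minor, direction",
        [
            ((4, 2, 1, 2, 4, 2, 1, 2), 4.0, 1.0, 0),
            ((1, 5, 2, 2, 1, 5, 2, 2), 5.0, 2.0, 45),
            ((3, 3, 3, 3, 3, 3, 3, 3), 3.0, 3.0, 0),
        ],
    )
    def test_polygon_axis_extraction(self, means, major, minor, direction):
        profile = SectorProfile(np.array(means, float), np.ones(8, int))
        got_major, got_minor, got_dir = radar_axes(profile)
        assert (got_major, got_minor, got_dir) == (major, minor, direction)

    def test_all_zero_profile_rejected(self):
        profile = SectorProfile(np.zeros(8), np.ones(8, int))
        with pytest.raises(ValueError):
            radar_axes(profile)

    def test_ellipse_fit_recovers_exact_ellipse(self):
        # radial samples of an axis-aligned ellipse a=4, b=2
        theta = np.deg2rad(45.0 * np.arange(8))
        r = 1.0 / np.sqrt((np.cos(theta) / 4.0) ** 2 + (np.sin(theta) / 2.0) ** 2)
        profile = SectorProfile(r, np.ones(8, int))
        major, minor, direction = fit_ellipse_axes(profile)
        assert major == pytest.approx(4.0, rel=1e-9)
        assert minor == pytest.approx(2.0, rel=1e-9)
        assert direction == pytest.approx(0.0, abs=1e-6)


class TestDamageIndex:
    def test_isotropic_ring_is_undamaged_axes(self):
        r = damage_index(make_ring_phantom())
        assert r.damage_index >= 0.95

    def test_aligned_rods_strongly_anisotropic(self):
        vals = [damage_index(make_rod_field(RodFieldSpec(seed=s))).damage_index for s in range(5)]
        assert np.median(vals) <= 0.5

    def test_fragmented_rods_isotropic(self):
        vals = [
            damage_index(
                make_rod_field(RodFieldSpec(orientation_kappa=0.0, rod_length_mean=3.0, n_rods=300, seed=s))
            ).damage_index
            for s in range(5)
        ]
        assert np.median(vals) >= 0.8

    def test_rotation_by_90_degrees(self):
        img = make_rod_field(RodFieldSpec(seed=3))
        r1 = damage_index(img)
        r2 = damage_index(GrayImage(np.rot90(img.pixels).copy()))
        assert r2.damage_index == pytest.approx(r1.damage_index, rel=1e-9)
        assert (r2.major_axis_direction_deg - r1.major_axis_direction_deg) % 180 == 90

    def test_intensity_scale_invariance(self):
        img = make_rod_field(RodFieldSpec(seed=1))
        base = damage_index(img).damage_index
        scaled = damage_index(GrayImage(3.7 * img.pixels)).damage_index
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_orientation_dispersion_monotone(self):
        medians = []
        for kappa in (100.0, 1.0, 0.25, 0.0):
            vals = [
                damage_index(make_rod_field(RodFieldSpec(orientation_kappa=kappa, seed=s))).damage_index
                for s in range(8)
            ]
            medians.append(np.median(vals))
        assert all(np.diff(medians) > 0)

    def test_ellipse_estimator_agrees_on_direction(self):
        img = make_rod_field(RodFieldSpec(seed=0))
        radar = damage_index(img, estimator="radar")
        ellipse = damage_index(img, estimator="ellipse")
        assert 0 < ellipse.damage_index <= 1
        assert ellipse.damage_index <= 0.7  # clearly anisotropic under both


class TestDamageBatch:
    def test_identical_rois_mean_equals_single(self):
        img = make_rod_field(RodFieldSpec(seed=0))
        df = damage_batch([img] * 21, subjects=["p"] * 21)
        single = damage_index(img).damage_index
        assert df[df["kind"] == "subject_mean"]["damage_index"].iloc[0] == pytest.approx(single)

    def test_fragmented_exceeds_aligned_by_mwu(self):
        aligned = [make_rod_field(RodFieldSpec(seed=s)) for s in range(8)]
        frag = [
            make_rod_field(RodFieldSpec(orientation_kappa=0.0, rod_length_mean=3.0, n_rods=300, seed=s))
            for s in range(8)
        ]
        df = damage_batch(aligned + frag, subjects=["mga"] * 8 + ["tin"] * 8)
        rois = df[df["kind"] == "roi"]
        a = rois[rois["subject"] == "mga"]["damage_index"]
        b = rois[rois["subject"] == "tin"]["damage_index"]
        res = mann_whitney(b, a)
        assert res.p_two_sided < 0.01
        assert b.median() > a.median()

    def test_label_mapping_preserved(self):
        imgs = [make_rod_field(RodFieldSpec(seed=s)) for s in range(3)]
        df = damage_batch(imgs, subjects=["x", "y", "x"], roi_ids=["a", "b", "c"])
        rois = df[df["kind"] == "roi"]
        assert list(rois["roi_id"]) == ["a", "b", "c"]
        assert list(rois["subject"]) == ["x", "y", "x"]
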