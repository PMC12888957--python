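"""Spot detection, 3D linking, geometry, intensity and classification."""

import numpy as np
import pytest

from fntdose.detect import (
    ClassificationParams,
    DetectionParams,
    ImageStack,
    LinkingParams,
    Spot,
    Track,
    classify_track,
    compute_track_geometry,
    compute_track_intensity,
    detect_spots,
    extract_tracks,
    link_spots,
)
from fntdose.synthetic import FieldConfig, NoiseConfig, render_stack, sample_tracks
from tests.conftest import make_track

DEPTHS = 2.0 + 2.0 * np.arange(11)


def gaussian_slice(shape=(128, 128), center_px=(40.0, 64.0), amp=1000.0,
                   sigma_px=2.0, background=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = background + amp * np.exp(
        -0.5 * (((yy - center_px[0]) / sigma_px) ** 2
                + ((xx - center_px[1]) / sigma_px) ** 2))
    return img


class TestDetectSpots:
    def test_blank_slice(self):
        assert detect_spots(np.full((64, 64), 100.0)) == []

    def test_single_gaussian_centroid_and_peak(self):
        pixel = 100.0 / 512.0
        img = gaussian_slice(center_px=(40.3, 64.6))
        spots = detect_spots(img, pixel_um=pixel)
        assert len(spots) == 1
        s = spots[0]
        # centroid within half a pixel of truth
        assert s.centroid_xy_um[0] == pytest.approx((64.6 + 0.5) * pixel,
                                                    abs=0.5 * pixel)
        assert s.centroid_xy_um[1] == pytest.approx((40.3 + 0.5) * pixel,
                                                    abs=0.5 * pixel)
        # refined peak recovers the amplitude despite the sub-pixel offset
        assert s.max_intensity == pytest.approx(1000.0, rel=0.01)

    def test_two_separated_spots(self):
        img = gaussian_slice() + gaussian_slice(center_px=(90.0, 30.0)) - 100.0
        spots = detect_spots(img)
        assert len(spots) == 2

    def test_nonfinite_rejected(self):
        img = np.full((32, 32), 100.0)
        img[3, 3] = np.nan
        with pytest.raises(Exception):
            detect_spots(img)


def chain_spots(theta_deg=0.0, azimuth_deg=0.0, start=(50.0, 50.0),
                n=11, intensity=500.0):
    """Ideal spot chain along a straight track."""
    t = np.tan(np.radians(theta_deg))
    phi = np.radians(azimuth_deg)
    return [
        Spot(slice_index=j,
             centroid_xy_um=(start[0] + DEPTHS[j] * t * np.cos(phi),
                             start[1] + DEPTHS[j] * t * np.sin(phi)),
             max_intensity=intensity, area_px=10)
        for j in range(n)
    ]


class TestLinking:
    def test_single_full_chain(self):
        spots = chain_spots(theta_deg=20.0)
        per_slice = [[s for s in spots if s.slice_index == j] for j in range(11)]
        tracks = link_spots(per_slice, DEPTHS)
        assert len(tracks) == 1
        assert tracks[0].n_slices_spanned == 11

    def test_two_parallel_chains(self):
        a = chain_spots(start=(20.0, 20.0))
        b = chain_spots(start=(80.0, 80.0))
        per_slice = [[s for s in a + b if s.slice_index == j] for j in range(11)]
        tracks = link_spots(per_slice, DEPTHS)
        assert len(tracks) == 2
        assert all(t.n_slices_spanned == 11 for t in tracks)
        assert not any(t.overlap for t in tracks)

    def test_permutation_invariance(self, rng):
        chains = [chain_spots(theta_deg=th, start=(x, y))
                  for th, x, y in [(0, 20, 20), (15, 70, 30), (30, 40, 80)]]
        allspots = [s for c in chains for s in c]

        def run(order):
            per_slice = [[allspots[i] for i in order
                          if allspots[i].slice_index == j] for j in range(11)]
            tracks = link_spots(per_slice, DEPTHS)
            return sorted(
                tuple(sorted((s.slice_index, round(s.centroid_xy_um[0], 6))
                             for s in t.spots)) for t in tracks)

        base = run(range(len(allspots)))
        for _ in range(3):
            assert run(rng.permutation(len(allspots))) == base

    def test_singletons_reported(self):
        lone = Spot(slice_index=5, centroid_xy_um=(10.0, 10.0),
                    max_intensity=400.0, area_px=8)
        per_slice = [[] for _ in range(11)]
        per_slice[5] = [lone]
        tracks = link_spots(per_slice, DEPTHS)
        assert len(tracks) == 1
        assert tracks[0].n_slices_spanned == 1

    def test_recovers_rendered_field(self, rng):
        # moderately dense rendered field: nearly all ion tracks recovered
        # with the right spot membership
        config = FieldConfig(fluence_per_cm2=5e4, delta_fraction=0.0, seed=9)
        n_found, n_truth = 0, 0
        for _ in range(10):
            area = (100e-4) ** 2
            tracks = sample_tracks(config, area, rng)
            stack, manifest = render_stack(tracks, config, rng)
            found = extract_tracks(stack)
            truth = [t for t in manifest["tracks"] if len(t["spots"]) >= 5]
            n_truth += len(truth)
            for g in truth:
                gx = {s["slice_index"]: (s["x_um"], s["y_um"])
                      for s in g["spots"]}
                for t in found:
                    hits = sum(
                        1 for sp in t.spots if sp.slice_index in gx
                        and np.hypot(sp.centroid_xy_um[0] - gx[sp.slice_index][0],
                                     sp.centroid_xy_um[1] - gx[sp.slice_index][1])
                        < 0.8)
                    if hits >= len(gx) - 1 and t.n_slices_spanned >= 5:
                        n_found += 1
                        break
        assert n_truth >= 30
        assert n_found >= 0.96 * n_truth


class TestGeometry:
    @pytest.mark.parametrize("theta,tol", [(0.0, 1e-9), (45.0, 1e-6),
                                           (60.0, 0.5)])
    def test_polar_angle_from_displacement(self, theta, tol):
        tr = Track(spots=chain_spots(theta_deg=theta))
        polar, _, _ = compute_track_geometry(tr, DEPTHS)
        assert polar == pytest.approx(theta, abs=max(tol, 1e-9))

    def test_lateral_346_per_2um_is_60deg(self):
        # displacement of 3.46 um per 2 um depth step: arctan(sqrt(3))
        spots = [Spot(j, (50.0 + j * 3.46, 50.0), 500.0, 10) for j in range(6)]
        tr = Track(spots=spots)
        polar, _, _ = compute_track_geometry(tr, DEPTHS)
        assert polar == pytest.approx(60.0, abs=0.5)

    def test_identical_centroids_theta_zero(self):
        spots = [Spot(0, (10.0, 10.0), 500.0, 10),
                 Spot(1, (10.0, 10.0), 500.0, 10)]
        polar, _, depth = compute_track_geometry(Track(spots=spots), DEPTHS)
        assert polar == 0.0
        assert depth == pytest.approx(2.0)

    def test_noiseless_angle_recovery_through_rendering(self, noiseless_config):
        for theta in (0.0, 15.0, 30.0, 45.0, 60.0):
            track = make_track(theta=theta, azimuth=30.0, entry=(30.0, 40.0))
            stack, _ = render_stack([track], noiseless_config,
                                    np.random.default_rng(0))
            found = extract_tracks(stack)
            assert len(found) == 1
            assert found[0].polar_deg == pytest.approx(theta, abs=1.0)


class TestIntensity:
    def test_middle_slice_examples(self):
        t1 = Track(spots=[Spot(j, (0, 0), m, 5)
                          for j, m in enumerate([10.0, 20.0, 30.0])])
        assert compute_track_intensity(t1) == 20.0
        t2 = Track(spots=[Spot(j, (0, 0), m, 5)
                          for j, m in enumerate([5.0, 10.0, 20.0, 30.0, 5.0])])
        assert compute_track_intensity(t2) == pytest.approx(20.0)

    def test_short_track_undefined(self):
        t = Track(spots=[Spot(0, (0, 0), 10.0, 5), Spot(1, (0, 0), 20.0, 5)])
        assert compute_track_intensity(t) is None

    def test_rendered_amplitude_round_trip(self, noiseless_config):
        # normal-incidence track: measured intensity equals the calibrated
        # amplitude within 1%
        track = make_track(theta=0.0, let=4.0)
        stack, _ = render_stack([track], noiseless_config,
                                np.random.default_rng(0))
        found = extract_tracks(stack)
        expected = noiseless_config.intensity_model(4.0)
        assert found[0].intensity == pytest.approx(expected, rel=0.01)


class TestClassification:
    def test_out_of_field_rules(self):
        short = Track(spots=chain_spots(n=3))
        long = Track(spots=chain_spots(n=11))
        assert classify_track(short, "out_of_field", DEPTHS) == "delta"
        assert classify_track(long, "out_of_field", DEPTHS) == "ion"

    def test_alpha_region_range_rule(self):
        # vanishes below 16 um (slices at 2..14) -> alpha reference track
        shallow = Track(spots=chain_spots(n=7))
        deep = Track(spots=chain_spots(n=11))
        assert classify_track(shallow, "alpha_ref", DEPTHS) == "alpha_ref"
        assert classify_track(deep, "alpha_ref", DEPTHS) == "ion"

    def test_overlap_takes_precedence(self):
        t = Track(spots=chain_spots(n=11), overlap=True)
        assert classify_track(t, "out_of_field", DEPTHS) == "rejected_overlap"

    def test_partition_is_complete(self, default_config, rng):
        tracks = sample_tracks(default_config, (100e-4) ** 2, rng)
        stack, _ = render_stack(tracks, default_config, rng)
        found = extract_tracks(stack)
        labels = {t.classification for t in found}
        assert labels <= {"ion", "delta", "alpha_ref", "rejected_overlap"}
        counts = sum(1 for t in found)
        assert counts == len(found)


class TestImageStackIO:
    def test_tiff_round_trip(self, single_track_stack, tmp_path):
        stack, _, _ = single_track_stack
        path = tmp_path / "stack.tiff"
        stack.to_tiff(path)
        back = ImageStack.from_tiff(path)
        assert back.n_slices == stack.n_slices
        assert back.pixel_um == pytest.approx(stack.pixel_um)
        assert back.region == stack.region
        assert np.allclose(back.voxels, np.clip(np.rint(stack.voxels), 0, 65535))

    def test_geometry_validation(self):
        with pytest.raises(Exception):
            ImageStack(voxels=np.zeros((3, 8, 8)),
                       slice_depths_um=np.array([2.0, 2.0, 4.0]))
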