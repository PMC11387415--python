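"""Drift correction, detection, registration, and transient extraction."""

import numpy as np
import pytest

from dominoarray.imaging import (
    AffineTransform2D,
    DriftTrace,
    Movie,
    SpotRecord,
    aperture_intensity,
    detect_appearing_spots,
    detect_fiducials,
    estimate_drift,
    extract_transient,
    pair_colocalized,
    register_channels,
)
from dominoarray.lattice import LatticeModel, LatticeTrajectory
from dominoarray.optics import OpticsConfig, StructurePlacement, render_movie


def _turn_on_scene(
    n_spots,
    rng,
    transform_times=None,
    image_size=(96, 96),
    duration=600.0,
    n_fiducials=3,
    drift_velocity=(0.0, 0.0),
    chromatic_offset=(0.0, 0.0),
    bleach=0.0,
):
    """Render a controlled scene of turn-on emitters at default SNR."""
    lattice = LatticeModel(grid=np.ones((1, 1), bool), J=0.0, k0=1.0)
    opt = OpticsConfig(
        image_size=image_size,
        total_duration=duration,
        n_fiducials=n_fiducials,
        drift_velocity=drift_velocity,
        drift_jitter=0.0,
        chromatic_offset=chromatic_offset,
        bleach_rate={"red": bleach, "green": bleach},
    )
    margin, min_sep = 8.0, 6.0
    pts = []
    while len(pts) < n_spots:
        x = rng.uniform(margin, image_size[1] - margin)
        y = rng.uniform(margin, image_size[0] - margin)
        if all((x - a) ** 2 + (y - b) ** 2 >= min_sep**2 for a, b in pts):
            pts.append((x, y))
    if transform_times is None:
        transform_times = (
            rng.uniform(100.0, duration - 150.0, n_spots) if n_spots else np.zeros(0)
        )
    structures = [
        StructurePlacement(
            x=x, y=y, probes={"red": (0, 0), "green": (0, 0)},
            trajectory=LatticeTrajectory(
                events=((float(t), (0, 0), 1),), duration=duration, seed=0, model=lattice
            ),
        )
        for (x, y), t in zip(pts, transform_times)
    ]
    ds = render_movie(structures, opt, seed=int(rng.integers(2**31 - 1)))
    return ds, np.asarray(pts), np.asarray(transform_times)


class TestFiducials:
    def test_always_on_emitters_found_with_subpixel_accuracy(self, rng):
        ds, _, _ = _turn_on_scene(0, rng, image_size=(64, 64), duration=120.0, n_fiducials=3)
        found = detect_fiducials(ds.movies["red"])
        assert len(found) == 3
        for f in found:
            d = np.linalg.norm(ds.fiducials_xy - [f.x, f.y], axis=1).min()
            assert d < 0.3

    def test_background_only_movie_yields_no_fiducials(self, rng):
        frames = rng.poisson(20.0, size=(30, 48, 48)).astype(np.uint16)
        movie = Movie(frames=frames, timestamps=np.arange(30.0), channel="red")
        assert detect_fiducials(movie) == []

    def test_turn_on_emitter_not_a_fiducial(self, rng):
        ds, _, _ = _turn_on_scene(
            1, rng, transform_times=[60.0], image_size=(64, 64),
            duration=120.0, n_fiducials=0,
        )
        assert detect_fiducials(ds.movies["red"]) == []


class TestDrift:
    def test_linear_drift_recovered(self, rng):
        ds, _, _ = _turn_on_scene(
            0, rng, image_size=(64, 64), duration=300.0, n_fiducials=4,
            drift_velocity=(2.0 / 300.0, -2.0 / 300.0),
        )
        movie = ds.movies["red"]
        fids = detect_fiducials(movie)
        assert len(fids) == 4
        trace = estimate_drift(movie, fids)
        err = trace.shifts - ds.drift["red"]
        rms = np.sqrt(np.mean(err**2))
        assert rms < 0.2

    def test_no_drift_gives_flat_trace(self, rng):
        ds, _, _ = _turn_on_scene(0, rng, image_size=(64, 64), duration=200.0, n_fiducials=3)
        movie = ds.movies["red"]
        trace = estimate_drift(movie, detect_fiducials(movie))
        assert np.sqrt(np.mean(trace.shifts**2)) < 0.1

    def test_no_fiducials_downgrades_to_identity(self, rng):
        frames = rng.poisson(20.0, size=(30, 48, 48)).astype(np.uint16)
        movie = Movie(frames=frames, timestamps=np.arange(30.0), channel="red")
        trace = estimate_drift(movie, [])
        assert np.all(trace.shifts == 0.0)


class TestRegistration:
    def _spots(self, xy, channel="red"):
        return [SpotRecord(channel=channel, x=x, y=y, first_frame=0, is_fiducial=True)
                for x, y in xy]

    def test_translation_offset_recovered(self, rng):
        ds, _, _ = _turn_on_scene(
            0, rng, image_size=(64, 64), duration=150.0, n_fiducials=5,
            chromatic_offset=(1.5, -0.8),
        )
        fr = detect_fiducials(ds.movies["red"])
        fg = detect_fiducials(ds.movies["green"])
        tr = register_channels(fr, fg)
        # green = red + offset, so green -> red removes the offset
        mapped = tr.apply(np.array([[30.0, 30.0]]))[0]
        assert np.allclose(mapped, [30.0 - 1.5, 30.0 + 0.8], atol=0.1)

    def test_identical_coordinates_give_identity(self):
        xy = [(10.0, 12.0), (40.0, 8.0), (25.0, 30.0)]
        tr = register_channels(self._spots(xy), self._spots(xy, "green"))
        assert np.allclose(tr.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)

    def test_exact_affine_recovered_from_three_pairs(self):
        A = np.array([[1.01, 0.02, 1.2], [-0.015, 0.99, -0.7]])
        green = np.array([[10.0, 10.0], [40.0, 12.0], [20.0, 35.0]])
        red = (np.hstack([green, np.ones((3, 1))]) @ A.T)
        tr = register_channels(self._spots(red), self._spots(green, "green"))
        assert np.allclose(tr.matrix, A, atol=1e-8)

    def test_no_pairs_gives_identity_fallback(self):
        tr = register_channels([], [])
        assert np.allclose(tr.matrix, AffineTransform2D.identity().matrix)


class TestAppearingSpots:
    def test_turn_on_spots_detected_with_low_false_positive_rate(self, rng):
        ds, pts, _ = _turn_on_scene(20, rng, duration=600.0)
        movie = ds.movies["red"]
        drift = estimate_drift(movie, detect_fiducials(movie))
        spots = detect_appearing_spots(movie, drift)
        det = np.array([[s.x, s.y] for s in spots]).reshape(-1, 2)
        hits = sum(
            np.linalg.norm(det - p, axis=1).min() < 1.5 for p in pts if len(det)
        )
        false_pos = sum(
            np.linalg.norm(pts - d, axis=1).min() >= 1.5 for d in det
        )
        assert hits >= 19  # >= 95% of 20
        assert false_pos <= 1

    def test_background_only_movie_has_no_appearing_spots(self, rng):
        frames = rng.poisson(20.0, size=(60, 48, 48)).astype(np.uint16)
        movie = Movie(frames=frames, timestamps=np.arange(60.0), channel="red")
        assert detect_appearing_spots(movie, DriftTrace.identity(60)) == []

    def test_fiducials_are_not_appearing_spots(self, rng):
        ds, _, _ = _turn_on_scene(0, rng, image_size=(64, 64), duration=200.0, n_fiducials=4)
        movie = ds.movies["red"]
        spots = detect_appearing_spots(movie, DriftTrace.identity(movie.n_frames))
        assert spots == []

    def test_first_appearance_frame_near_truth(self, rng):
        times = np.array([80.0, 200.0, 350.0])
        ds, pts, tt = _turn_on_scene(3, rng, transform_times=times, duration=500.0)
        movie = ds.movies["red"]
        spots = detect_appearing_spots(movie, DriftTrace.identity(movie.n_frames))
        assert len(spots) == 3
        for s in spots:
            j = int(np.argmin(np.linalg.norm(pts - [s.x, s.y], axis=1)))
            assert abs(s.first_frame - np.ceil(tt[j])) <= 2

    def test_detection_is_translation_equivariant(self, rng):
        ds, _, _ = _turn_on_scene(5, rng, image_size=(72, 72), duration=300.0, n_fiducials=0)
        movie = ds.movies["red"]
        shifted = Movie(
            frames=np.roll(movie.frames, shift=(3, -2), axis=(1, 2)),
            timestamps=movie.timestamps,
            channel="red",
        )
        a = detect_appearing_spots(movie, DriftTrace.identity(movie.n_frames))
        b = detect_appearing_spots(shifted, DriftTrace.identity(movie.n_frames))
        xy_a = sorted((round(s.x + -2, 1), round(s.y + 3, 1)) for s in a)
        xy_b = sorted((round(s.x, 1), round(s.y, 1)) for s in b)
        assert len(a) == len(b)
        for (xa, ya), (xb, yb) in zip(xy_a, xy_b):
            assert abs(xa - xb) < 0.2 and abs(ya - yb) < 0.2


class TestTransients:
    def test_constant_emitter_recovers_photon_rate(self, rng):
        ds, pts, _ = _turn_on_scene(1, rng, transform_times=[0.5], duration=200.0)
        movie = ds.movies["red"]
        spot = SpotRecord(channel="red", x=pts[0][0], y=pts[0][1], first_frame=1)
        tr = extract_transient(movie, DriftTrace.identity(movie.n_frames), spot)
        expected = ds.optics.photon_rate * 0.95  # disk captures ~95% of the PSF
        assert tr.intensities[5:].mean() == pytest.approx(expected, rel=0.1)

    def test_dark_position_has_zero_mean(self, rng):
        frames = rng.poisson(20.0, size=(100, 48, 48)).astype(np.uint16)
        movie = Movie(frames=frames, timestamps=np.arange(100.0), channel="red")
        spot = SpotRecord(channel="red", x=24.0, y=24.0, first_frame=0)
        tr = extract_transient(movie, DriftTrace.identity(100), spot)
        assert abs(tr.intensities.mean()) < 3 * tr.intensities.std() / 10

    def test_background_subtraction_unbiased_over_many_disks(self, rng):
        frames = rng.poisson(20.0, size=(100, 64, 64)).astype(np.uint16)
        movie = Movie(frames=frames, timestamps=np.arange(100.0), channel="red")
        vals = []
        for _ in range(1000):
            x = rng.uniform(10, 54)
            y = rng.uniform(10, 54)
            t = int(rng.integers(100))
            vals.append(aperture_intensity(movie.frames[t], x, y))
        vals = np.asarray(vals)
        assert abs(vals.mean()) < 3 * vals.std() / np.sqrt(len(vals))

    def test_turn_on_transition_within_one_frame(self, rng):
        ds, pts, _ = _turn_on_scene(1, rng, transform_times=[100.3], duration=300.0)
        movie = ds.movies["red"]
        spot = SpotRecord(channel="red", x=pts[0][0], y=pts[0][1], first_frame=101)
        tr = extract_transient(movie, DriftTrace.identity(movie.n_frames), spot)
        on = ds.optics.photon_rate * 0.95
        assert tr.intensities[:100].mean() < 0.1 * on
        assert tr.intensities[101:].mean() > 0.8 * on

    def test_drift_corrected_extraction_matches_undrifted_scene(self):
        """Shot noise aside, drift correction leaves transients unchanged.

        Rendered at very high photon counts so that any systematic error of
        shift-corrected aperture placement would dominate the comparison.
        """
        lattice = LatticeModel(grid=np.ones((1, 1), bool), J=0.0, k0=1.0)
        traj = LatticeTrajectory(
            events=((50.0, (0, 0), 1),), duration=300.0, seed=0, model=lattice
        )
        x, y = 30.4, 27.8

        def scene(vel):
            opt = OpticsConfig(
                image_size=(64, 64), total_duration=300.0, n_fiducials=0,
                photon_rate=2.0e5, background=100.0, residual_fraction=0.0,
                drift_velocity=vel, drift_jitter=0.0,
            )
            s = StructurePlacement(
                x=x, y=y, probes={"red": (0, 0), "green": (0, 0)}, trajectory=traj
            )
            return render_movie([s], opt, seed=5)

        ds0 = scene((0.0, 0.0))
        ds1 = scene((2.0 / 300.0, 1.5 / 300.0))
        spot = SpotRecord(channel="red", x=x, y=y, first_frame=51)
        t0 = extract_transient(ds0.movies["red"], DriftTrace.identity(300), spot)
        t1 = extract_transient(
            ds1.movies["red"], DriftTrace(shifts=ds1.drift["red"]), spot
        )
        on = np.median(t0.intensities[60:])
        rms = np.sqrt(np.mean((t0.intensities[60:] - t1.intensities[60:]) ** 2))
        assert rms < 0.05 * on


class TestColocalization:
    def _spot(self, x, y, ch="red", ff=0):
        return SpotRecord(channel=ch, x=x, y=y, first_frame=ff)

    def test_coincident_spots_all_paired(self):
        red = [self._spot(10, 10), self._spot(30, 12)]
        green = [self._spot(10, 10, "green"), self._spot(30, 12, "green")]
        pairs, ur, ug = pair_colocalized(red, green, AffineTransform2D.identity(), 1.5)
        assert len(pairs) == 2 and not ur and not ug

    def test_distant_spots_stay_unpaired(self):
        red = [self._spot(10, 10)]
        green = [self._spot(15, 10, "green")]
        pairs, ur, ug = pair_colocalized(red, green, AffineTransform2D.identity(), 1.5)
        assert pairs == [] and len(ur) == 1 and len(ug) == 1

    def test_rendered_dataset_pairs_without_mismatches(self, five_dataset):
        ds = five_dataset
        fr = detect_fiducials(ds.movies["red"])
        fg = detect_fiducials(ds.movies["green"])
        dr = estimate_drift(ds.movies["red"], fr)
        dg = estimate_drift(ds.movies["green"], fg)
        tr = register_channels(fr, fg)
        sr = detect_appearing_spots(ds.movies["red"], dr)
        sg = detect_appearing_spots(ds.movies["green"], dg)
        pairs, _, _ = pair_colocalized(sr, sg, tr, 1.5)
        truth = ds.ground_truth[["x_px", "y_px"]].to_numpy()

        def structure_of(spot):
            return int(np.argmin(np.linalg.norm(truth - [spot.x, spot.y], axis=1)))

        both = {structure_of(s) for s in sr} & {structure_of(s) for s in sg}
        assert len(pairs) >= 0.95 * len(both)
        for a, b in pairs:
            assert structure_of(a) == structure_of(b)  # no cross-structure mispairs
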