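"""Tracking tests: exact geometries, termination rules, determinism."""

import numpy as np
import pytest

from tumortract import phantom, recon, tracking
from tumortract.recon import PeakField
from tumortract.tracking import Streamline, TrackingParams

from conftest import straight_peak_field


def _peak_field_from_directions(dir_fn, shape, voxel_size=(1.0, 1.0, 1.0),
                                qa_fn=None):
    """Build a synthetic single-peak field from a direction function of the
    voxel-center world coordinate (returning None for empty voxels)."""
    d = np.zeros(shape + (1, 3))
    qa = np.zeros(shape + (1,))
    n = np.zeros(shape, dtype=np.int32)
    vs = np.asarray(voxel_size)
    for idx in np.ndindex(shape):
        x = (np.asarray(idx) + 0.5) * vs
        vec = dir_fn(x)
        if vec is None:
            continue
        vec = np.asarray(vec, float)
        d[idx + (0,)] = vec / np.linalg.norm(vec)
        qa[idx + (0,)] = 1.0 if qa_fn is None else qa_fn(x)
        n[idx] = 1
    aff = np.eye(4)
    aff[:3, :3] = np.diag(vs)
    aff[:3, 3] = 0.5 * vs
    return PeakField(directions=d, qa=qa, n_peaks=n,
                     voxel_size=tuple(voxel_size), affine=aff)


class TestSeedPoints:
    def test_count_and_containment(self):
        mask = np.zeros((5, 5, 5), bool)
        mask.reshape(-1)[:10] = True
        aff = np.eye(4)
        aff[:3, 3] = 0.5
        seeds = tracking.seed_points(mask, aff, seeds_per_voxel=2, seed=0)
        assert len(seeds) == 20
        vox = seeds - 0.5   # inverse of the unit affine
        idx = np.rint(vox).astype(int)
        assert mask[idx[:, 0], idx[:, 1], idx[:, 2]].all()

    def test_determinism(self):
        mask = np.ones((4, 4, 4), bool)
        a = tracking.seed_points(mask, np.eye(4), 1, seed=3)
        b = tracking.seed_points(mask, np.eye(4), 1, seed=3)
        assert np.array_equal(a, b)

    def test_full_grid_count(self):
        mask = np.ones((40, 40, 20), bool)
        seeds = tracking.seed_points(mask, np.eye(4), 1, seed=0)
        assert len(seeds) == 32000

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            tracking.seed_points(np.zeros((3, 3, 3), bool), np.eye(4))


class TestStreamlineLength:
    @pytest.mark.parametrize(
        "pts, expected",
        [
            (np.column_stack([np.arange(11) * 0.3,
                              np.zeros(11), np.zeros(11)]), 3.0),
            (np.array([[0.0, 0, 0], [5.0, 0, 0]]), 5.0),
            (np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1.0, 0]]), 2.0),
        ],
    )
    def test_arithmetic(self, pts, expected):
        assert tracking.streamline_length(Streamline(points=pts)) == \
            pytest.approx(expected, abs=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            Streamline(points=np.array([[0.0, 0, 0]]))


class TestTrackStreamline:
    def test_straight_line_spacing(self):
        """Uniform +x field: straight track spanning the volume with exact
        0.3 mm consecutive spacing."""
        peaks = straight_peak_field(shape=(40, 10, 10))
        sl = tracking.track_streamline(peaks, [20.0, 5.0, 5.0])
        pts = sl.points
        assert np.ptp(pts[:, 1]) < 1e-9 and np.ptp(pts[:, 2]) < 1e-9
        spacing = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert np.allclose(spacing, 0.3, atol=1e-6)
        assert sl.length > 37.0   # reaches both volume faces

    def test_terminates_at_90deg_plane(self):
        """Abrupt 90-degree direction change exceeds the 45-degree rule."""
        def field(x):
            return (1.0, 0.0, 0.0) if x[0] < 20 else (0.0, 1.0, 0.0)

        peaks = _peak_field_from_directions(field, (40, 40, 5))
        sl = tracking.track_streamline(peaks, [5.0, 20.0, 2.5])
        assert sl.points[:, 0].max() <= 21.0

    def test_circular_arc_length(self):
        """Half-annulus field: tracked length within 5% of the analytic
        arc length pi * r."""
        c = np.array([30.0, 30.0])
        r = 20.0

        def field(x):
            dx = x[:2] - c
            rho = np.linalg.norm(dx)
            if abs(rho - r) > 4.0 or x[1] < c[1]:   # upper half-annulus
                return None
            return (-dx[1] / rho, dx[0] / rho, 0.0)

        peaks = _peak_field_from_directions(field, (60, 60, 5))
        sl = tracking.track_streamline(peaks, [c[0] + r, c[1] + 0.5, 2.5],
                                       TrackingParams(qa_termination=0.5))
        assert sl.length == pytest.approx(np.pi * r, rel=0.05)

    def test_seed_in_zero_peak_voxel(self):
        peaks = straight_peak_field(shape=(10, 10, 10))
        peaks.qa[:5] = 0.0
        peaks.n_peaks[:5] = 0
        peaks.directions[:5] = 0.0
        assert tracking.track_streamline(peaks, [2.0, 5.0, 5.0]) is None


class TestTrackAll:
    def test_empty_seed_list(self):
        peaks = straight_peak_field(shape=(5, 5, 5))
        tg = tracking.track_all(peaks, np.empty((0, 3)))
        assert len(tg) == 0

    def test_bit_reproducible(self):
        peaks = straight_peak_field(shape=(20, 20, 10))
        seeds = tracking.seed_points(np.ones((20, 20, 10), bool),
                                     peaks.affine, 1, seed=5)[:50]
        a = tracking.track_all(peaks, seeds)
        b = tracking.track_all(peaks, seeds)
        assert len(a) == len(b)
        for s, t in zip(a.streamlines, b.streamlines):
            assert np.array_equal(s.points, t.points)

    def test_lengths_within_window_and_turn_rule(self):
        """Phantom-wide invariants: emitted lengths in [min, max]; no
        consecutive turn exceeds the angular threshold."""
        spec = phantom.bundle_crossing_spec(2)
        gtab = phantom.make_gradient_table(64, 1000.0, seed=1)
        vol, truth = phantom.simulate_dwi(spec, gtab, snr=30, seed=2)
        odf = recon.reconstruct_sdf(vol, mask=truth.bundle_masks.any(0))
        peaks = recon.extract_peaks(odf)
        seeds = tracking.seed_points(truth.bundle_masks.any(0),
                                     spec.affine, 1, seed=3)
        params = TrackingParams()
        tg = tracking.track_all(peaks, seeds, params)
        assert len(tg) > 50
        cos_t = np.cos(np.deg2rad(params.angular_threshold))
        for s in tg.streamlines:
            assert params.min_length <= s.length <= params.max_length
            seg = np.diff(s.points, axis=0)
            seg /= np.linalg.norm(seg, axis=1, keepdims=True)
            turns = np.einsum("ij,ij->i", seg[:-1], seg[1:])
            assert turns.min() >= cos_t - 1e-9

    def test_piecewise_constant_field_matches_polyline_oracle(self):
        """Euler integration on a piecewise-constant single-peak field
        reproduces the exact polyline solution: endpoint error < 1 voxel
        over ~300 steps."""
        d1 = np.array([1.0, 0.0, 0.0])
        a = np.deg2rad(30.0)
        d2 = np.array([np.cos(a), np.sin(a), 0.0])

        def field(x):
            return d1 if x[0] < 50 else d2

        peaks = _peak_field_from_directions(field, (100, 100, 7))
        seed = np.array([5.0, 30.0, 3.5])
        sl = tracking.track_streamline(peaks, seed)
        n_steps = len(sl.points) - 1
        assert n_steps >= 150
        # exact polyline: +x to the interface, then along d2 to the far face
        hits = []
        for sense in (d1, -d1):
            p = seed.copy()
            if sense[0] > 0:
                p = p + (50.0 - p[0]) * d1       # reach the interface
                t = (99.5 - p[0]) / d2[0]        # leave through x = 99.5
                t_y = (99.5 - p[1]) / d2[1]
                hits.append(p + min(t, t_y) * d2)
            else:
                hits.append(p - (p[0] - 0.5) * d1)
        ends = {0: sl.points[0], 1: sl.points[-1]}
        errs = []
        for h in hits:
            errs.append(min(np.linalg.norm(ends[0] - h),
                            np.linalg.norm(ends[1] - h)))
        assert max(errs) < 1.0   # voxel size 1 mm

    def test_crossing_continuity(self):
        """Orthogonal-crossing field: tracks seeded in bundle A continue
        through the crossing in A's orientation (>= 80% reach the far end)."""
        def field(x):
            in_a = abs(x[1] - 20.0) < 3.0
            in_b = abs(x[0] - 20.0) < 3.0
            if in_a:
                return (1.0, 0.0, 0.0)
            if in_b:
                return (0.0, 1.0, 0.0)
            return None

        # rebuild with 2 peak slots so crossing voxels hold both directions
        shape = (40, 40, 5)
        peaks = _peak_field_from_directions(field, shape)
        dirs = np.zeros(shape + (2, 3))
        qa = np.zeros(shape + (2,))
        n = np.zeros(shape, np.int32)
        dirs[..., 0, :] = peaks.directions[..., 0, :]
        qa[..., 0] = peaks.qa[..., 0]
        n[...] = peaks.n_peaks
        for idx in np.ndindex(shape):
            x = (np.asarray(idx) + 0.5)
            if abs(x[1] - 20.0) < 3.0 and abs(x[0] - 20.0) < 3.0:
                dirs[idx][0] = [1.0, 0.0, 0.0]
                dirs[idx][1] = [0.0, 1.0, 0.0]
                qa[idx] = [1.0, 1.0]
                n[idx] = 2
        peaks2 = PeakField(directions=dirs, qa=qa, n_peaks=n,
                           voxel_size=peaks.voxel_size, affine=peaks.affine)
        rng = np.random.default_rng(0)
        seeds = np.column_stack([
            rng.uniform(2, 10, 50), rng.uniform(18.5, 21.5, 50),
            rng.uniform(2, 3, 50)])
        tg = tracking.track_all(peaks2, seeds)
        far = sum(s.points[:, 0].max() > 36.0 for s in tg.streamlines)
        assert len(tg) == 50
        assert far >= 0.8 * 50


class TestTrackingParams:
    @pytest.mark.parametrize("kwargs", [
        {"step_size": 0.0},
        {"angular_threshold": 95.0},
        {"min_length": 10.0, "max_length": 5.0},
    ])
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            TrackingParams(**kwargs)
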