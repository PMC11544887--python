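"""Deterministic streamline tractography over a multi-peak fiber field.

Streamlines are propagated bidirectionally from each seed by Euler
integration with a fixed step (default 0.3 mm).  At every step the direction
is obtained by sub-voxel tri-linear interpolation of the peak field: in each
of the 8 surrounding voxels the peak best aligned with the incoming
direction is chosen (peaks misaligned beyond the angular threshold are
excluded — only maxima of similar orientation in neighboring voxels are
linked), sign-flipped to agree with it, scaled by its QA, tri-linearly
weighted, summed and renormalized.  Propagation stops when the turning
angle exceeds the angular threshold (default 45 degrees), when the
interpolated top-peak QA falls below the termination threshold, when the
position leaves the volume, or at the step cap.
Finished streamlines outside the permitted length window (default 0-300 mm)
are discarded.

The propagation itself is fully deterministic; the only randomness in the
module is the seed-point jitter, controlled by an explicit RNG seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recon import PeakField

__all__ = [
    "TrackingParams",
    "Streamline",
    "Tractogram",
    "seed_points",
    "track_streamline",
    "track_all",
    "streamline_length",
]


@dataclass(frozen=True)
class TrackingParams:
    """Streamline propagation parameters (lengths in mm, angles in degrees)."""

    step_size: float = 0.3
    angular_threshold: float = 45.0
    min_length: float = 0.0
    max_length: float = 300.0
    qa_termination: float = 0.08
    max_steps: int | None = None

    def __post_init__(self):
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if not 0.0 < self.angular_threshold < 90.0:
            raise ValueError("angular_threshold must be in (0, 90) degrees")
        if not 0.0 <= self.min_length < self.max_length:
            raise ValueError("need 0 <= min_length < max_length")

    @property
    def effective_max_steps(self) -> int:
        if self.max_steps is not None:
            return int(self.max_steps)
        return int(np.ceil(self.max_length / self.step_size)) + 1


@dataclass
class Streamline:
    """Ordered 3D points in world (mm) coordinates."""

    points: np.ndarray  # (P, 3)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise ValueError("a streamline needs >= 2 three-dimensional points")
        object.__setattr__(self, "points", pts)

    @property
    def length(self) -> float:
        return streamline_length(self)


@dataclass
class Tractogram:
    """A set of streamlines sharing one spatial reference."""

    streamlines: list
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    labels: list | None = None

    def __len__(self) -> int:
        return len(self.streamlines)

    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.streamlines])


def streamline_length(s: Streamline) -> float:
    """Sum of consecutive point distances in mm."""
    pts = s.points
    if len(pts) < 2:
        raise ValueError("length undefined for fewer than 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def seed_points(
    mask: np.ndarray,
    affine: np.ndarray,
    seeds_per_voxel: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Uniformly jittered seed coordinates (mm), ``seeds_per_voxel`` per
    masked voxel; deterministic given ``seed``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("seed mask is empty")
    if seeds_per_voxel < 1:
        raise ValueError("seeds_per_voxel must be positive")
    rng = np.random.default_rng(seed)
    idx = np.argwhere(mask)                       # (M, 3) voxel indices
    idx = np.repeat(idx, seeds_per_voxel, axis=0).astype(np.float64)
    jitter = rng.random(idx.shape) - 0.5          # voxel centers at index
    vox = idx + jitter
    return vox @ affine[:3, :3].T + affine[:3, 3]


class _FieldInterpolator:
    """Tri-linear directional interpolation of a multi-peak field.

    Works on batches of positions.  Voxel centers sit at integer voxel
    coordinates (consistent with a voxel-center affine).
    """

    def __init__(self, peaks: PeakField):
        self.dirs = peaks.directions          # (X, Y, Z, M, 3)
        self.qa = peaks.qa                    # (X, Y, Z, M)
        self.npk = peaks.n_peaks
        self.shape = np.array(peaks.grid_shape)
        aff = np.asarray(peaks.affine if peaks.affine is not None else np.eye(4))
        self.inv_aff = np.linalg.inv(aff)
        corner = np.stack(np.meshgrid([0, 1], [0, 1], [0, 1], indexing="ij"),
                          axis=-1).reshape(8, 3)
        self.corner = corner                  # (8, 3)

    def world_to_voxel(self, pos: np.ndarray) -> np.ndarray:
        return pos @ self.inv_aff[:3, :3].T + self.inv_aff[:3, 3]

    def inside(self, pos: np.ndarray) -> np.ndarray:
        v = self.world_to_voxel(pos)
        return np.all((v >= 0) & (v <= self.shape - 1), axis=-1)

    def interpolate(self, pos: np.ndarray, incoming: np.ndarray,
                    min_cos: float = 0.0):
        """Directional tri-linear interpolation at world positions.

        Parameters
        ----------
        pos : (N, 3) world coordinates.
        incoming : (N, 3) unit vectors; per corner voxel the peak with the
            largest |dot| with ``incoming`` is selected and sign-aligned.
        min_cos : orientational coherence gate — corner peaks whose |dot|
            with the incoming direction falls below this cosine are excluded
            (linking only maxima of similar orientation across neighbors).

        Returns
        -------
        direction : (N, 3) unit vectors (zero where no supporting peak).
        qa : (N,) tri-linearly interpolated top-peak QA — a tissue
            anisotropy measure independent of the direction gate, so a
            track is not killed by one poorly resolved crossing voxel.
        """
        v = self.world_to_voxel(pos)
        base = np.floor(v).astype(np.int64)
        base = np.clip(base, 0, self.shape - 2)
        frac = np.clip(v - base, 0.0, 1.0)

        acc_dir = np.zeros_like(pos)
        acc_qa = np.zeros(len(pos))
        for c in self.corner:
            ijk = base + c                                   # (N, 3)
            w = np.prod(np.where(c == 1, frac, 1.0 - frac), axis=1)
            d = self.dirs[ijk[:, 0], ijk[:, 1], ijk[:, 2]]   # (N, M, 3)
            q = self.qa[ijk[:, 0], ijk[:, 1], ijk[:, 2]]     # (N, M)
            dots = np.einsum("nmk,nk->nm", d, incoming)
            has = (q > 0) & (np.abs(dots) >= min_cos)
            score = np.where(has, np.abs(dots), -np.inf)
            best = score.argmax(axis=1)
            rows = np.arange(len(pos))
            bd = d[rows, best]
            bq = np.where(has[rows, best], q[rows, best], 0.0)
            sign = np.where(dots[rows, best] < 0, -1.0, 1.0)
            ok = has[rows, best]
            # amplitude-scaled interpolation: each corner's peak enters with
            # its QA so spurious low-amplitude peaks cannot steer the track
            acc_dir += np.where(ok[:, None], (w * sign * bq)[:, None] * bd, 0.0)
            acc_qa += w * q[:, 0]
        norm = np.linalg.norm(acc_dir, axis=1)
        direction = np.where(norm[:, None] > 1e-12, acc_dir / np.maximum(norm, 1e-12)[:, None], 0.0)
        return direction, acc_qa

    def strongest(self, pos: np.ndarray):
        """Initial direction at seeds: interpolation aligned with the
        strongest-QA peak among the corner voxels."""
        v = self.world_to_voxel(pos)
        base = np.clip(np.floor(v).astype(np.int64), 0, self.shape - 2)
        ref = np.zeros_like(pos)
        best_q = np.zeros(len(pos))
        for c in self.corner:
            ijk = base + c
            d = self.dirs[ijk[:, 0], ijk[:, 1], ijk[:, 2], 0]   # top peak
            q = self.qa[ijk[:, 0], ijk[:, 1], ijk[:, 2], 0]
            better = q > best_q
            ref[better] = d[better]
            best_q = np.where(better, q, best_q)
        return self.interpolate(pos, np.where(best_q[:, None] > 0, ref, 0.0))


def _propagate(interp, start, first_dir, params):
    """Batched Euler propagation in one sense.  Returns (points, n_steps):
    ``points`` is (N, max_steps + 1, 3) with positions, ``n_steps`` the number
    of accepted steps per streamline."""
    n = len(start)
    max_steps = params.effective_max_steps
    cos_thresh = np.cos(np.deg2rad(params.angular_threshold))
    pts = np.zeros((n, max_steps + 1, 3))
    pts[:, 0] = start
    n_steps = np.zeros(n, dtype=np.int64)
    pos = start.copy()
    prev = first_dir.copy()
    active = np.linalg.norm(first_dir, axis=1) > 0
    for step in range(max_steps):
        if not active.any():
            break
        cand = pos[active] + params.step_size * prev[active]
        ok_inside = interp.inside(cand)
        d, qa = interp.interpolate(cand, prev[active], min_cos=cos_thresh)
        has_dir = np.linalg.norm(d, axis=1) > 0
        turn_ok = np.einsum("nk,nk->n", d, prev[active]) >= cos_thresh
        ok = ok_inside & has_dir & (qa >= params.qa_termination) & turn_ok
        idx = np.flatnonzero(active)
        good = idx[ok]
        pos[good] = cand[ok]
        prev[good] = d[ok]
        n_steps[good] += 1
        pts[good, n_steps[good]] = cand[ok]
        active[idx[~ok]] = False
    return pts, n_steps


def track_all(
    peaks: PeakField,
    seeds: np.ndarray,
    params: TrackingParams | None = None,
) -> Tractogram:
    """Track every seed bidirectionally; drop failures and out-of-range
    lengths.  Deterministic given inputs."""
    params = params or TrackingParams()
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    affine = peaks.affine if peaks.affine is not None else np.eye(4)
    if seeds.size == 0:
        return Tractogram(streamlines=[], affine=np.asarray(affine))
    interp = _FieldInterpolator(peaks)

    inside = interp.inside(seeds)
    first_dir, qa0 = interp.strongest(seeds)
    has0 = (np.linalg.norm(first_dir, axis=1) > 0) & (qa0 >= params.qa_termination)
    usable = inside & has0

    streamlines = []
    if usable.any():
        s = seeds[usable]
        d0 = first_dir[usable]
        fwd_pts, fwd_n = _propagate(interp, s, d0, params)
        bwd_pts, bwd_n = _propagate(interp, s, -d0, params)
        for i in range(len(s)):
            back = bwd_pts[i, 1 : bwd_n[i] + 1][::-1]
            fore = fwd_pts[i, : fwd_n[i] + 1]
            pts = np.vstack([back, fore])
            if len(pts) < 2:
                continue
            sl = Streamline(points=pts)
            if params.min_length <= sl.length <= params.max_length:
                streamlines.append(sl)
    return Tractogram(streamlines=streamlines, affine=np.asarray(affine))


def track_streamline(
    peaks: PeakField,
    seed_point: np.ndarray,
    params: TrackingParams | None = None,
) -> Streamline | None:
    """Track a single seed; returns None when no streamline is produced."""
    tg = track_all(peaks, np.atleast_2d(seed_point), params)
    return tg.streamlines[0] if len(tg) else None
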