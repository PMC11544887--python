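"""Tumor-ROI tract selection, classification and prognostic metrics.

Tumor-intersecting streamlines (those with at least one point inside the
segmented tumor ROI) are partitioned into three classes:

* ``core`` — every point inside the ROI;
* ``shell`` — exits the ROI but never moves further than ``shell_margin``
  (default 3 mm, about an in-plane voxel diagonal) from its surface,
  i.e. tracts adhering closely to the tumor surface;
* ``projecting`` — extends beyond the shell margin into surrounding tissue.

From the classified tractogram the module computes the prognostic metrics
studied for the tumor cohort: mean tract length over all tumor-intersecting
tracts, mean projecting tract length (projecting tracts only, full
streamline length), the number of projecting tract bundles (greedy
QuickBundles-style clustering under the minimum-average-direct-flip
distance), tumor volume, and intra-tumoral means of QA / FA / MD / AD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .recon import PeakField, ScalarMaps
from .tracking import Streamline, Tractogram

__all__ = [
    "RoiMask",
    "TractMetrics",
    "select_tumor_tracts",
    "classify_tract",
    "classify_tracts",
    "tract_metrics",
    "count_bundles",
    "resample_streamline",
    "mdf_distance",
]


@dataclass
class RoiMask:
    """Binary tumor ROI on the DWI lattice with a signed surface distance.

    The distance field is computed by exact Euclidean distance transforms on
    the voxel lattice (world-scaled per axis): positive outside the ROI,
    negative inside, zero on the boundary shell.
    """

    mask: np.ndarray
    affine: np.ndarray
    voxel_size: tuple
    _outside_dist: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if not m.any():
            raise ValueError("ROI mask is empty")
        object.__setattr__(self, "mask", m)
        # distance (mm) from any voxel center to the nearest ROI voxel center
        self._outside_dist = ndimage.distance_transform_edt(
            ~m, sampling=self.voxel_size
        )

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size)) / 1000.0

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(np.asarray(self.affine))
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Point-in-mask test after world -> voxel transform (nearest voxel)."""
        v = np.rint(self.world_to_voxel(np.atleast_2d(pts))).astype(np.int64)
        shape = np.asarray(self.mask.shape)
        ok = np.all((v >= 0) & (v < shape), axis=1)
        out = np.zeros(len(v), dtype=bool)
        out[ok] = self.mask[v[ok, 0], v[ok, 1], v[ok, 2]]
        return out

    def surface_distance(self, pts: np.ndarray) -> np.ndarray:
        """Distance (mm) to the ROI for exterior points, tri-linearly
        interpolated; 0 for points inside."""
        v = self.world_to_voxel(np.atleast_2d(pts))
        return ndimage.map_coordinates(
            self._outside_dist, v.T, order=1, mode="nearest"
        )


@dataclass
class TractMetrics:
    mean_tract_length: float
    mean_projecting_tract_length: float | None   # None when no projecting tracts
    n_projecting_bundles: int
    n_tracts_by_class: dict
    tumor_volume_cm3: float
    intratumoral: dict = field(default_factory=dict)  # means of qa/fa/md/ad


def select_tumor_tracts(tracts: Tractogram, roi: RoiMask) -> Tractogram:
    """Keep streamlines with at least one point inside the ROI."""
    if not np.allclose(tracts.affine, roi.affine, atol=1e-6):
        raise ValueError("tractogram and ROI affines do not match")
    kept = [s for s in tracts.streamlines if roi.contains(s.points).any()]
    return Tractogram(streamlines=kept, affine=tracts.affine)


def classify_tract(s: Streamline, roi: RoiMask, shell_margin: float = 3.0) -> str:
    """Classify one tumor-intersecting streamline as core / shell / projecting."""
    inside = roi.contains(s.points)
    if not inside.any():
        raise ValueError("streamline does not intersect the ROI; pre-filter first")
    if inside.all():
        return "core"
    e = float(roi.surface_distance(s.points[~inside]).max())
    return "shell" if e <= shell_margin else "projecting"


def classify_tracts(
    tracts: Tractogram, roi: RoiMask, shell_margin: float = 3.0
) -> list:
    """Class label per streamline (every tract gets exactly one class)."""
    return [classify_tract(s, roi, shell_margin) for s in tracts.streamlines]


def resample_streamline(s: Streamline, n_points: int = 12) -> np.ndarray:
    """Resample to ``n_points`` equidistant points along arc length."""
    pts = s.points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] <= 0:
        return np.repeat(pts[:1], n_points, axis=0)
    targets = np.linspace(0.0, t[-1], n_points)
    out = np.empty((n_points, 3))
    for k in range(3):
        out[:, k] = np.interp(targets, t, pts[:, k])
    return out


def mdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum-average-direct-flip distance between equally resampled
    streamlines: min of the mean pointwise distance in direct and flipped
    order.  Symmetric, zero for identical curves."""
    direct = float(np.linalg.norm(a - b, axis=1).mean())
    flipped = float(np.linalg.norm(a - b[::-1], axis=1).mean())
    return min(direct, flipped)


def count_bundles(
    tracts: Tractogram,
    distance_threshold: float = 8.0,
    min_members: int = 2,
    n_points: int = 12,
) -> int:
    """Count distinct bundles by greedy centroid clustering under MDF.

    Streamlines are resampled to ``n_points`` and assigned, in input order,
    to the nearest cluster centroid within ``distance_threshold`` mm
    (flip-aligning before updating the running centroid) or start a new
    cluster.  Clusters smaller than ``min_members`` are discarded.
    """
    if len(tracts) == 0:
        return 0
    resampled = [resample_streamline(s, n_points) for s in tracts.streamlines]
    centroids: list[np.ndarray] = []
    sizes: list[int] = []
    for r in resampled:
        best, best_d, flip = -1, np.inf, False
        for ci, c in enumerate(centroids):
            direct = np.linalg.norm(r - c, axis=1).mean()
            flipped = np.linalg.norm(r[::-1] - c, axis=1).mean()
            d = min(direct, flipped)
            if d < best_d:
                best, best_d, flip = ci, d, flipped < direct
        if best >= 0 and best_d <= distance_threshold:
            r_al = r[::-1] if flip else r
            centroids[best] = (centroids[best] * sizes[best] + r_al) / (sizes[best] + 1)
            sizes[best] += 1
        else:
            centroids.append(r.copy())
            sizes.append(1)
    return int(sum(1 for sz in sizes if sz >= min_members))


def tract_metrics(
    tracts: Tractogram,
    classes: list,
    roi: RoiMask,
    scalar_maps: ScalarMaps | None = None,
    peaks: PeakField | None = None,
    bundle_distance_threshold: float = 8.0,
    bundle_min_members: int = 2,
) -> TractMetrics:
    """Tract-derived prognostic metrics for one subject.

    ``mean_tract_length`` averages over all tumor-intersecting tracts;
    ``mean_projecting_tract_length`` over projecting tracts only (full
    streamline lengths) and is None — flagged undefined, not 0 — when there
    are no projecting tracts.  Intra-tumoral scalar means are taken over ROI
    voxels of the supplied maps.
    """
    if len(tracts) == 0:
        raise ValueError("need at least one tumor-intersecting tract")
    if len(classes) != len(tracts):
        raise ValueError("one class label per streamline required")
    lengths = tracts.lengths()
    cls = np.asarray(classes)
    counts = {c: int((cls == c).sum()) for c in ("core", "shell", "projecting")}
    proj_mask = cls == "projecting"
    proj_mean = float(lengths[proj_mask].mean()) if proj_mask.any() else None
    proj_tg = Tractogram(
        streamlines=[s for s, p in zip(tracts.streamlines, proj_mask) if p],
        affine=tracts.affine,
    )
    n_bundles = count_bundles(
        proj_tg, distance_threshold=bundle_distance_threshold,
        min_members=bundle_min_members,
    )

    intratumoral = {}
    m = roi.mask
    if scalar_maps is not None:
        for name, arr in (("fa", scalar_maps.fa), ("md", scalar_maps.md),
                          ("ad", scalar_maps.ad)):
            vals = arr[m]
            vals = vals[np.isfinite(vals)]
            intratumoral[name] = float(vals.mean()) if vals.size else np.nan
    if peaks is not None:
        qa_top = peaks.qa[..., 0][m]
        intratumoral["qa"] = float(qa_top.mean()) if qa_top.size else np.nan

    return TractMetrics(
        mean_tract_length=float(lengths.mean()),
        mean_projecting_tract_length=proj_mean,
        n_projecting_bundles=n_bundles,
        n_tracts_by_class=counts,
        tumor_volume_cm3=roi.volume_cm3,
        intratumoral=intratumoral,
    )
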