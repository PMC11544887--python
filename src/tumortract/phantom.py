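"""Synthetic data generators: DWI phantoms, survival cohorts, RNA-seq counts.

Every downstream stage of the pipeline (reconstruction, tracking, tumor-tract
metrics, survival statistics, differential expression) is exercised on data
from this module, so the generators are first-class, tested code with known
ground truth attached.

The DWI phantom uses the standard multi-tensor forward model: per voxel the
diffusion-weighted signal is

    S(g, b) = S0 * [ sum_k f_k * exp(-b g^T D_k g) + f_free * exp(-b d_iso) ]

where the D_k are cylindrically framed diffusion tensors aligned with the
local fiber tangent of each bundle covering the voxel, and the free
compartment carries either the tumor's isotropic diffusivity or the
background diffusivity.  Noise is Rician: independent Gaussian channels of
standard deviation S0/SNR added to the real and imaginary parts before
taking the magnitude, the standard model for MR magnitude images.

Two acquisition presets mirror the geometries of the study system: a human
3T protocol (64 directions, b = 1000 s/mm^2, 1.8 x 1.8 x 4.0 mm voxels) and
an ex-vivo mouse 7T protocol (512 directions, b = 1200 s/mm^2, 0.16 mm
isotropic voxels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GradientTable",
    "Bundle",
    "Tumor",
    "PhantomSpec",
    "TissueTruth",
    "DwiVolume",
    "make_gradient_table",
    "simulate_dwi",
    "simulate_cohort",
    "simulate_counts",
    "CountsMatrix",
    "bundle_crossing_spec",
    "PRESETS",
]


# ---------------------------------------------------------------------------
# gradient tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: unit directions, b-values, b0 flags."""

    directions: np.ndarray  # (N, 3), unit norm (b0 rows are zero vectors)
    bvalues: np.ndarray     # (N,), s/mm^2
    b0_flags: np.ndarray    # (N,), bool

    def __post_init__(self):
        directions = np.asarray(self.directions, dtype=np.float64)
        bvalues = np.asarray(self.bvalues, dtype=np.float64)
        b0 = np.asarray(self.b0_flags, dtype=bool)
        if not (len(directions) == len(bvalues) == len(b0)):
            raise ValueError("directions, bvalues and b0_flags must have equal length")
        if np.any(bvalues < 0):
            raise ValueError("b-values must be non-negative")
        if not b0.any():
            raise ValueError("gradient table needs at least one b0 entry")
        norms = np.linalg.norm(directions[~b0], axis=1)
        if norms.size and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("diffusion-weighted directions must be unit vectors")
        object.__setattr__(self, "directions", directions)
        object.__setattr__(self, "bvalues", bvalues)
        object.__setattr__(self, "b0_flags", b0)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def n_dwi(self) -> int:
        return int((~self.b0_flags).sum())


def _repulsion_directions(n: int, seed: int, n_iter: int = 1000) -> np.ndarray:
    """Spread ``n`` unit vectors by electrostatic repulsion with antipodal
    symmetry: each point repels every other point and its antipode, so the
    minimum pairwise (acute) angle is approximately maximized."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    if n == 1:
        return pts
    step = 0.1
    for it in range(n_iter):
        # pairwise forces from points and their antipodes
        diff = pts[:, None, :] - pts[None, :, :]
        diff_anti = pts[:, None, :] + pts[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
        d2a = np.einsum("ijk,ijk->ij", diff_anti, diff_anti)
        np.fill_diagonal(d2, np.inf)
        d2 = np.maximum(d2, 1e-12)
        d2a = np.maximum(d2a, 1e-12)
        force = (diff / d2[..., None] ** 1.5).sum(axis=1)
        force += (diff_anti / d2a[..., None] ** 1.5).sum(axis=1)
        # tangential component only, shrinking step
        force -= pts * np.einsum("ij,ij->i", force, pts)[:, None]
        pts = pts + step * (1.0 - it / n_iter) * force / n
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def make_gradient_table(
    n_directions: int, bvalue: float, n_b0: int = 1, seed: int = 0
) -> GradientTable:
    """Build a single-shell gradient table with repulsion-optimized directions.

    Parameters
    ----------
    n_directions : number of diffusion-weighted directions (>= 6, otherwise a
        tensor fit would be underdetermined).
    bvalue : diffusion weighting in s/mm^2 applied to every direction.
    n_b0 : number of unweighted (b = 0) entries, prepended.
    seed : seed for the repulsion initialization; the same seed reproduces
        the table bit-identically.
    """
    if n_directions < 6:
        raise ValueError("need at least 6 diffusion directions for a tensor fit")
    if n_b0 < 0:
        raise ValueError("n_b0 must be non-negative")
    dirs = _repulsion_directions(n_directions, seed=seed)
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvalues = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(bvalue))])
    b0_flags = np.concatenate([np.ones(n_b0, bool), np.zeros(n_directions, bool)])
    if n_b0 == 0:
        # a b0 entry is required downstream; treat the table as invalid
        raise ValueError("gradient table needs at least one b0 entry (n_b0 >= 1)")
    return GradientTable(directions, bvalues, b0_flags)


#: Acquisition presets by direction count / b-value / voxel geometry.
PRESETS = {
    "human64": dict(n_directions=64, bvalue=1000.0, voxel_size=(1.8, 1.8, 4.0)),
    "human27": dict(n_directions=27, bvalue=1200.0, voxel_size=(0.86, 0.86, 3.5)),
    "mouse512": dict(n_directions=512, bvalue=1200.0, voxel_size=(0.16, 0.16, 0.16)),
}


# ---------------------------------------------------------------------------
# phantom geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bundle:
    """A tubular fiber bundle around a polyline centerline (mm coordinates)."""

    centerline: np.ndarray        # (P, 3) mm; straight bundles need 2 points
    radius: float                 # mm
    eigenvalues: tuple = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s, descending
    volume_fraction: float = 0.8

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.centerline, dtype=np.float64))
        if len(pts) < 2:
            raise ValueError("centerline needs at least 2 points")
        ev = tuple(float(e) for e in self.eigenvalues)
        if any(e <= 0 for e in ev) or list(ev) != sorted(ev, reverse=True):
            raise ValueError("eigenvalues must be positive and sorted descending")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise ValueError("volume_fraction must be in (0, 1]")
        object.__setattr__(self, "centerline", pts)


@dataclass(frozen=True)
class Tumor:
    """Ellipsoidal isotropic 'tumor' region (mm coordinates)."""

    center: tuple
    semi_axes: tuple
    isotropic_diffusivity: float = 2.0e-3  # mm^2/s


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, bundles, tumor, background."""

    grid_shape: tuple
    voxel_size: tuple
    bundles: tuple = ()
    tumor: Tumor | None = None
    background_diffusivity: float = 0.8e-3  # mm^2/s
    s0: float = 1000.0

    def __post_init__(self):
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size entries must be positive")
        object.__setattr__(self, "bundles", tuple(self.bundles))
        if self.tumor is not None:
            fov = np.asarray(self.grid_shape) * np.asarray(self.voxel_size)
            c = np.asarray(self.tumor.center)
            a = np.asarray(self.tumor.semi_axes)
            if np.any(c - a < 0) or np.any(c + a > fov):
                raise ValueError("tumor ellipsoid must lie inside the grid")

    @property
    def affine(self) -> np.ndarray:
        """Voxel index -> mm; voxel centers at (i + 0.5) * voxel_size."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = 0.5 * np.asarray(self.voxel_size)
        return aff

    def voxel_centers(self) -> np.ndarray:
        """(X, Y, Z, 3) array of voxel-center world coordinates in mm."""
        axes = [
            (np.arange(n) + 0.5) * v
            for n, v in zip(self.grid_shape, self.voxel_size)
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack(grid, axis=-1)


@dataclass
class TissueTruth:
    """Ground truth attached to a simulated DWI volume."""

    fiber_directions: np.ndarray   # (X, Y, Z, K, 3) unit vectors, zero-padded
    fiber_fractions: np.ndarray    # (X, Y, Z, K)
    n_fibers: np.ndarray           # (X, Y, Z) int
    bundle_masks: np.ndarray       # (n_bundles, X, Y, Z) bool
    tumor_mask: np.ndarray         # (X, Y, Z) bool


@dataclass
class DwiVolume:
    """4D diffusion-weighted signal with voxel geometry and gradient table."""

    signal: np.ndarray       # (X, Y, Z, N) >= 0
    voxel_size: tuple
    affine: np.ndarray       # 4x4 voxel -> mm
    gradient_table: GradientTable

    def __post_init__(self):
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, gradient)")
        if self.signal.shape[3] != len(self.gradient_table):
            raise ValueError("4th dimension must match gradient table length")
        if not np.all(np.isfinite(self.signal)) or np.any(self.signal < 0):
            raise ValueError("signal must be finite and non-negative")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine must be invertible")

    @property
    def grid_shape(self) -> tuple:
        return self.signal.shape[:3]


def _point_to_polyline(points: np.ndarray, poly: np.ndarray):
    """Distance from each point to a polyline and the local unit tangent.

    Returns (dist, tangent) with shapes (N,) and (N, 3).
    """
    a = poly[:-1]                       # (S, 3)
    ab = poly[1:] - a                   # (S, 3)
    ab2 = np.maximum((ab * ab).sum(1), 1e-30)
    # (N, S) projection parameter, clamped to the segment
    t = np.einsum("ns,s->ns", np.einsum("nk,sk->ns", points, ab)
                  - np.einsum("sk,sk->s", a, ab)[None, :], 1.0 / ab2)
    t = np.clip(t, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    idx = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(len(points)), idx])
    tangent = ab[idx] / np.sqrt(ab2[idx])[:, None]
    return dist, tangent


def rasterize(spec: PhantomSpec, max_fibers: int = 3) -> TissueTruth:
    """Assign fiber compartments and tumor membership to every voxel.

    A voxel belongs to a bundle when its center lies within the bundle radius
    of the centerline.  If the nominal volume fractions of the covering
    bundles exceed 1, they are rescaled to sum to 1 (crossing regions).
    """
    shape = tuple(int(s) for s in spec.grid_shape)
    centers = spec.voxel_centers().reshape(-1, 3)
    n_vox = len(centers)
    k = max(max_fibers, 1)
    dirs = np.zeros((n_vox, k, 3))
    fracs = np.zeros((n_vox, k))
    nfib = np.zeros(n_vox, dtype=np.int32)
    bmasks = np.zeros((len(spec.bundles), n_vox), dtype=bool)

    for bi, bundle in enumerate(spec.bundles):
        dist, tangent = _point_to_polyline(centers, bundle.centerline)
        inside = dist <= bundle.radius
        bmasks[bi] = inside
        slot = nfib[inside]
        if np.any(slot >= k):
            raise ValueError(f"more than {k} bundles overlap a voxel; raise max_fibers")
        rows = np.flatnonzero(inside)
        dirs[rows, slot] = tangent[inside]
        fracs[rows, slot] = bundle.volume_fraction
        nfib[inside] += 1

    total = fracs.sum(axis=1)
    over = total > 1.0
    if np.any(over):
        fracs[over] /= total[over, None]

    tumor_mask = np.zeros(n_vox, dtype=bool)
    if spec.tumor is not None:
        c = np.asarray(spec.tumor.center)
        a = np.asarray(spec.tumor.semi_axes)
        tumor_mask = (((centers - c) / a) ** 2).sum(1) <= 1.0

    return TissueTruth(
        fiber_directions=dirs.reshape(shape + (k, 3)),
        fiber_fractions=fracs.reshape(shape + (k,)),
        n_fibers=nfib.reshape(shape),
        bundle_masks=bmasks.reshape((len(spec.bundles),) + shape),
        tumor_mask=tumor_mask.reshape(shape),
    )


def simulate_dwi(
    spec: PhantomSpec,
    gtab: GradientTable,
    snr: float = np.inf,
    seed: int = 0,
) -> tuple[DwiVolume, TissueTruth]:
    """Simulate a DWI volume from the multi-tensor forward model.

    ``snr`` is defined as S0 / sigma with sigma the per-channel Gaussian
    noise standard deviation; the magnitude signal is Rician distributed.
    ``snr=inf`` gives the exact noise-free closed form.
    """
    if not snr > 0:
        raise ValueError("snr must be positive (use np.inf for noise-free)")
    truth = rasterize(spec, max_fibers=max(3, len(spec.bundles)))
    shape = truth.n_fibers.shape
    n_vox = int(np.prod(shape))
    n_grad = len(gtab)

    g = gtab.directions           # (N, 3)
    b = gtab.bvalues              # (N,)

    dirs = truth.fiber_directions.reshape(n_vox, -1, 3)
    fracs = truth.fiber_fractions.reshape(n_vox, -1)
    tumor = truth.tumor_mask.reshape(n_vox)

    d_iso = np.where(tumor,
                     spec.tumor.isotropic_diffusivity if spec.tumor else 0.0,
                     spec.background_diffusivity)
    f_free = 1.0 - fracs.sum(axis=1)
    attn = f_free[:, None] * np.exp(-b[None, :] * d_iso[:, None])

    for ki in range(dirs.shape[1]):
        active = fracs[:, ki] > 0
        if not active.any():
            continue
        v = dirs[active, ki]                    # (M, 3)
        # slot ki of a voxel was filled by the (ki+1)-th bundle covering it
        # (bundles fill slots in declaration order); recover per-voxel
        # eigenvalues from the bundle masks.
        ev = np.zeros((int(active.sum()), 3))
        rows = np.flatnonzero(active)
        for bi, bundle in enumerate(spec.bundles):
            bm = truth.bundle_masks[bi].reshape(n_vox)[rows]
            order = np.zeros(len(rows), dtype=np.int32)
            for bj in range(bi):
                order += truth.bundle_masks[bj].reshape(n_vox)[rows].astype(np.int32)
            take = bm & (order == ki)
            ev[take] = bundle.eigenvalues
        # cylindrical frame around the fiber direction
        e1 = np.cross(v, np.where(np.abs(v[:, :1]) < 0.9,
                                  [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]))
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(v, e1)
        gv = v @ g.T
        g1 = e1 @ g.T
        g2 = e2 @ g.T
        gdg = ev[:, :1] * gv**2 + ev[:, 1:2] * g1**2 + ev[:, 2:3] * g2**2
        attn[active] += fracs[active, ki][:, None] * np.exp(-b[None, :] * gdg)

    signal = spec.s0 * attn
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        sigma = spec.s0 / snr
        noise_r = rng.standard_normal((n_vox, n_grad))
        noise_i = rng.standard_normal((n_vox, n_grad))
        signal = np.sqrt((signal + sigma * noise_r) ** 2 + (sigma * noise_i) ** 2)

    vol = DwiVolume(
        signal=signal.reshape(shape + (n_grad,)),
        voxel_size=tuple(spec.voxel_size),
        affine=spec.affine,
        gradient_table=gtab,
    )
    return vol, truth


def bundle_crossing_spec(
    n_bundles: int,
    grid_shape: tuple = (40, 40, 12),
    voxel_size: tuple = (1.8, 1.8, 4.0),
    tumor_radius: float = 9.0,
    bundle_radius: float = 3.0,
    seed: int = 0,
) -> PhantomSpec:
    """Phantom with ``n_bundles`` straight tubes piercing a spherical 'tumor'.

    Each bundle runs through (a chord of) the tumor and extends to the volume
    boundary on both sides, so every bundle both intersects the ROI and
    projects well beyond it — the geometry used in the end-to-end recovery
    studies.  Bundle orientations are spread in the axial plane (with small
    out-of-plane tilts) and their chords are offset from the center so that
    at most two bundles cross in any single voxel.
    """
    if not 1 <= n_bundles <= 5:
        raise ValueError("n_bundles must be between 1 and 5")
    fov = np.asarray(grid_shape) * np.asarray(voxel_size)
    center = fov / 2.0
    half_len = float(np.linalg.norm(fov))  # long enough to leave the volume
    # Layout: in-plane tubes on up to three z-levels.  Tubes sharing a level
    # cross at 90 degrees (resolvable by the orientation reconstruction at
    # the human b-value); tubes on different levels are separated by more
    # than a tube diameter in z, so they pierce the tumor without touching
    # each other.  Each entry: (in-plane angle deg, z offset, in-plane
    # offset), offsets as fractions of the tumor radius.
    layout = [
        (0.0, 0.0, 0.22),
        (90.0, 0.0, -0.22),
        (45.0, -0.72, 0.22),
        (135.0, -0.72, -0.22),
        (30.0, 0.72, 0.0),
    ][:n_bundles]
    bundles = []
    for ang_deg, z_off, inplane_off in layout:
        ang = np.deg2rad(ang_deg)
        d = np.array([np.cos(ang), np.sin(ang), 0.0])
        normal = np.array([-np.sin(ang), np.cos(ang), 0.0])
        through = (center + inplane_off * tumor_radius * normal
                   + np.array([0.0, 0.0, z_off * tumor_radius]))
        p0 = through - half_len * d
        p1 = through + half_len * d
        bundles.append(Bundle(centerline=np.array([p0, p1]), radius=bundle_radius))
    tumor = Tumor(center=tuple(center), semi_axes=(tumor_radius,) * 3,
                  isotropic_diffusivity=2.0e-3)
    return PhantomSpec(
        grid_shape=tuple(grid_shape),
        voxel_size=tuple(voxel_size),
        bundles=tuple(bundles),
        tumor=tumor,
    )


def interior_seed_points(
    spec: PhantomSpec,
    truth: TissueTruth,
    seeds_per_voxel: int = 2,
    margin: float = 1.5,
    seed: int = 0,
) -> np.ndarray:
    """Jittered tracking seeds kept only where the point itself lies at
    least ``margin`` mm inside a bundle.

    Partial-volume voxels at a tube surface carry weak, noisy orientation
    estimates; restricting seeds to the tube interior is the phantom analog
    of seeding inside a tissue mask rather than on its boundary.
    """
    from .tracking import seed_points  # local import to avoid a cycle

    mask = truth.bundle_masks.any(axis=0)
    pts = seed_points(mask, spec.affine, seeds_per_voxel=seeds_per_voxel,
                      seed=seed)
    inside = np.zeros(len(pts), dtype=bool)
    for b in spec.bundles:
        dist, _ = _point_to_polyline(pts, b.centerline)
        inside |= dist <= max(b.radius - margin, 0.25)
    return pts[inside]


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

def simulate_cohort(
    n: int = 66,
    effect: dict | None = None,
    baseline_hazard: float = 1.0 / 714.0,
    censor_rate: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a survival cohort whose hazard depends on a tract metric.

    Survival times are exponential with log-hazard linear in the
    z-standardized named metric:

        T_i ~ Exp(rate = baseline_hazard * exp(beta * z_i))

    so ``hazard_coefficient`` is a log hazard ratio per metric standard
    deviation.  Censoring is independent: with probability ``censor_rate`` a
    subject is censored at a uniform fraction of its event time.  The default
    cohort size (66), baseline survival scale (~714 days) and metric scales
    follow the study system's historical cohort.

    Returns a DataFrame with columns ``subject_id, os_days, event, age`` and
    one column per metric.
    """
    if n < 8:
        raise ValueError("cohort size must be at least 8")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    effect = dict(effect or {"metric_name": "mean_projecting_tract_length",
                             "hazard_coefficient": 0.0})
    metric_name = effect["metric_name"]
    beta = float(effect["hazard_coefficient"])

    # log-normal metric scales loosely matching observed tract metrics
    metric_params = {
        "mean_tract_length": (29.1, 11.7),
        "mean_projecting_tract_length": (64.2, 19.6),
        "n_projecting_bundles": (5.0, 2.1),
        "tumor_volume": (43.1, 37.9),
    }
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"subject_id": [f"S{i:03d}" for i in range(n)]})
    df["age"] = np.clip(rng.normal(59.4, 12.1, size=n), 18.0, None)
    for name, (mean, sd) in metric_params.items():
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        df[name] = np.exp(rng.normal(mu, np.sqrt(sigma2), size=n))
    if metric_name not in df.columns:
        df[metric_name] = rng.lognormal(mean=0.0, sigma=0.5, size=n)

    x = df[metric_name].to_numpy()
    z = (x - x.mean()) / x.std(ddof=0)
    rate = baseline_hazard * np.exp(beta * z)
    t_event = rng.exponential(1.0 / rate)
    censored = rng.random(n) < censor_rate
    frac = rng.random(n)
    os_days = np.where(censored, np.maximum(t_event * frac, 1e-6), t_event)
    df["os_days"] = os_days
    df["event"] = ~censored
    return df


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

@dataclass
class CountsMatrix:
    """Gene-by-sample integer counts with group labels and optional truth."""

    counts: pd.DataFrame          # genes x samples, non-negative ints
    sample_groups: pd.Series      # per sample, e.g. tract / tumor / normal
    true_fold_change: pd.Series | None = None  # per gene (synthetic only)

    def __post_init__(self):
        c = self.counts
        if not c.index.is_unique:
            raise ValueError("gene ids must be unique")
        vals = c.to_numpy()
        if np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        groups = self.sample_groups.reindex(c.columns)
        if groups.isna().any():
            raise ValueError("every sample needs a group label")
        if groups.nunique() < 2:
            raise ValueError("at least 2 sample groups required")
        object.__setattr__(self, "sample_groups", groups)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def simulate_counts(
    n_genes: int = 2000,
    samples_per_group: dict | None = None,
    de_fraction: float = 0.1,
    fold_change: float = 2.0,
    dispersion: float = 0.1,
    seed: int = 0,
    de_gene_pool: list | None = None,
) -> CountsMatrix:
    """Simulate negative-binomial RNA-seq counts with a tract-group signal.

    ``de_fraction`` of genes are up-regulated by ``fold_change`` in the
    ``tract`` group relative to all other groups; the per-gene true fold
    change is recorded.  Library sizes are log-normal around 5 million reads.
    The default group sizes (tract 6, tumor 5, normal 2; 13 samples total)
    mirror the biopsy design this stage emulates.

    ``de_gene_pool`` optionally restricts which genes may be differentially
    expressed (used to construct enrichment truth sets).
    """
    samples_per_group = dict(samples_per_group or {"tract": 6, "tumor": 5, "normal": 2})
    if len(samples_per_group) < 2 or any(v < 1 for v in samples_per_group.values()):
        raise ValueError("need >= 1 sample in >= 2 groups")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must be in [0, 1]")
    n_de = int(round(de_fraction * n_genes))
    if de_fraction > 0 and n_de < 1:
        raise ValueError("de_fraction * n_genes must be >= 1 when de_fraction > 0")
    if fold_change < 1.0:
        raise ValueError("fold_change must be >= 1")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    samples, groups = [], []
    for gname, cnt in samples_per_group.items():
        for j in range(cnt):
            samples.append(f"{gname}_{j+1}")
            groups.append(gname)
    groups = pd.Series(groups, index=samples, name="group")

    base_mean = rng.lognormal(mean=4.0, sigma=1.5, size=n_genes)  # counts per 5M
    lib = rng.lognormal(mean=np.log(5e6), sigma=0.2, size=len(samples))

    fc = np.ones(n_genes)
    if n_de > 0:
        pool = (np.asarray([gene_ids.index(g) for g in de_gene_pool])
                if de_gene_pool is not None else np.arange(n_genes))
        de_idx = rng.choice(pool, size=n_de, replace=False)
        fc[de_idx] = fold_change

    is_tract = (groups.to_numpy() == "tract")
    mu = base_mean[:, None] * (lib[None, :] / 5e6)
    mu = mu * np.where(is_tract[None, :], fc[:, None], 1.0)

    if dispersion > 0:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=samples)
    return CountsMatrix(
        counts=counts_df,
        sample_groups=groups,
        true_fold_change=pd.Series(fc, index=gene_ids, name="true_fold_change"),
    )
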