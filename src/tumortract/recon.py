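"""Per-voxel diffusion reconstruction.

Two reconstructions are provided:

* a log-linear diffusion tensor fit with the usual scalar maps — fractional
  anisotropy (FA), mean diffusivity (MD) and axial diffusivity (AD);
* a generalized q-space orientation reconstruction: a spin-distribution
  function (SDF) evaluated on a tessellated sphere,

      psi(u) = sum_i S_i * sinc( L * sqrt(6 * D0 * b_i) * <g_i, u> ),

  with sinc(x) = sin(x)/x, sampling ratio L (default 1.25) and free-water
  diffusivity D0 = 2.5e-3 mm^2/s.  Protrusions of psi above the isotropic
  background mark fiber directions; the peak amplitude after per-voxel
  minimum subtraction, normalized by the volume-wide maximum, is the
  quantitative anisotropy (QA) used by the tracker as a termination
  criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sphere import Sphere, icosphere, tangent_basis
from .phantom import DwiVolume

__all__ = [
    "TensorVolume",
    "ScalarMaps",
    "OdfVolume",
    "PeakField",
    "fit_tensor",
    "tensor_metrics",
    "reconstruct_sdf",
    "extract_peaks",
    "FREE_WATER_DIFFUSIVITY",
]

#: Free-water diffusivity constant used in the SDF kernel (mm^2/s).
FREE_WATER_DIFFUSIVITY = 2.5e-3


@dataclass
class TensorVolume:
    tensors: np.ndarray   # (X, Y, Z, 3, 3) symmetric, mm^2/s
    s0: np.ndarray        # (X, Y, Z) fitted S0
    valid: np.ndarray     # (X, Y, Z) bool
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None


@dataclass
class ScalarMaps:
    """FA (dimensionless), MD and AD (mm^2/s); NaN outside the valid mask."""

    fa: np.ndarray
    md: np.ndarray
    ad: np.ndarray
    valid: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None


@dataclass
class OdfVolume:
    sphere: Sphere
    psi: np.ndarray       # (X, Y, Z, V), min-subtracted per voxel, >= 0
    mask: np.ndarray      # (X, Y, Z) bool
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None


@dataclass
class PeakField:
    """Per-voxel fiber directions sorted by descending QA."""

    directions: np.ndarray  # (X, Y, Z, M, 3) unit vectors, zero-padded
    qa: np.ndarray          # (X, Y, Z, M), in [0, 1], non-increasing per voxel
    n_peaks: np.ndarray     # (X, Y, Z) int
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    @property
    def grid_shape(self) -> tuple:
        return self.n_peaks.shape


# ---------------------------------------------------------------------------
# tensor fit
# ---------------------------------------------------------------------------

def _design_matrix(gtab) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz]."""
    g = gtab.directions
    b = gtab.bvalues
    return np.column_stack([
        np.ones(len(b)),
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
    ])


def _params_to_tensors(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(N, 7) fitted params -> (N, 3, 3) tensors and (N,) S0."""
    s0 = np.exp(params[:, 0])
    dxx, dyy, dzz, dxy, dxz, dyz = params[:, 1:7].T
    t = np.empty((len(params), 3, 3))
    t[:, 0, 0] = dxx
    t[:, 1, 1] = dyy
    t[:, 2, 2] = dzz
    t[:, 0, 1] = t[:, 1, 0] = dxy
    t[:, 0, 2] = t[:, 2, 0] = dxz
    t[:, 1, 2] = t[:, 2, 1] = dyz
    return t, s0


def fit_tensor(dwi: DwiVolume, mask: np.ndarray | None = None) -> TensorVolume:
    """Unweighted log-linear least-squares tensor fit per masked voxel.

    Solves ln S = ln S0 - b g^T D g.  Measurements with non-positive signal
    are excluded from a voxel's equations; voxels left with fewer than 7
    usable measurements are flagged invalid (never silently zeroed).
    """
    gtab = dwi.gradient_table
    if gtab.n_dwi < 6 or not gtab.b0_flags.any():
        raise ValueError("tensor fit needs >= 6 DWI directions and >= 1 b0")
    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    X = _design_matrix(gtab)
    sig = dwi.signal.reshape(-1, len(gtab))
    flat_mask = mask.reshape(-1)
    tensors = np.full((sig.shape[0], 3, 3), np.nan)
    s0 = np.full(sig.shape[0], np.nan)
    valid = np.zeros(sig.shape[0], dtype=bool)

    rows = np.flatnonzero(flat_mask)
    pos = sig[rows] > 0
    all_pos = pos.all(axis=1)

    # fast path: every measurement usable -> one shared lstsq
    if all_pos.any():
        r = rows[all_pos]
        y = np.log(sig[r])
        params, *_ = np.linalg.lstsq(X, y.T, rcond=None)
        t, s = _params_to_tensors(params.T)
        tensors[r], s0[r], valid[r] = t, s, True

    # slow path: voxels with some non-positive measurements
    for r in rows[~all_pos]:
        use = sig[r] > 0
        if use.sum() < 7:
            continue
        params, *_ = np.linalg.lstsq(X[use], np.log(sig[r, use]), rcond=None)
        t, s = _params_to_tensors(params[None, :])
        tensors[r], s0[r], valid[r] = t[0], s[0], True

    return TensorVolume(
        tensors=tensors.reshape(shape + (3, 3)),
        s0=s0.reshape(shape),
        valid=valid.reshape(shape),
        voxel_size=dwi.voxel_size,
        affine=dwi.affine,
    )


def tensor_metrics(tv: TensorVolume) -> ScalarMaps:
    """FA / MD / AD from the tensor eigenvalues.

    MD = (l1+l2+l3)/3, AD = l1,
    FA = sqrt(3/2) * sqrt(sum (l_i - MD)^2) / sqrt(sum l_i^2),
    with FA defined as 0 when all eigenvalues vanish.
    """
    shape = tv.valid.shape
    fa = np.full(shape, np.nan)
    md = np.full(shape, np.nan)
    ad = np.full(shape, np.nan)
    rows = tv.valid.reshape(-1)
    if rows.any():
        t = tv.tensors.reshape(-1, 3, 3)[rows]
        lam = np.linalg.eigvalsh(t)[:, ::-1]       # descending
        m = lam.mean(axis=1)
        num = ((lam - m[:, None]) ** 2).sum(axis=1)
        den = (lam ** 2).sum(axis=1)
        f = np.where(den > 0, np.sqrt(1.5 * num / np.where(den > 0, den, 1.0)), 0.0)
        fa.reshape(-1)[rows] = f
        md.reshape(-1)[rows] = m
        ad.reshape(-1)[rows] = lam[:, 0]
    return ScalarMaps(fa=fa, md=md, ad=ad, valid=tv.valid.copy(),
                      voxel_size=tv.voxel_size, affine=tv.affine)


# ---------------------------------------------------------------------------
# q-space SDF
# ---------------------------------------------------------------------------

def reconstruct_sdf(
    dwi: DwiVolume,
    mask: np.ndarray | None = None,
    sphere_order: int = 3,
    sampling_ratio: float = 1.25,
) -> OdfVolume:
    """Spin-distribution function on a subdivided icosahedral sphere.

    The SDF is a single matrix product of the signal with the sinc kernel;
    each voxel's function is then shifted so its minimum over the sphere is
    zero (removing the isotropic background).
    """
    shape = dwi.grid_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")

    sphere = icosphere(sphere_order)
    g = dwi.gradient_table.directions
    b = dwi.gradient_table.bvalues
    # kernel K[i, v] = sinc(L * sqrt(6 D0 b_i) * <g_i, u_v>), sinc(x)=sin(x)/x
    q = sampling_ratio * np.sqrt(6.0 * FREE_WATER_DIFFUSIVITY * b)
    arg = q[:, None] * (g @ sphere.vertices.T)
    kernel = np.sinc(arg / np.pi)   # np.sinc is sin(pi x)/(pi x)

    psi = np.zeros(shape + (sphere.n_vertices,), dtype=np.float64)
    flat = dwi.signal.reshape(-1, len(b))
    rows = np.flatnonzero(mask.reshape(-1))
    vals = flat[rows] @ kernel
    vals -= vals.min(axis=1, keepdims=True)
    psi.reshape(-1, sphere.n_vertices)[rows] = vals
    return OdfVolume(sphere=sphere, psi=psi, mask=mask,
                     voxel_size=dwi.voxel_size, affine=dwi.affine)


def _refine_peak(sphere: Sphere, psi_v: np.ndarray, vertex: int) -> np.ndarray:
    """Refine a vertex maximum by a local quadratic fit in tangent coords.

    Fits psi ~ quadratic over the vertex and its ring neighbors and moves to
    the stationary point when it is a maximum inside the cell; this brings
    the angular error well below the tessellation spacing.
    """
    v0 = sphere.vertices[vertex]
    nbrs = list(sphere.neighbors[vertex])
    pts = sphere.vertices[[vertex] + nbrs]
    e1, e2 = tangent_basis(v0)
    x = pts @ e1
    y = pts @ e2
    A = np.column_stack([np.ones_like(x), x, y, x * x, y * y, x * y])
    try:
        coef, *_ = np.linalg.lstsq(A, psi_v[[vertex] + nbrs], rcond=None)
    except np.linalg.LinAlgError:
        return v0
    _, b1, b2, c11, c22, c12 = coef
    H = np.array([[2 * c11, c12], [c12, 2 * c22]])
    # stationary point of the quadratic; keep only interior maxima
    try:
        sol = np.linalg.solve(H, -np.array([b1, b2]))
    except np.linalg.LinAlgError:
        return v0
    if np.any(np.linalg.eigvalsh(H) >= 0):
        return v0
    cell = np.max(np.sqrt((x[1:] ** 2 + y[1:] ** 2)))
    if np.linalg.norm(sol) > cell:
        return v0
    refined = v0 + sol[0] * e1 + sol[1] * e2
    return refined / np.linalg.norm(refined)


def extract_peaks(
    odf: OdfVolume,
    max_peaks: int = 3,
    min_separation_angle: float = 25.0,
    qa_floor: float = 0.05,
) -> PeakField:
    """Fiber peaks: local SDF maxima with separation and QA thresholds.

    Local maxima over the sphere's vertex graph are merged across antipodes,
    greedily accepted in descending psi subject to a pairwise separation of
    at least ``min_separation_angle`` degrees, refined by local quadratic
    interpolation, and assigned QA = psi(peak) normalized by the volume-wide
    maximum.  Peaks with QA below ``qa_floor`` are discarded.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    sphere = odf.sphere
    shape = odf.mask.shape
    n_vert = sphere.n_vertices
    psi = odf.psi.reshape(-1, n_vert)
    rows = np.flatnonzero(odf.mask.reshape(-1))

    # vertex -> padded neighbor index array for vectorized local-max test
    max_deg = max(len(nb) for nb in sphere.neighbors)
    nbr = np.full((n_vert, max_deg), -1, dtype=np.int64)
    for i, nb in enumerate(sphere.neighbors):
        nbr[i, : len(nb)] = nb

    cos_sep = np.cos(np.deg2rad(min_separation_angle))

    directions = np.zeros(shape + (max_peaks, 3))
    qa_arr = np.zeros(shape + (max_peaks,))
    n_peaks = np.zeros(shape, dtype=np.int32)
    dir_flat = directions.reshape(-1, max_peaks, 3)
    qa_flat = qa_arr.reshape(-1, max_peaks)
    np_flat = n_peaks.reshape(-1)

    # vectorized neighbor-max over all masked voxels (loop over degree only)
    psi_rows = psi[rows]
    neigh_max = np.full_like(psi_rows, -np.inf)
    for d in range(max_deg):
        col = nbr[:, d]
        has = col >= 0
        vals = psi_rows[:, np.maximum(col, 0)]
        neigh_max[:, has] = np.maximum(neigh_max[:, has], vals[:, has])
    is_max_rows = psi_rows >= neigh_max

    peak_vals_all = []
    peaks_per_voxel = []
    for ri, r in enumerate(rows):
        p = psi[r]
        cand = np.flatnonzero(is_max_rows[ri])
        cand = cand[np.argsort(p[cand])[::-1]]
        accepted: list[int] = []
        acc_dirs: list[np.ndarray] = []
        for c in cand:
            d = sphere.vertices[c]
            if any(abs(d @ a) > cos_sep for a in acc_dirs):
                continue
            accepted.append(int(c))
            acc_dirs.append(d)
            if len(accepted) == max_peaks:
                break
        refined = [_refine_peak(sphere, p, c) for c in accepted]
        vals = p[accepted]
        peaks_per_voxel.append((r, refined, vals))
        peak_vals_all.append(vals.max() if len(vals) else 0.0)

    vol_max = max(peak_vals_all) if peak_vals_all else 0.0
    if vol_max <= 0:
        vol_max = 1.0

    for r, refined, vals in peaks_per_voxel:
        qa = vals / vol_max
        keep = qa >= qa_floor
        k = int(keep.sum())
        if k == 0:
            continue
        dir_flat[r, :k] = np.asarray(refined)[keep][:k]
        qa_flat[r, :k] = qa[keep][:k]
        np_flat[r] = k

    return PeakField(directions=directions, qa=qa_arr, n_peaks=n_peaks,
                     voxel_size=odf.voxel_size, affine=odf.affine)
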