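"""End-to-end phantom studies: simulate -> reconstruct -> track -> classify.

This module wires the stages together the way the analyses use them, most
importantly the projecting-bundle recovery study: k straight bundles pierce
a spherical "tumor" and extend beyond it; the full pipeline must find the
tumor-intersecting tracts, classify them, and count k projecting bundles.

Seeding is restricted to the bundle interior (voxels whose center lies
within a margin of the centerline): partial-volume voxels at a tube surface
carry weaker, noisier orientation estimates and are poor seed locations, as
in standard white-matter seeding practice where seeds are placed inside a
tissue mask rather than on its boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import phantom, recon, tracking, tumor_tracts

__all__ = ["BundleRecovery", "recover_bundles"]


@dataclass
class BundleRecovery:
    """Outcome of one end-to-end bundle-recovery run."""

    n_bundles_true: int
    n_bundles_found: int
    n_tracts: int
    n_by_class: dict
    frac_projecting: float        # fraction of tumor-intersecting tracts
    metrics: tumor_tracts.TractMetrics


def recover_bundles(
    n_bundles: int,
    snr: float = 30.0,
    seed: int = 0,
    preset: str = "human64",
    seed_margin: float = 1.5,
    tracking_params: tracking.TrackingParams | None = None,
) -> BundleRecovery:
    """Run the full pipeline on a k-bundle crossing phantom.

    Parameters
    ----------
    n_bundles : number of constructed bundles piercing the tumor (1-5).
    snr : acquisition signal-to-noise ratio (S0 / sigma).
    seed : seeds the acquisition noise, gradient scheme and seed jitter.
    preset : acquisition preset name (direction count, b-value, voxel size).
    seed_margin : mm subtracted from the bundle radius when building the
        seed mask, keeping seeds off partial-volume surface voxels.
    """
    p = phantom.PRESETS[preset]
    spec = phantom.bundle_crossing_spec(n_bundles, voxel_size=p["voxel_size"])
    gtab = phantom.make_gradient_table(p["n_directions"], p["bvalue"],
                                       n_b0=1, seed=seed + 1)
    vol, truth = phantom.simulate_dwi(spec, gtab, snr=snr, seed=seed + 2)

    tissue = truth.bundle_masks.any(axis=0) | truth.tumor_mask
    mask = ndimage.binary_dilation(tissue, iterations=2)
    odf = recon.reconstruct_sdf(vol, mask=mask)
    peaks = recon.extract_peaks(odf)

    seeds = phantom.interior_seed_points(spec, truth, seeds_per_voxel=2,
                                         margin=seed_margin, seed=seed + 3)
    tg = tracking.track_all(peaks, seeds, tracking_params)

    roi = tumor_tracts.RoiMask(mask=truth.tumor_mask, affine=spec.affine,
                               voxel_size=spec.voxel_size)
    sel = tumor_tracts.select_tumor_tracts(tg, roi)
    classes = tumor_tracts.classify_tracts(sel, roi)
    scalar_maps = recon.tensor_metrics(recon.fit_tensor(vol, mask=mask))
    metrics = tumor_tracts.tract_metrics(sel, classes, roi,
                                         scalar_maps=scalar_maps, peaks=peaks)
    n_proj = metrics.n_tracts_by_class["projecting"]
    return BundleRecovery(
        n_bundles_true=n_bundles,
        n_bundles_found=metrics.n_projecting_bundles,
        n_tracts=len(sel),
        n_by_class=metrics.n_tracts_by_class,
        frac_projecting=n_proj / len(sel) if len(sel) else 0.0,
        metrics=metrics,
    )
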