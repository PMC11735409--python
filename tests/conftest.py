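import numpy as np
import pytest

from axialquant import (
    ConsolidationParams,
    NoiseSpec,
    PlaneMask,
    SceneSpec,
    consolidate,
    emit_detections,
    generate_scene,
)
from axialquant.synthetic import true_mask_labels


def mask_from_array(arr, plane, label=1, **kw):
    rr, cc = np.nonzero(np.asarray(arr))
    return PlaneMask(plane, label, np.column_stack((rr, cc)), **kw)


def rect_mask(plane, label, r0, c0, h, w, **kw):
    rr, cc = np.mgrid[r0 : r0 + h, c0 : c0 + w]
    return PlaneMask(plane, label, np.column_stack((rr.ravel(), cc.ravel())), **kw)


def params_for(truth, **kw):
    """Synthetic-default size thresholds from the true median z-extent."""
    extents = [len(np.unique(n.voxels[:, 0])) for n in truth.nuclei] or [1.0]
    return ConsolidationParams.from_median_extent(float(np.median(extents)), **kw)


def recovered_labels(nuclei, masks):
    by_key = {k: n.nucleus_id for n in nuclei for k in n.member_masks}
    return np.array([by_key[m.key] for m in masks])


def scene_ari(seed, n_nuclei=120, geometry="disc", noise=None, max_plane_gap=1):
    """Generate, detect, consolidate; return (ARI, truth, masks, nuclei)."""
    from sklearn.metrics import adjusted_rand_score

    area_scale = np.sqrt(n_nuclei / 150.0)
    if geometry == "disc":
        spec = SceneSpec.micropattern(diameter=200.0 * area_scale, n_nuclei=n_nuclei, rng_seed=seed)
    else:
        spec = SceneSpec.notoroid(
            length=500.0 * area_scale, width=160.0 * area_scale, n_nuclei=n_nuclei, rng_seed=seed
        )
    _, truth = generate_scene(spec, render=False)
    masks = emit_detections(truth, noise or NoiseSpec(), np.random.default_rng(seed + 1))
    params = params_for(truth, rng_seed=seed, max_plane_gap=max_plane_gap)
    nuclei = consolidate(masks, params)
    ari = adjusted_rand_score(true_mask_labels(truth, masks), recovered_labels(nuclei, masks))
    return ari, truth, masks, nuclei


@pytest.fixture(scope="session")
def small_scene():
    """One modest noise-free disc scene shared across tests."""
    spec = SceneSpec.micropattern(diameter=160.0, n_nuclei=80, rng_seed=7)
    stack, truth = generate_scene(spec)
    masks = emit_detections(truth, NoiseSpec(), np.random.default_rng(8))
    return spec, stack, truth, masks
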