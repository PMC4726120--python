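import numpy as np
import pytest
from hypothesis import settings

import striation as st

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_segcfg(noisy: bool) -> st.SegmentationConfig:
    """Segmentation gates sized for the synthetic scenes (nuclei ~250-600 px)."""
    return st.SegmentationConfig(
        min_area_px=150,
        max_area_px=5000,
        smoothing_sigma_px=1.0 if noisy else 0.0,
    )


def match_track_to_truth(track, truth, frame_index=0):
    """Ground-truth nucleus index (0-based) for a track, by majority overlap."""
    mask = track.mask_at(frame_index)
    lab = truth.label_images[frame_index]
    ids, counts = np.unique(
        lab[mask.coords[:, 0], mask.coords[:, 1]], return_counts=True
    )
    keep = ids > 0
    if not keep.any():
        return None
    return int(ids[keep][np.argmax(counts[keep])]) - 1


def closure_errors(stack, truth, result):
    """Per-record |MS - MS_true| for every unflagged record."""
    times = list(stack.times_min)
    by_id = {t.nucleus_id: t for t in result.tracks}
    errs = []
    for rec in result.records:
        if rec.flagged:
            continue
        f = times.index(rec.time_min)
        track = by_id[rec.nucleus_id]
        mask = track.mask_at(f)
        lab = truth.label_images[f]
        ids, counts = np.unique(
            lab[mask.coords[:, 0], mask.coords[:, 1]], return_counts=True
        )
        keep = ids > 0
        gt = int(ids[keep][np.argmax(counts[keep])]) - 1
        errs.append(abs(rec.ms - truth.ms_true[f, gt]))
    return np.asarray(errs)


def striped_nucleus(
    d_px=12, p_from_right=4, width=3, shape=(64, 64), a=26, b=18,
    stripe_value=3.0, base_value=1.0,
):
    """Masked elliptical nucleus with exact vertical stripes.

    Stripe bands are ``width`` consecutive columns whose anchor column is
    ``p_from_right`` left of the rightmost mask column, repeating every
    ``d_px`` columns (the same band convention the fit uses).
    """
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1
    img = np.where(mask, base_value, 0.0)
    x_right = int(np.nonzero(mask.any(axis=0))[0].max())
    d = np.mod(xx - (x_right - p_from_right), d_px)
    member = (d <= width // 2) | (d >= d_px - (width - 1) // 2)
    img[mask & member] = stripe_value
    return img, mask


@pytest.fixture(scope="session")
def noiseless_scene():
    """Motionless, noiseless DDR scene: the end-to-end exactness oracle."""
    cfg = st.SceneConfig(
        field_size_px=(512, 512),
        n_nuclei=20,
        lines_per_field=32,
        read_noise_sigma=0.0,
        motion_sigma_px=0.0,
        seed=7,
    )
    return cfg, *st.render_scene(cfg)


@pytest.fixture(scope="session")
def noiseless_result(noiseless_scene):
    cfg, stack, truth = noiseless_scene
    acfg = st.AnalysisConfig(
        mode="live_ddr",
        lines_per_field=cfg.lines_per_field,
        width_px=cfg.width_px,
        segmentation=make_segcfg(noisy=False),
    )
    return st.analyze_stack(stack, acfg)
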