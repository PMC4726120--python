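"""Nucleus tracking across frames by local re-segmentation.

After irradiation the inter-stripe regions of a nucleus can fall all
the way to background, so whole-frame re-segmentation would lose the
nucleus entirely.  Instead, each nucleus is re-found by running the
threshold cascade only inside the neighbourhood of its position in the
previous frame (the previous bounding box dilated by the search
radius), with a lowered threshold floor because striped nuclei are
dimmer between stripes.  The candidate whose centroid is nearest to the
previous centroid wins; if none qualifies, the previous mask is carried
forward rigidly for a bounded number of frames before the track is
declared lost.  Lost tracks are never resurrected, and no pixel is
claimed by two tracks in the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from scipy import ndimage
from skimage.measure import label, regionprops
from skimage.morphology import convex_hull_image

from .io import FrameStack
from .segmentation import NucleusMask, SegmentationConfig, _threshold_schedule

__all__ = ["NucleusTrack", "track_nuclei"]


@dataclass
class NucleusTrack:
    """Identity of one nucleus maintained across frames.

    ``entries`` holds (frame_index, mask) pairs with strictly increasing
    frame indices starting at frame 0; ``lost_at`` is the first frame
    index at which the track was lost (None while alive).
    """

    nucleus_id: int
    entries: list[tuple[int, NucleusMask]] = field(default_factory=list)
    lost_at: int | None = None

    @property
    def n_tracked(self) -> int:
        return len(self.entries)

    def mask_at(self, frame_index: int) -> NucleusMask | None:
        for f, m in self.entries:
            if f == frame_index:
                return m
        return None


def _local_candidates(
    frame: np.ndarray,
    prev: NucleusMask,
    radius: int,
    cfg: SegmentationConfig,
) -> list[NucleusMask]:
    """Candidate masks near a previous nucleus position.

    Sweeps the full threshold schedule on the cropped neighbourhood and
    collects, at every level, the connected components that look like a
    plausible continuation of the previous mask (solidity gate, area
    between 0.3x and 3x the previous area).  Unlike the first-frame
    cascade, no level "freezes" pixels: a striped nucleus first appears
    as its bright stripes and only becomes whole at a deeper threshold,
    so the caller picks the level whose component is most consistent
    with the previous mask rather than the brightest fragment.
    """
    h, w = frame.shape
    min_r, min_c, max_r, max_c = prev.bbox
    r0, c0 = max(min_r - radius, 0), max(min_c - radius, 0)
    r1, c1 = min(max_r + radius + 1, h), min(max_c + radius + 1, w)
    sub = frame[r0:r1, c0:c1]
    if cfg.smoothing_sigma_px > 0:
        smoothed = ndimage.gaussian_filter(sub, cfg.smoothing_sigma_px)
    else:
        smoothed = sub
    area_lo = max(int(0.3 * prev.area_px), 8)
    area_hi = int(3.0 * prev.area_px)
    out: list[NucleusMask] = []
    for t in _threshold_schedule(smoothed, cfg):
        lab = label(smoothed >= t, connectivity=1)
        for rp in regionprops(lab):
            b0, b1, b2, b3 = rp.bbox
            comp = ndimage.binary_fill_holes(lab[b0:b2, b1:b3] == rp.label)
            area = int(comp.sum())
            if not (area_lo <= area <= area_hi):
                continue
            solidity = float(regionprops(comp.astype(np.uint8))[0].solidity)
            if solidity < cfg.min_solidity:
                continue
            # Thresholding under-covers striped nuclei on their dim side
            # (inter-stripe intensity can reach background), which would
            # bias MS by preferentially excluding dim pixels.  Accepted
            # nuclei are near-convex by the solidity gate, so the convex
            # hull restores the full outline without following intensity.
            # offset_coordinates=False keeps the hull inside the pixel-center
            # polygon, so it never annexes background pixels.
            comp = convex_hull_image(comp, offset_coordinates=False)
            rr, cc = np.nonzero(comp)
            coords = np.column_stack([rr + b0 + r0, cc + b1 + c0])
            out.append(
                NucleusMask(nucleus_id=prev.nucleus_id, coords=coords, solidity=solidity)
            )
    return out


def _place_template(
    frame: np.ndarray,
    ref: NucleusMask,
    cand: NucleusMask,
    claimed: np.ndarray,
    refine_px: int = 2,
) -> NucleusMask | None:
    """Rigidly place the reference mask at the candidate's position.

    The initial integer shift moves the reference centroid onto the
    candidate centroid; it is then refined over a small window by
    maximising the total intensity inside the placed mask (the optimum
    is where the mask covers the nucleus rather than background, and is
    neutral with respect to the stripe pattern, which the mask covers at
    any nearby shift).  Returns None when the placed mask would overlap
    pixels already claimed by another track or fall entirely outside
    the frame.
    """
    dr0 = int(round(cand.centroid[0] - ref.centroid[0]))
    dc0 = int(round(cand.centroid[1] - ref.centroid[1]))
    best: tuple[float, int, int] | None = None
    for dr in range(dr0 - refine_px, dr0 + refine_px + 1):
        for dc in range(dc0 - refine_px, dc0 + refine_px + 1):
            shifted = ref.translated(dr, dc, frame.shape)
            if shifted is None or shifted.area_px < ref.area_px:
                continue  # falling off the frame edge is not a valid placement
            score = float(frame[shifted.coords[:, 0], shifted.coords[:, 1]].sum())
            if best is None or score > best[0]:
                best = (score, dr, dc)
    if best is None:
        # Allow edge-clipped placement as a last resort.
        shifted = ref.translated(dr0, dc0, frame.shape)
        if shifted is None:
            return None
        best = (0.0, dr0, dc0)
    placed = ref.translated(best[1], best[2], frame.shape)
    if placed is None or claimed[placed.coords[:, 0], placed.coords[:, 1]].any():
        return None
    return placed


def track_nuclei(
    stack: FrameStack,
    initial: list[NucleusMask],
    search_radius_px: float = 25.0,
    cfg: SegmentationConfig | None = None,
    max_carry: int = 2,
    local_floor_quantile: float = 0.3,
) -> list[NucleusTrack]:
    """Track nuclei segmented on frame 0 through all later frames.

    Parameters
    ----------
    stack : FrameStack
        The time series being analysed.
    initial : list of NucleusMask
        Masks from frame 0 (typically ``segment_cascade`` output).
    search_radius_px : float
        Vicinity radius: the previous bounding box is dilated by this
        amount for local re-segmentation, and accepted centroids must
        lie within this distance of the previous centroid.
    cfg : SegmentationConfig
        Gates for the local cascade; its ``threshold_floor_quantile``
        is replaced by ``local_floor_quantile`` and border exclusion is
        disabled (the crop boundary is not a real image border).
    max_carry : int
        Maximum number of consecutive frames the previous mask may be
        carried forward rigidly before the track is marked lost.

    Returns one :class:`NucleusTrack` per initial mask.  Conflicts (two
    tracks wanting overlapping pixels) are resolved greedily by centroid
    distance, ties by lower nucleus id.
    """
    if search_radius_px <= 0:
        raise ValueError("search_radius_px must be > 0")
    if not initial:
        return []
    if cfg is None:
        cfg = SegmentationConfig()
    local_cfg = replace(
        cfg,
        threshold_floor_quantile=local_floor_quantile,
        exclude_border=False,
    )
    radius = int(np.ceil(search_radius_px))

    tracks = [
        NucleusTrack(nucleus_id=m.nucleus_id, entries=[(0, m)]) for m in initial
    ]
    carry_count = {t.nucleus_id: 0 for t in tracks}
    # The frame-0 mask is the shape template for the whole track: local
    # re-segmentation only *positions* it.  A mask re-drawn by
    # thresholding every frame would follow the intensity pattern and
    # preferentially drop dim inter-stripe pixels, biasing MS upward;
    # shape change over time is instead absorbed by the per-frame
    # stripe-fit downstream.
    ref_mask = {m.nucleus_id: m for m in initial}
    shape = stack.shape

    for f in range(1, stack.n_frames):
        frame = stack.frames[f]
        claimed = np.zeros(shape, dtype=bool)
        alive = [t for t in tracks if t.lost_at is None]

        # Rank each track's candidates by area consistency with the
        # previous mask (then centroid distance); process tracks in order
        # of their best candidate's distance, so on a pixel conflict the
        # nearer centroid wins and the loser falls through to next-best.
        ranked: dict[int, list[tuple[float, float, NucleusMask]]] = {}
        for t in alive:
            prev = t.entries[-1][1]
            pr, pc = prev.centroid
            scored = []
            for cand in _local_candidates(frame, prev, radius, local_cfg):
                cr, cc = cand.centroid
                dist = float(np.hypot(cr - pr, cc - pc))
                if dist > search_radius_px:
                    continue
                area_score = abs(np.log(cand.area_px / prev.area_px))
                scored.append((area_score, dist, cand))
            scored.sort(key=lambda x: (x[0], x[1]))
            ranked[t.nucleus_id] = scored

        order = sorted(
            (t for t in alive if ranked[t.nucleus_id]),
            key=lambda t: (ranked[t.nucleus_id][0][1], t.nucleus_id),
        )
        assigned: dict[int, NucleusMask] = {}
        for t in order:
            ref = ref_mask[t.nucleus_id]
            for _, _, cand in ranked[t.nucleus_id]:
                placed = _place_template(frame, ref, cand, claimed)
                if placed is None:
                    continue
                claimed[placed.coords[:, 0], placed.coords[:, 1]] = True
                assigned[t.nucleus_id] = placed
                break

        for t in alive:
            if t.nucleus_id in assigned:
                cand = assigned[t.nucleus_id]
                t.entries.append((f, replace(cand, nucleus_id=t.nucleus_id)))
                carry_count[t.nucleus_id] = 0
                continue
            # Carry the previous mask forward rigidly, clipped against
            # pixels already claimed in this frame.
            carry_count[t.nucleus_id] += 1
            if carry_count[t.nucleus_id] > max_carry:
                t.lost_at = f
                continue
            prev = t.entries[-1][1]
            keep = ~claimed[prev.coords[:, 0], prev.coords[:, 1]]
            if not keep.any():
                t.lost_at = f
                continue
            carried = replace(prev, coords=prev.coords[keep])
            claimed[carried.coords[:, 0], carried.coords[:, 1]] = True
            t.entries.append((f, carried))
    return tracks
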