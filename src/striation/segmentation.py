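"""Nucleus segmentation by a cascade of decreasing thresholds.

Live-cell reporter fields show a very large spread of per-nucleus
baseline intensity (easily a 10x fold-range), so a single global
threshold (e.g. Otsu) either merges bright nuclei with background
structure or misses dim ones entirely.  The cascade instead sweeps a
sequence of decreasing intensity thresholds: at each level, connected
components that satisfy the size and solidity gates are accepted and
their pixels frozen (removed from all lower levels), so each nucleus is
captured at the highest threshold at which it appears as a complete,
compact object.

In fixed-sample mode the same cascade is applied to a DNA counterstain
(Hoechst) channel, and the resulting masks are used to measure the
signal channel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import cached_property

import numpy as np
from scipy import ndimage
from skimage.measure import label, regionprops

__all__ = [
    "NucleusMask",
    "SegmentationConfig",
    "segment_cascade",
    "segment_hoechst",
    "masks_to_label_image",
]

# Safety cap on cascade depth; the geometric schedule reaches its floor in
# far fewer levels for any realistic dynamic range.
_MAX_LEVELS = 500


@dataclass(frozen=True)
class NucleusMask:
    """One segmented nucleus in one frame.

    ``coords`` is an (N, 2) integer array of (row, col) pixel
    coordinates forming a single 4-connected component.  Masks of
    distinct nuclei in one frame are disjoint.
    """

    nucleus_id: int
    coords: np.ndarray
    solidity: float

    def __post_init__(self):
        if len(self.coords) == 0:
            raise ValueError("a nucleus mask cannot be empty")
        if not (0.0 < self.solidity <= 1.0 + 1e-12):
            raise ValueError(f"solidity must be in (0, 1], got {self.solidity}")

    @property
    def area_px(self) -> int:
        return len(self.coords)

    @cached_property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid."""
        return (float(self.coords[:, 0].mean()), float(self.coords[:, 1].mean()))

    @cached_property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        return (
            int(self.coords[:, 0].min()),
            int(self.coords[:, 1].min()),
            int(self.coords[:, 0].max()),
            int(self.coords[:, 1].max()),
        )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Render the pixel set as a boolean image of the given shape."""
        m = np.zeros(shape, dtype=bool)
        m[self.coords[:, 0], self.coords[:, 1]] = True
        return m

    def translated(self, dr: int, dc: int, shape: tuple[int, int]) -> "NucleusMask | None":
        """Rigidly shifted copy, clipped to the frame; None if nothing remains."""
        coords = self.coords + np.array([dr, dc])
        keep = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] < shape[0])
            & (coords[:, 1] >= 0)
            & (coords[:, 1] < shape[1])
        )
        if not keep.any():
            return None
        return replace(self, coords=coords[keep])


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunables of the threshold cascade.

    The threshold sequence starts at the image intensity quantile
    ``threshold_start_quantile``, is multiplied by
    ``threshold_decay_factor`` at each step, and stops once it falls
    below the intensity at ``threshold_floor_quantile``.  Candidate
    components are gated on pixel area in
    [``min_area_px``, ``max_area_px``] and on solidity (area over convex
    hull area) of at least ``min_solidity``; holes in accepted
    components are filled.  ``smoothing_sigma_px`` controls a light
    Gaussian pre-smoothing that suppresses shot noise; set it to 0 to
    threshold raw intensities.
    """

    threshold_start_quantile: float = 0.995
    threshold_decay_factor: float = 0.9
    threshold_floor_quantile: float = 0.5
    min_area_px: int = 500
    max_area_px: int = 15000
    min_solidity: float = 0.90
    exclude_border: bool = True
    smoothing_sigma_px: float = 1.0

    def __post_init__(self):
        if not (0 < self.threshold_floor_quantile <= self.threshold_start_quantile <= 1):
            raise ValueError("require 0 < floor quantile <= start quantile <= 1")
        if not (0 < self.threshold_decay_factor < 1):
            raise ValueError("threshold_decay_factor must be in (0, 1)")
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("require 0 < min_area_px < max_area_px")
        if not (0 < self.min_solidity <= 1):
            raise ValueError("min_solidity must be in (0, 1]")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")


def _threshold_schedule(smoothed: np.ndarray, cfg: SegmentationConfig) -> list[float]:
    start = float(np.quantile(smoothed, cfg.threshold_start_quantile))
    floor = float(np.quantile(smoothed, cfg.threshold_floor_quantile))
    if start <= 0:
        return []
    # Keep the schedule finite even when the floor quantile lands on zero
    # (e.g. a mostly-empty field).
    floor = max(floor, start * 1e-6)
    levels: list[float] = []
    t = start
    while t >= floor and len(levels) < _MAX_LEVELS:
        levels.append(t)
        t *= cfg.threshold_decay_factor
    return levels


def segment_cascade(frame: np.ndarray, cfg: SegmentationConfig) -> list[NucleusMask]:
    """Find nuclei in a single frame with the decreasing-threshold cascade.

    Returns disjoint :class:`NucleusMask` objects, each a 4-connected
    component satisfying the area and solidity gates, ordered and
    numbered deterministically (by acceptance level, then top-left bbox
    corner).  An all-zero frame yields an empty list.

    Raises
    ------
    ValueError
        If the frame is empty, not 2D, or contains non-finite or
        negative values.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2D array")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame must be finite")
    if frame.min() < 0:
        raise ValueError("frame must be non-negative")

    if cfg.smoothing_sigma_px > 0:
        smoothed = ndimage.gaussian_filter(frame, cfg.smoothing_sigma_px)
    else:
        smoothed = frame

    claimed = np.zeros(frame.shape, dtype=bool)
    accepted: list[NucleusMask] = []
    h, w = frame.shape

    for t_level in _threshold_schedule(smoothed, cfg):
        bw = (smoothed >= t_level) & ~claimed
        if not bw.any():
            continue
        lab = label(bw, connectivity=1)
        candidates = []
        for rp in regionprops(lab):
            min_r, min_c, max_r, max_c = rp.bbox
            comp = lab[min_r:max_r, min_c:max_c] == rp.label
            # Fill interior holes, but never annex pixels of a mask
            # accepted at a higher threshold.
            comp = ndimage.binary_fill_holes(comp)
            comp &= ~claimed[min_r:max_r, min_c:max_c]
            area = int(comp.sum())
            if not (cfg.min_area_px <= area <= cfg.max_area_px):
                continue
            if cfg.exclude_border and (
                min_r == 0 or min_c == 0 or max_r == h or max_c == w
            ):
                continue
            # Clipping against claimed pixels can in principle split the
            # component; only single 4-connected pieces are nuclei.
            comp_lab = label(comp, connectivity=1)
            if comp_lab.max() != 1:
                continue
            solidity = float(regionprops(comp_lab)[0].solidity)
            if solidity < cfg.min_solidity:
                continue
            rr, cc = np.nonzero(comp)
            coords = np.column_stack([rr + min_r, cc + min_c])
            candidates.append((min_r, min_c, coords, solidity))
        # Deterministic ordering within a level: top-left bbox corner.
        for min_r, min_c, coords, solidity in sorted(
            candidates, key=lambda x: (x[0], x[1])
        ):
            # A later candidate at the same level may overlap an earlier
            # one after hole filling; first (top-left) acceptance wins.
            if claimed[coords[:, 0], coords[:, 1]].any():
                continue
            claimed[coords[:, 0], coords[:, 1]] = True
            accepted.append(
                NucleusMask(nucleus_id=len(accepted), coords=coords, solidity=solidity)
            )
    # Sequential refinement against the evolving claim map keeps refined
    # masks mutually disjoint.
    refined: list[NucleusMask] = []
    for m in accepted:
        claimed[m.coords[:, 0], m.coords[:, 1]] = False
        new = _refine_mask(smoothed, m, claimed, cfg)
        claimed[new.coords[:, 0], new.coords[:, 1]] = True
        refined.append(new)
    return refined


def _refine_mask(
    smoothed: np.ndarray,
    mask: NucleusMask,
    claimed: np.ndarray,
    cfg: SegmentationConfig,
    pad: int = 10,
) -> NucleusMask:
    """Re-threshold one accepted nucleus at its own local level.

    The cascade accepts a component at the highest threshold at which it
    passes the gates, which for a dim nucleus can be well above its
    boundary intensity and cuts off an outer ring.  This pass re-draws
    each accepted mask at the midpoint between the nucleus's median
    intensity and the local background median (pixels of other nuclei
    excluded), keeping the 4-connected component that contains the
    provisional mask.  If the refined component fails the area or
    solidity gates (e.g. it bleeds into structured background) the
    provisional mask is kept.
    """
    h, w = smoothed.shape
    min_r, min_c, max_r, max_c = mask.bbox
    r0, c0 = max(min_r - pad, 0), max(min_c - pad, 0)
    r1, c1 = min(max_r + pad + 1, h), min(max_c + pad + 1, w)
    crop = smoothed[r0:r1, c0:c1]
    own = np.zeros(crop.shape, dtype=bool)
    own[mask.coords[:, 0] - r0, mask.coords[:, 1] - c0] = True
    others = claimed[r0:r1, c0:c1]
    bg = crop[~own & ~others]
    if bg.size == 0:
        return mask
    t_mid = 0.5 * (float(np.median(crop[own])) + float(np.median(bg)))
    bw = (crop >= t_mid) & ~others
    lab = label(bw, connectivity=1)
    seed_labels = np.unique(lab[own])
    seed_labels = seed_labels[seed_labels > 0]
    if len(seed_labels) != 1:
        return mask
    comp = ndimage.binary_fill_holes(lab == seed_labels[0]) & ~others
    area = int(comp.sum())
    if not (mask.area_px <= area <= cfg.max_area_px):
        return mask
    props = regionprops(label(comp, connectivity=1))
    if len(props) != 1 or float(props[0].solidity) < cfg.min_solidity:
        return mask
    rr, cc = np.nonzero(comp)
    coords = np.column_stack([rr + r0, cc + c0])
    return NucleusMask(
        nucleus_id=mask.nucleus_id, coords=coords, solidity=float(props[0].solidity)
    )


def segment_hoechst(dna_frame: np.ndarray, cfg: SegmentationConfig) -> list[NucleusMask]:
    """Segment nuclei from a DNA counterstain (Hoechst) channel.

    Identical contract to :func:`segment_cascade`; used in fixed-sample
    mode where nucleus outlines come from the DNA channel and the
    striation signal is measured on a separate channel with these masks.
    """
    return segment_cascade(dna_frame, cfg)


def masks_to_label_image(
    masks: list[NucleusMask], shape: tuple[int, int]
) -> np.ndarray:
    """Render masks as a 16-bit label image (0 = background, id+1 = nucleus)."""
    lab = np.zeros(shape, dtype=np.uint16)
    for m in masks:
        lab[m.coords[:, 0], m.coords[:, 1]] = m.nucleus_id + 1
    return lab
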