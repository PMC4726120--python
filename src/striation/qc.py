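"""Optional quality-control figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .io import FrameStack
from .measure import MSRecord, rotate_image, rotate_mask, _crop_masked, _stripe_region
from .tracking import NucleusTrack

__all__ = ["save_qc_montage"]


def save_qc_montage(
    stack: FrameStack,
    track: NucleusTrack,
    records: list[MSRecord],
    path: str | Path,
    max_panels: int = 8,
) -> None:
    """Montage of one nucleus over time: mask outline, fitted stripe bands
    and the MS value per panel."""
    entries = track.entries[:max_panels]
    fig, axes = plt.subplots(1, len(entries), figsize=(2.2 * len(entries), 2.6))
    if len(entries) == 1:
        axes = [axes]
    by_time = {r.time_min: r for r in records}
    for ax, (f, mask_obj) in zip(axes, entries):
        t = float(stack.times_min[f])
        rec = by_time.get(t)
        sub_img, sub_mask = _crop_masked(stack.frames[f], mask_obj)
        if rec is not None and rec.fit is not None:
            img = rotate_image(sub_img, rec.fit.angle_deg)
            msk = rotate_mask(sub_mask, rec.fit.angle_deg)
            region = _stripe_region(msk, rec.fit)
        else:
            img, msk, region = sub_img, sub_mask, np.zeros_like(sub_mask)
        ax.imshow(img, cmap="gray", interpolation="nearest")
        overlay = np.zeros((*img.shape, 4))
        overlay[region] = (1.0, 0.3, 0.1, 0.35)
        ax.imshow(overlay, interpolation="nearest")
        ax.contour(msk, levels=[0.5], colors="cyan", linewidths=0.6)
        label = f"t={t:g}'"
        if rec is not None and not rec.flagged:
            label += f"\nMS={rec.ms:.2f}"
        ax.set_title(label, fontsize=8)
        ax.axis("off")
    fig.suptitle(f"nucleus {track.nucleus_id}", fontsize=10)
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)
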