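"""End-to-end analysis: stack in, MS table and curve parameters out.

Wires segmentation, tracking, stripe fitting and kinetics for the three
acquisition modes:

* ``live_ddr`` — time-lapse after micro-irradiation; nuclei are
  segmented on the pre-irradiation frame, tracked, and each track is
  summarised by DDR curve parameters;
* ``live_frap`` — time-lapse after stripe bleaching; same pipeline with
  minimum-based amplitude and the FRAP slope windows;
* ``fixed_if`` — fixed immunofluorescence: tracking is disabled, nuclei
  are recognised on a Hoechst (DNA) channel, and MS is measured on the
  signal channel of the single frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import pandas as pd

from .io import FrameStack
from .kinetics import CurveParams, ddr_params, frap_params, series_arrays
from .measure import MSRecord, ms_series
from .segmentation import SegmentationConfig, segment_cascade, segment_hoechst
from .tracking import NucleusTrack, track_nuclei

__all__ = ["AnalysisConfig", "AnalysisResult", "analyze_stack", "params_dataframe"]

_MODES = {"live_ddr", "live_frap", "fixed_if"}


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunables of one analysis run.

    ``lines_per_field`` comes from the acquisition (the low-resolution
    scan that drew the stripes); it implies a nominal gauge
    ``D = image rows / lines_per_field``.  The fit searches integer D in
    [0.5, 1.5] x nominal (unless ``d_range`` overrides) and offsets
    within half a nominal gauge of the column of maximal vertical signal
    (unless ``p_window`` overrides).  ``width_px`` is the user-defined
    stripe width; it is never fitted.
    """

    mode: str = "live_ddr"
    lines_per_field: int = 32
    width_px: int = 3
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    search_radius_px: float = 25.0
    max_carry: int = 2
    local_floor_quantile: float = 0.3
    d_range: tuple[int, int] | None = None
    p_window: int | None = None
    refit_policy: str = "per_frame"

    def __post_init__(self):
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {sorted(_MODES)}, got {self.mode!r}")
        if self.lines_per_field <= 0 or self.width_px <= 0:
            raise ValueError("lines_per_field and width_px must be positive")

    def nominal_gauge(self, image_rows: int) -> int:
        return max(image_rows // self.lines_per_field, self.width_px + 1)

    def effective_d_range(self, image_rows: int) -> tuple[int, int]:
        if self.d_range is not None:
            return self.d_range
        d = self.nominal_gauge(image_rows)
        return (max(self.width_px + 1, round(0.5 * d)), round(1.5 * d))

    def effective_p_window(self, image_rows: int) -> int:
        if self.p_window is not None:
            return self.p_window
        return max(1, round(self.nominal_gauge(image_rows) / 2))


@dataclass
class AnalysisResult:
    """Per-record MS values, tracks, per-nucleus curve parameters and counts."""

    records: list[MSRecord]
    tracks: list[NucleusTrack]
    curve_params: dict[int, CurveParams]
    counts: dict[str, int]

    @property
    def ms_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "field_id": r.field_id,
                "nucleus_id": r.nucleus_id,
                "time_min": r.time_min,
                "ms": r.ms,
                "flagged": r.flagged,
            }
            for r in self.records
        ]
        return pd.DataFrame(
            rows, columns=["field_id", "nucleus_id", "time_min", "ms", "flagged"]
        )


def params_dataframe(curve_params: dict[int, CurveParams]) -> pd.DataFrame:
    """Per-nucleus curve-parameter table (one row per nucleus)."""
    rows = []
    for nid, p in curve_params.items():
        d = asdict(p)
        d["nucleus_id"] = nid
        rows.append(d)
    cols = [
        "nucleus_id",
        "mode",
        "amp",
        "tpeak_min",
        "relax",
        "relax30",
        "n_relax",
        "n_relax30",
        "peaked",
    ]
    return pd.DataFrame(rows, columns=cols)


def analyze_stack(
    stack: FrameStack,
    cfg: AnalysisConfig,
    dna_stack: FrameStack | None = None,
    field_id: int = 0,
) -> AnalysisResult:
    """Run the full striation analysis on one field of view."""
    rows = stack.shape[0]
    d_range = cfg.effective_d_range(rows)
    p_window = cfg.effective_p_window(rows)

    if cfg.mode == "fixed_if":
        if dna_stack is None:
            raise ValueError("fixed_if mode requires a DNA-channel (Hoechst) stack")
        if dna_stack.shape != stack.shape:
            raise ValueError("DNA and signal stacks must have identical frame shape")
        masks = segment_hoechst(dna_stack.frames[0], cfg.segmentation)
        tracks = [NucleusTrack(nucleus_id=m.nucleus_id, entries=[(0, m)]) for m in masks]
    else:
        masks = segment_cascade(stack.frames[0], cfg.segmentation)
        tracks = track_nuclei(
            stack,
            masks,
            search_radius_px=cfg.search_radius_px,
            cfg=cfg.segmentation,
            max_carry=cfg.max_carry,
            local_floor_quantile=cfg.local_floor_quantile,
        )

    records: list[MSRecord] = []
    curve_params: dict[int, CurveParams] = {}
    fit_failures = 0
    for t in tracks:
        recs = ms_series(
            t,
            stack,
            width_px=cfg.width_px,
            d_range=d_range,
            p_window=p_window,
            refit_policy=cfg.refit_policy,
            field_id=field_id,
            # Bleached stripes are darker than their surroundings, so the
            # FRAP fit locks onto the dark bands.
            sense="min" if cfg.mode == "live_frap" else "max",
        )
        fit_failures += sum(r.flagged for r in recs)
        records.extend(recs)
        if cfg.mode in {"live_ddr", "live_frap"}:
            times, values = series_arrays(recs)
            try:
                if cfg.mode == "live_ddr":
                    curve_params[t.nucleus_id] = ddr_params(times, values)
                else:
                    curve_params[t.nucleus_id] = frap_params(times, values)
            except ValueError:
                pass  # fewer than two usable points: no curve summary

    counts = {
        "nuclei_found": len(masks),
        "tracks_lost": sum(1 for t in tracks if t.lost_at is not None),
        "fit_failures": fit_failures,
        "curves_summarised": len(curve_params),
    }
    return AnalysisResult(
        records=records, tracks=tracks, curve_params=curve_params, counts=counts
    )
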