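"""Curve parameters summarising MS time courses (DDR and FRAP).

A DDR curve is the measure of striation of one nucleus as a function of
time after micro-irradiation.  It is summarised by:

* ``Amp`` — the maximum MS over all observed time points (the amount of
  protein recruited to the stripes at the peak);
* ``Tpeak`` — the time in minutes from micro-irradiation until MS
  reaches its maximum (recruitment speed); on ties the earliest time
  point wins;
* ``Relax`` — the slope (MS per minute) of the ordinary-least-squares
  line fitted to MS(t) for t > Tpeak.  When the curve never peaks
  (maximum at the last observed time point, e.g. under repair-blocking
  compounds) the slope is fitted over t > 30 min instead;
* ``Relax30`` — always the slope over t > 30 min.

A FRAP curve (stripes bleached rather than irradiated) uses the minimum
of MS as ``Amp``; Tpeak is not reported because the minimum is reached
immediately after bleaching.  ``Relax30`` is the slope over
1 <= t <= 30 min and ``Relax`` the slope over 1 <= t <= 60 min;
recovery toward 0 gives positive slopes.

Slopes with fewer than two points in their window are undefined (NaN
with ``n_points = 0 or 1``), never silently zero, and are excluded from
group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measure import MSRecord

__all__ = ["CurveParams", "ddr_params", "frap_params", "median_curve", "series_arrays"]


@dataclass(frozen=True)
class CurveParams:
    """Summary parameters of one nucleus's DDR or FRAP curve."""

    mode: str  # "DDR" or "FRAP"
    amp: float
    tpeak_min: float | None
    relax: float
    relax30: float
    n_relax: int
    n_relax30: int
    peaked: bool


def _ols_slope(t: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Least-squares slope and the number of points used; NaN if < 2 points."""
    n = len(t)
    if n < 2:
        return float("nan"), n
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    tc = t - t.mean()
    denom = (tc**2).sum()
    if denom == 0:
        return float("nan"), n
    return float((tc * (y - y.mean())).sum() / denom), n


def series_arrays(records: list[MSRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Times and MS values of the unflagged records, ordered by time."""
    pts = sorted(
        ((r.time_min, r.ms) for r in records if not r.flagged and np.isfinite(r.ms)),
        key=lambda p: p[0],
    )
    if not pts:
        return np.empty(0), np.empty(0)
    t, y = zip(*pts)
    return np.asarray(t, float), np.asarray(y, float)


def ddr_params(
    times_min: np.ndarray,
    ms: np.ndarray,
    relax_fallback_min: float = 30.0,
) -> CurveParams:
    """DDR-curve parameters from a sampled MS(t).

    Only points with t >= 0 (at or after micro-irradiation) enter the
    summary.  Requires at least two such points.
    """
    t = np.asarray(times_min, float)
    y = np.asarray(ms, float)
    keep = (t >= 0) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < 2:
        raise ValueError("need at least two usable time points with t >= 0")
    order = np.argsort(t)
    t, y = t[order], y[order]

    i_max = int(np.argmax(y))  # first occurrence = earliest time on ties
    amp = float(y[i_max])
    tpeak = float(t[i_max])
    peaked = i_max < len(t) - 1

    if peaked:
        sel = t > tpeak
    else:
        sel = t > relax_fallback_min
    relax, n_relax = _ols_slope(t[sel], y[sel])
    sel30 = t > relax_fallback_min
    relax30, n_relax30 = _ols_slope(t[sel30], y[sel30])
    return CurveParams(
        mode="DDR",
        amp=amp,
        tpeak_min=tpeak,
        relax=relax,
        relax30=relax30,
        n_relax=n_relax,
        n_relax30=n_relax30,
        peaked=peaked,
    )


def frap_params(times_min: np.ndarray, ms: np.ndarray) -> CurveParams:
    """FRAP-curve parameters: minimum-based amplitude and recovery slopes."""
    t = np.asarray(times_min, float)
    y = np.asarray(ms, float)
    keep = np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < 2:
        raise ValueError("need at least two usable time points")
    order = np.argsort(t)
    t, y = t[order], y[order]

    amp = float(y.min())
    sel30 = (t >= 1.0) & (t <= 30.0)
    sel60 = (t >= 1.0) & (t <= 60.0)
    relax30, n_relax30 = _ols_slope(t[sel30], y[sel30])
    relax, n_relax = _ols_slope(t[sel60], y[sel60])
    return CurveParams(
        mode="FRAP",
        amp=amp,
        tpeak_min=None,
        relax=relax,
        relax30=relax30,
        n_relax=n_relax,
        n_relax30=n_relax30,
        peaked=False,
    )


def median_curve(
    series: list[tuple[np.ndarray, np.ndarray]],
    timepoints: np.ndarray,
    atol_min: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-timepoint median MS over a collection of nuclei.

    Each series is a (times, values) pair sampled at (a subset of) the
    shared timepoints; missing or non-finite values are simply absent
    from that timepoint's median.  Returns ``(medians, n)`` with NaN
    where no value is available.  Even counts use the midpoint
    convention.
    """
    timepoints = np.asarray(timepoints, float)
    medians = np.full(len(timepoints), np.nan)
    counts = np.zeros(len(timepoints), dtype=int)
    for i, tp in enumerate(timepoints):
        vals = []
        for t, y in series:
            hit = np.nonzero(np.abs(np.asarray(t, float) - tp) <= atol_min)[0]
            if len(hit) and np.isfinite(y[hit[0]]):
                vals.append(float(y[hit[0]]))
        counts[i] = len(vals)
        if vals:
            medians[i] = float(np.median(vals))
    return medians, counts
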