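"""Group comparison of per-nucleus curve parameters.

Treated and mock-treated populations are compared per parameter (Amp,
Tpeak, Relax, Relax30) with the Kruskal-Wallis rank test at a fixed
significance level (default 0.05), without multiple-testing correction;
the guard against false positives is replicate concordance: when two
biological replicates are available, an effect counts only if both
replicates are independently significant in the same direction.  The
effect direction is the sign of (treated median - mock median), coded
``up`` / ``down`` / ``ns`` as in a screen summary table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "kruskal_wallis",
    "compare_to_mock",
    "concordant",
    "summary_table",
    "PARAMETERS",
]

PARAMETERS = ("amp", "tpeak_min", "relax", "relax30")


@dataclass(frozen=True)
class GroupComparison:
    """Kruskal-Wallis comparison of one curve parameter between groups."""

    parameter: str
    h_stat: float
    p_value: float
    significant: bool
    direction: str  # "up", "down" or "ns"
    n_treated: int
    n_mock: int


def kruskal_wallis(
    *groups: Sequence[float],
    method: str = "chi2",
    n_permutations: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value for two or more groups.

    H is computed on mid-ranks with the standard tie correction.  With
    ``method="chi2"`` (the default, appropriate for >= 5 values per
    group) the p-value uses the chi-square approximation with k - 1
    degrees of freedom; ``method="permutation"`` estimates it by
    shuffling group labels, for very small samples.  All pooled values
    identical is the fully tied degenerate case: H = 0, p = 1.
    """
    if method not in {"chi2", "permutation"}:
        raise ValueError(f"method must be 'chi2' or 'permutation', got {method!r}")
    cleaned = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        a = a[np.isfinite(a)]
        if len(a) == 0:
            raise ValueError("each group must contain at least one finite value")
        cleaned.append(a)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    total = sum(len(a) for a in cleaned)
    if total < 3:
        raise ValueError("need at least three values in total")
    pooled = np.concatenate(cleaned)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*cleaned)
    if method == "permutation":
        sizes = [len(a) for a in cleaned]
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = np.split(perm, np.cumsum(sizes)[:-1])
            if all(np.all(part == part[0]) for part in parts) and np.all(
                perm == perm[0]
            ):
                h_perm = 0.0
            else:
                h_perm, _ = sps.kruskal(*parts)
            count += h_perm >= h - 1e-12
        p = (count + 1) / (n_permutations + 1)
    return float(h), float(p)


def compare_to_mock(
    treated: Mapping[str, Sequence[float]] | pd.DataFrame,
    mock: Mapping[str, Sequence[float]] | pd.DataFrame,
    alpha: float = 0.05,
    min_cells: int = 100,
    parameters: Sequence[str] = PARAMETERS,
) -> list[GroupComparison]:
    """Compare each curve parameter of a treated sample against mock.

    ``treated`` and ``mock`` map parameter names to per-nucleus values
    (a DataFrame with those columns works); technical duplicates should
    be pooled by the caller before the comparison.  NaN values
    (undefined slopes) are dropped per parameter.  Groups smaller than
    ``min_cells`` raise, mirroring the practice of scoring a minimum
    number of cells per experiment; pass a smaller ``min_cells``
    explicitly for exploratory use.
    """
    if mock is None:
        raise ValueError("a mock-treated group is required")
    out = []
    for param in parameters:
        tv = np.asarray(pd.Series(treated[param]), dtype=float)
        mv = np.asarray(pd.Series(mock[param]), dtype=float)
        tv = tv[np.isfinite(tv)]
        mv = mv[np.isfinite(mv)]
        if len(tv) < min_cells or len(mv) < min_cells:
            raise ValueError(
                f"parameter {param!r}: need >= {min_cells} cells per group "
                f"(got {len(tv)} treated, {len(mv)} mock)"
            )
        h, p = kruskal_wallis(tv, mv)
        significant = p < alpha
        if significant:
            direction = "up" if np.median(tv) > np.median(mv) else "down"
        else:
            direction = "ns"
        out.append(
            GroupComparison(
                parameter=param,
                h_stat=h,
                p_value=p,
                significant=significant,
                direction=direction,
                n_treated=len(tv),
                n_mock=len(mv),
            )
        )
    return out


def concordant(
    replicates: Sequence[Sequence[GroupComparison]],
) -> list[GroupComparison]:
    """Combine biological replicates by the concordance rule.

    A parameter is reported significant only when every replicate is
    independently significant with the same direction; otherwise it is
    coded ``ns``.  The reported H and p are those of the first
    replicate (the rule is a veto, not a meta-analysis).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    by_param = []
    first = replicates[0]
    for i, comp in enumerate(first):
        others = [rep[i] for rep in replicates]
        if any(o.parameter != comp.parameter for o in others):
            raise ValueError("replicates must list parameters in the same order")
        ok = all(o.significant for o in others) and len(
            {o.direction for o in others}
        ) == 1
        by_param.append(
            GroupComparison(
                parameter=comp.parameter,
                h_stat=comp.h_stat,
                p_value=comp.p_value,
                significant=ok,
                direction=comp.direction if ok else "ns",
                n_treated=comp.n_treated,
                n_mock=comp.n_mock,
            )
        )
    return by_param


def summary_table(
    comparisons_by_compound: Mapping[str, Sequence[GroupComparison]],
) -> pd.DataFrame:
    """Screen-style summary: rows = compounds, columns = parameters,
    cells in {up, down, ns}."""
    rows = {}
    for compound, comps in comparisons_by_compound.items():
        rows[compound] = {c.parameter: c.direction for c in comps}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("compound")
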