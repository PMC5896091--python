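"""Stratified Spearman correlation with Benjamini-Hochberg FDR control.

The analysis surface: correlate any two variable families (gene expression,
motif/kataegis abundance measures, mutation counts, drug log10(IC50)
columns) across cell lines, either pooled over all cancer categories
("pan-cancer") or within each category separately, keeping only strata with
at least ``min_n`` pairwise-complete cell lines for a given pair.  All raw
p-values of one family are adjusted jointly with the BH step-up procedure;
the realized family size ``N_tests`` (the number of tests actually
computed) is reported with every result so alternative family accountings
can be audited.

Spearman's rho is computed on tie-averaged ranks.  The two-sided p-value
comes from the t statistic ``t = rho * sqrt((n-2) / (1-rho^2))`` with n-2
degrees of freedom; a perfect correlation (|rho| = 1), where the t
approximation degenerates, is assigned the exact two-sided permutation tail
``2 / n!`` instead.  Pairs with fewer than three complete observations or
with zero rank variance are untestable: they are excluded from the family
(not assigned p = 1, which would silently inflate the family size) and
logged.

The headline significance filter keeps results with ``p_adj < 0.05`` and
``|rho| > 0.25``, both strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"


@dataclass(frozen=True)
class CorrelationResult:
    """One Spearman test: variable pair, stratum, n, rho, raw and adjusted p."""

    left: str
    right: str
    stratum: str
    n: int
    rho: float
    p: float
    p_adj: float | None = None
    family_id: str = ""
    n_tests: int | None = None


@dataclass
class TestFamily:
    """One BH family: left x right variable sets over a set of strata.

    ``strata`` is a list of category labels, or ``[PAN_CANCER]`` for the
    pooled analysis.  ``min_n`` is the minimum pairwise-complete sample size
    for a (pair, stratum) combination to enter the family.
    """

    family_id: str
    left: Sequence[str]
    right: Sequence[str]
    strata: Sequence[str] = field(default_factory=lambda: [PAN_CANCER])
    min_n: int = 5

    def __post_init__(self) -> None:
        if self.min_n < 3:
            raise ValueError(f"min_n must be >= 3, got {self.min_n}")


class UntestablePair(ValueError):
    """Too few complete pairs or zero rank variance."""


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Incomplete pairs (either value missing) are dropped first.  Raises
    :class:`UntestablePair` when fewer than 3 complete pairs remain or one
    vector has zero rank variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = xa.size
    if n < 3:
        raise UntestablePair(f"only {n} complete pairs (need >= 3)")
    rx = stats.rankdata(xa)  # average ranks for ties
    ry = stats.rankdata(ya)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0.0:
        raise UntestablePair("zero rank variance")
    rho = float(rx_c @ ry_c) / denom
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        # exact two-sided permutation tail: only the two extreme orderings
        p = 2.0 / math.factorial(n)
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, min(p, 1.0)


def bh_adjust(pvals: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    With p sorted ascending, ``q_(i) = min_{j >= i} (m * p_(j) / j)`` capped
    at 1, mapped back to input order.  ``m`` defaults to ``len(pvals)`` (the
    family is the set of computed tests).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0.0 or np.nanmax(p) > 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.isnan(p).any():
        raise ValueError("p-values must not be NaN")
    if m is None:
        m = p.size
    elif m < p.size:
        raise ValueError(f"family size m={m} smaller than number of tests {p.size}")
    if p.size == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty_like(q)
    out[order] = q
    return out


def run_family(
    family: TestFamily,
    left_table: pd.DataFrame,
    right_table: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
) -> list[CorrelationResult]:
    """Run every (left, right, stratum) Spearman test of a family, BH-adjusted.

    ``left_table`` and ``right_table`` are cell-line-indexed matrices.  For a
    non-pan-cancer stratum, eligible cell lines are those the
    ``category_map`` assigns to that category.  A (pair, stratum) test enters
    the family only when at least ``family.min_n`` pairwise-complete cell
    lines exist; untestable combinations are logged and excluded from the
    family size.  Output ordering is deterministic: (stratum, left, right).
    """
    missing_left = [v for v in family.left if v not in left_table.columns]
    missing_right = [v for v in family.right if v not in right_table.columns]
    if missing_left or missing_right:
        raise KeyError(
            f"unresolvable variables: left={missing_left}, right={missing_right}"
        )
    if not family.left or not family.right or not family.strata:
        logger.warning("family %s is empty; no tests run", family.family_id)
        return []

    shared = left_table.index.intersection(right_table.index)
    raw: list[CorrelationResult] = []
    for stratum in family.strata:
        if stratum == PAN_CANCER:
            cells = shared
        else:
            if category_map is None:
                raise ValueError(
                    f"stratum {stratum!r} requested but no category map given"
                )
            cells = pd.Index(
                [c for c in shared if category_map.get(c) == stratum]
            )
        if len(cells) < family.min_n:
            logger.info(
                "stratum %s: only %d shared cell lines (< %d), omitted",
                stratum,
                len(cells),
                family.min_n,
            )
            continue
        lsub = left_table.loc[cells, list(family.left)]
        rsub = right_table.loc[cells, list(family.right)]
        for lv in family.left:
            for rv in family.right:
                x = lsub[lv].to_numpy(dtype=float)
                y = rsub[rv].to_numpy(dtype=float)
                n = int((~(np.isnan(x) | np.isnan(y))).sum())
                if n < family.min_n:
                    logger.info(
                        "pair (%s, %s) in %s: n=%d < %d, omitted",
                        lv, rv, stratum, n, family.min_n,
                    )
                    continue
                try:
                    rho, p = spearman(x, y)
                except UntestablePair as exc:
                    logger.info(
                        "pair (%s, %s) in %s untestable: %s", lv, rv, stratum, exc
                    )
                    continue
                raw.append(
                    CorrelationResult(
                        left=lv, right=rv, stratum=stratum, n=n, rho=rho, p=p,
                        family_id=family.family_id,
                    )
                )
    if not raw:
        logger.warning("family %s produced no testable pairs", family.family_id)
        return []
    n_tests = len(raw)
    adjusted = bh_adjust([r.p for r in raw])
    return [
        CorrelationResult(
            left=r.left, right=r.right, stratum=r.stratum, n=r.n, rho=r.rho,
            p=r.p, p_adj=float(q), family_id=r.family_id, n_tests=n_tests,
        )
        for r, q in zip(raw, adjusted)
    ]


def significant(
    results: Sequence[CorrelationResult],
    alpha: float = 0.05,
    rho_min: float = 0.25,
) -> list[CorrelationResult]:
    """The headline filter: ``p_adj < alpha`` and ``|rho| > rho_min``, strict.

    Results must carry adjusted p-values.  Output sorted by p_adj ascending,
    then |rho| descending.
    """
    for r in results:
        if r.p_adj is None:
            raise ValueError("results must be BH-adjusted before filtering")
    kept = [r for r in results if r.p_adj < alpha and abs(r.rho) > rho_min]
    kept.sort(key=lambda r: (r.p_adj, -abs(r.rho)))
    return kept


def results_to_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "left": r.left,
                "right": r.right,
                "stratum": r.stratum,
                "n": r.n,
                "rho": r.rho,
                "p": r.p,
                "p_adj": r.p_adj,
                "family_id": r.family_id,
                "N_tests": r.n_tests,
            }
            for r in results
        ],
        columns=[
            "left", "right", "stratum", "n", "rho", "p", "p_adj",
            "family_id", "N_tests",
        ],
    )


def write_results_tsv(
    results: Sequence[CorrelationResult], path: str | Path
) -> None:
    results_to_frame(results).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )
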