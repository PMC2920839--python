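"""Synaptonemal-complex length metrics.

Bivalents within each spread nucleus are rank-ordered by SC length from 1
(largest) to 19 (smallest) — rank is a size proxy, never a chromosome
identity claim — then pooled into groups of similarly sized chromosomes for
summaries and between-genotype comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import FocusTable, Meiocyte, StatResult, UNRANKED, group_into_meiocytes

logger = logging.getLogger("meioco")


@dataclass(frozen=True)
class SizeGroupScheme:
    """Ordered, disjoint rank intervals jointly covering 1..19."""

    intervals: tuple[tuple[int, int], ...] = ((1, 2), (3, 5), (6, 11), (12, 16), (17, 19))

    def __post_init__(self) -> None:
        covered = []
        for lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"interval {lo}-{hi} is reversed")
            covered.extend(range(lo, hi + 1))
        if covered != list(range(1, 20)):
            raise ValueError("intervals must be ordered, disjoint and cover ranks 1..19")

    def label(self, interval: tuple[int, int]) -> str:
        lo, hi = interval
        return f"{lo}-{hi}"

    @property
    def labels(self) -> list[str]:
        return [self.label(iv) for iv in self.intervals]

    def group_of(self, rank: int) -> str:
        for lo, hi in self.intervals:
            if lo <= rank <= hi:
                return self.label((lo, hi))
        raise ValueError(f"rank {rank} outside 1..19")

    def ranks_in(self, label: str) -> list[int]:
        for iv in self.intervals:
            if self.label(iv) == label:
                return list(range(iv[0], iv[1] + 1))
        raise ValueError(f"unknown group label {label!r}")


DEFAULT_SCHEME = SizeGroupScheme()


def rank_bivalents(cell: Meiocyte) -> Meiocyte:
    """Assign ranks 1..k by descending SC length (stable: ties keep input order)."""
    if not cell.bivalents:
        raise ValueError(f"cell {cell.cell_id} has no bivalents to rank")
    if len(cell.bivalents) < 19:
        logger.warning("cell %s has only %d bivalents; ranking over those present",
                       cell.cell_id, len(cell.bivalents))
    order = sorted(range(len(cell.bivalents)), key=lambda i: -cell.bivalents[i].sc_length)
    ranked = list(cell.bivalents)
    for rank_minus_1, idx in enumerate(order):
        ranked[idx] = replace(cell.bivalents[idx], chromosome_rank=rank_minus_1 + 1)
    return Meiocyte(cell.cell_id, cell.genotype, cell.stage, ranked)


def ensure_ranked(cells: list[Meiocyte]) -> list[Meiocyte]:
    """Rank any cell that still carries unranked bivalents."""
    return [
        rank_bivalents(c) if any(b.chromosome_rank == UNRANKED for b in c.bivalents) else c
        for c in cells
    ]


def total_autosomal_sc(cell: Meiocyte) -> float:
    """Sum of autosomal SC lengths (µm) in the cell."""
    if not cell.bivalents:
        logger.warning("cell %s is empty; total SC length is 0", cell.cell_id)
        return 0.0
    return float(sum(b.sc_length for b in cell.bivalents))


def _length_frame(dataset: FocusTable) -> pd.DataFrame:
    """One row per (cell, bivalent): genotype, rank, SC length, completeness."""
    cells = ensure_ranked(group_into_meiocytes(dataset))
    rows = []
    for cell in cells:
        complete = len(cell.bivalents) == 19
        for b in cell.bivalents:
            rows.append(dict(cell_id=cell.cell_id, genotype=cell.genotype,
                             rank=b.chromosome_rank, sc_length=b.sc_length, complete=complete))
    return pd.DataFrame(rows)


def sc_length_summary(dataset: FocusTable, scheme: SizeGroupScheme = DEFAULT_SCHEME) -> pd.DataFrame:
    """Per (genotype, size group): mean ± SD SC length, N, and percent of total.

    percent_of_total is the mean SC length per chromosome in the group
    divided by the mean per-cell total SC length, × 100.  Cells with an
    incomplete bivalent complement contribute to the per-group means but are
    excluded from the per-cell totals.
    """
    lf = _length_frame(dataset)
    out = []
    for genotype, gdf in lf.groupby("genotype", sort=False):
        totals = gdf[gdf["complete"]].groupby("cell_id")["sc_length"].sum()
        n_excluded = gdf.loc[~gdf["complete"], "cell_id"].nunique()
        if n_excluded:
            logger.warning("%s: %d incomplete cell(s) excluded from per-cell totals",
                           genotype, n_excluded)
        if len(totals) == 0:
            logger.warning("%s: no complete cells; per-cell totals fall back to all cells",
                           genotype)
            totals = gdf.groupby("cell_id")["sc_length"].sum()
        mean_total = totals.mean() if len(totals) else np.nan
        gdf = gdf.assign(group=gdf["rank"].map(scheme.group_of))
        for label in scheme.labels:
            sub = gdf[gdf["group"] == label]["sc_length"]
            if sub.empty:
                logger.warning("%s: size group %s has no chromosomes; omitted", genotype, label)
                continue
            out.append(dict(
                genotype=genotype, group=label,
                mean_sc_length_um=sub.mean(),
                sd_sc_length_um=sub.std(ddof=1) if len(sub) > 1 else 0.0,
                n_chromosomes=len(sub),
                percent_of_total=100.0 * sub.mean() / mean_total,
            ))
    return pd.DataFrame(out)


def percent_of_total(group_mean_um: float, mean_total_um: float) -> float:
    """Mean SC length per chromosome ÷ mean per-cell total × 100."""
    if mean_total_um <= 0:
        raise ValueError("mean per-cell total must be positive")
    return 100.0 * group_mean_um / mean_total_um


def compare_group_lengths(
    a: FocusTable, b: FocusTable, scheme: SizeGroupScheme = DEFAULT_SCHEME, welch: bool = True,
) -> dict[str, StatResult]:
    """Two-sided t tests per size group (per-chromosome units) plus a
    whole-genotype per-cell total-length test.  Welch by default."""
    fa, fb = _length_frame(a), _length_frame(b)
    results: dict[str, StatResult] = {}
    for label in scheme.labels:
        ranks = scheme.ranks_in(label)
        xa = fa[fa["rank"].isin(ranks)]["sc_length"].to_numpy()
        xb = fb[fb["rank"].isin(ranks)]["sc_length"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            results[label] = StatResult("t-test", float("nan"), float("nan"),
                                        n=(len(xa), len(xb)), extra={"undefined": True})
            continue
        t = stats.ttest_ind(xa, xb, equal_var=not welch)
        results[label] = StatResult("t-test", float(t.statistic), float(t.pvalue),
                                    df=float(t.df), n=(len(xa), len(xb)))
    ta = fa[fa["complete"]].groupby("cell_id")["sc_length"].sum().to_numpy()
    tb = fb[fb["complete"]].groupby("cell_id")["sc_length"].sum().to_numpy()
    if len(ta) >= 2 and len(tb) >= 2:
        t = stats.ttest_ind(ta, tb, equal_var=not welch)
        results["total"] = StatResult("t-test", float(t.statistic), float(t.pvalue),
                                      df=float(t.df), n=(len(ta), len(tb)))
    else:
        results["total"] = StatResult("t-test", float("nan"), float("nan"),
                                      n=(len(ta), len(tb)), extra={"undefined": True})
    return results
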