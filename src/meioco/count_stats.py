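"""Focus-count summaries and contingency/rank statistics.

Covers the statistics used on focus counts and categorical cytology:
mean ± SD summaries, fold changes with explicit rounding conventions,
Fisher's exact test (two-sided by the probability-mass convention), the
G (log-likelihood ratio) test, Mann–Whitney with an exact tie-aware null
for small samples, per-bivalent focus-multiplicity distributions, and
two-proportion rate comparisons.  Counts quoted only as "x% of N" are
recovered with :func:`reconstruct_count`, which refuses any reconstruction
that fails to reproduce the printed percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_types import FocusTable, StatResult, group_into_meiocytes


@dataclass
class CountSummary:
    genotype: str
    stage: str
    marker: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def summarize_focus_counts(
    counts, genotype: str = "", stage: str = "", marker: str = ""
) -> CountSummary:
    """Mean, sample SD (n−1 denominator) and n of per-cell focus counts."""
    x = np.asarray(counts, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one count")
    sd = float(x.std(ddof=1)) if len(x) > 1 else 0.0
    return CountSummary(genotype, stage, marker, float(x.mean()), sd, len(x))


ROUNDINGS = ("1-decimal", "nearest-integer", "nearest-ten", "none")


def _round_by(value: float, rounding: str) -> float:
    if rounding == "1-decimal":
        return round(value, 1)
    if rounding == "nearest-integer":
        return float(round(value))
    if rounding == "nearest-ten":
        return float(round(value / 10.0) * 10)
    if rounding == "none":
        return value
    raise ValueError(f"unknown rounding convention {rounding!r}; use one of {ROUNDINGS}")


@dataclass
class FoldChange:
    numerator: float
    denominator: float
    rounding: str = "1-decimal"

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("fold change needs a positive denominator")
        if self.rounding not in ROUNDINGS:
            raise ValueError(f"unknown rounding convention {self.rounding!r}; use one of {ROUNDINGS}")

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator

    @property
    def rounded(self) -> float:
        return _round_by(self.ratio, self.rounding)


def fold_change(a, b, rounding: str = "1-decimal") -> FoldChange:
    """Ratio of two means (CountSummary or plain numbers), rounded per convention."""
    num = a.mean if isinstance(a, CountSummary) else float(a)
    den = b.mean if isinstance(b, CountSummary) else float(b)
    return FoldChange(num, den, rounding)


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test on a 2×2 table.

    The two-sided p sums hypergeometric probabilities of all tables (with
    the observed margins) no more probable than the observed one.  A zero
    margin makes the table degenerate (p = 1, flagged).
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return StatResult("fisher-exact", float("nan"), 1.0, n=(int(t[0].sum()), int(t[1].sum())),
                          extra={"degenerate": True})
    odds, p = stats.fisher_exact(t, alternative="two-sided")
    _, p_greater = stats.fisher_exact(t, alternative="greater")
    _, p_less = stats.fisher_exact(t, alternative="less")
    return StatResult(
        "fisher-exact", float(odds), float(p),
        n=(int(t[0].sum()), int(t[1].sum())),
        extra={"odds_ratio": float(odds),
               "p_one_sided_greater": float(p_greater),
               "p_one_sided_less": float(p_less)},
    )


def g_test(table, williams: bool = False) -> StatResult:
    """Log-likelihood ratio (G) test of independence on an r×c table.

    G = 2 Σ O ln(O/E) with independence expecteds and df = (r−1)(c−1);
    p from the χ² distribution.  Optional Williams small-sample correction.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("need an r x c table of non-negative counts")
    N = obs.sum()
    row, col = obs.sum(axis=1), obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero expected cell (empty row/column); pool categories first")
    expected = np.outer(row, col) / N
    m = obs > 0
    G = 2.0 * float((obs[m] * np.log(obs[m] / expected[m])).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if williams:
        q = 1.0 + ((N / row).sum() - 1.0) * ((N / col).sum() - 1.0) / (6.0 * N * df)
        G /= q
    p = float(stats.chi2.sf(G, df))
    return StatResult("g-test", G, p, df=float(df), extra={"williams": williams})


def _rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Exact permutation distribution of the sample-1 doubled-rank sum.

    Dynamic programming over pooled items: ways[k, s] = number of size-k
    subsets with doubled-rank sum s.  Tie-aware because midranks enter the
    ranks directly.
    """
    max_sum = int(doubled_ranks.sum())
    ways = np.zeros((n1 + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in (int(v) for v in doubled_ranks):
        # k runs downward so each pooled item enters a subset at most once
        for k in range(n1, 0, -1):
            if r:
                ways[k, r:] += ways[k - 1, :-r]
            else:
                ways[k] += ways[k - 1]
    return ways[n1]


def mann_whitney(a, b, method: str = "auto") -> StatResult:
    """Two-sided Mann–Whitney U test.

    Exact tie-aware permutation null (computed by rank-sum dynamic
    programming) when n1·n2 ≤ 400; otherwise the tie-corrected normal
    approximation with continuity correction.  ``method`` forces
    "exact"/"asymptotic".  The reported statistic is U of the first sample.
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if method == "exact" or (method == "auto" and n1 * n2 <= 400):
        doubled = np.round(2.0 * ranks).astype(int)
        dist = _rank_sum_distribution(doubled, n1)
        total = dist.sum()
        s_obs = int(round(2.0 * r1))
        p_le = dist[: s_obs + 1].sum() / total
        p_ge = dist[s_obs:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        mode = "exact"
    else:
        mu = n1 * n2 / 2.0
        N = n1 + n2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1.0))
        var = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
        if var == 0:
            return StatResult("mann-whitney", u1, float("nan"), n=(n1, n2),
                              extra={"degenerate": True, "mode": "asymptotic"})
        z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
        p = min(1.0, 2.0 * float(stats.norm.sf(max(z, 0.0))))
        mode = "asymptotic"
    return StatResult("mann-whitney", float(u1), float(p), n=(n1, n2), extra={"mode": mode})


def focus_number_distribution(
    dataset: FocusTable, marker: str = "MLH1", max_class: int = 3
) -> tuple[dict[int, float], int]:
    """Fractions of bivalents with 0, 1, 2, ..., max_class+ foci.

    Zero-focus bivalent rows count as bivalents.  Returns (fractions, N);
    the top class pools ``max_class`` and above.
    """
    cells = group_into_meiocytes(dataset.subset(marker=marker))
    counts = [min(b.n_foci, max_class) for cell in cells for b in cell.bivalents]
    N = len(counts)
    if N == 0:
        return {}, 0
    fractions = {c: counts.count(c) / N for c in range(max_class + 1)}
    return fractions, N


@dataclass
class RateComparison:
    rate_a: float  # percent, one decimal
    rate_b: float
    fold: float
    fold_raw: float
    fisher: StatResult


def rate_comparison(
    events_a: int, n_a: int, events_b: int, n_b: int, rounding: str = "1-decimal"
) -> RateComparison:
    """Two proportions, their fold ratio and a Fisher test on the 2×2 table.

    The fold is the ratio of the one-decimal percent rates (the convention
    used when rates are reported to one decimal); the unrounded ratio of raw
    proportions is also kept.  A zero denominator rate yields +inf with the
    achievable lower bound reported via ``fold_raw``.
    """
    if events_a > n_a or events_b > n_b or min(events_a, events_b, n_a, n_b) < 0:
        raise ValueError("need 0 <= events <= n on both sides")
    rate_a = round(100.0 * events_a / n_a, 1)
    rate_b = round(100.0 * events_b / n_b, 1)
    if rate_b == 0:
        fold = math.inf
        fold_raw = math.inf if events_b == 0 else (events_a / n_a) / (events_b / n_b)
    else:
        fold = _round_by(rate_a / rate_b, rounding)
        fold_raw = (events_a / n_a) / (events_b / n_b) if events_b else math.inf
    fisher = fisher_exact_2x2([[events_a, n_a - events_a], [events_b, n_b - events_b]])
    return RateComparison(rate_a, rate_b, fold, fold_raw, fisher)


class ReconstructionError(ValueError):
    """A percent-derived count failed to reproduce the printed percentage."""


def reconstruct_count(percent: float, n: int, decimals: int = 1) -> int:
    """Recover the integer count behind a printed "percent of N".

    The reconstruction round(percent·N/100) must round-trip to the printed
    percent at its printed precision, otherwise it is refused.
    """
    count = round(percent * n / 100.0)
    back = round(100.0 * count / n, decimals)
    if back != round(percent, decimals):
        raise ReconstructionError(
            f"{percent}% of {n} -> count {count} reproduces {back}%, not {percent}%"
        )
    return count
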