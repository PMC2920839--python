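"""Crossover positional distributions along the centromere→telomere axis.

MLH1 focus positions are expressed as percent of SC length from the
centromeric end and stratified by chromosome size group and by focus
multiplicity class (bivalents with exactly one or exactly two foci; rare
three-focus bivalents are excluded).  Region-occupancy fractions use closed
intervals on positions pre-rounded to 0.1%, so printed one-decimal
percentages reproduce exactly.

Distribution shapes are compared with the Anderson–Darling k-sample test
(Scholz–Stephens rank statistic, midrank version for ties).  The asymptotic
p-value interpolates the published standardized critical values on the
log-odds scale without capping; a permutation p-value is available as the
ground-truth reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_types import FocusTable, StatResult, group_into_meiocytes
from .sc_metrics import DEFAULT_SCHEME, SizeGroupScheme, ensure_ranked
from .count_stats import fisher_exact_2x2

logger = logging.getLogger("meioco")


@dataclass(frozen=True)
class RegionSpec:
    """Named closed intervals on the percent-of-SC axis."""

    regions: tuple[tuple[str, float, float], ...] = (
        ("proximal", 0.0, 15.0),
        ("central", 40.0, 75.0),
        ("distal", 80.0, 95.0),
    )

    def __post_init__(self) -> None:
        for name, lo, hi in self.regions:
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError(f"region {name}: need 0 <= lo < hi <= 100")

    def bounds(self, name: str) -> tuple[float, float]:
        for n, lo, hi in self.regions:
            if n == name:
                return lo, hi
        raise KeyError(f"unknown region {name!r}")


DEFAULT_REGIONS = RegionSpec()


def position_table(
    dataset: FocusTable,
    scheme: SizeGroupScheme = DEFAULT_SCHEME,
    marker: str = "MLH1",
) -> pd.DataFrame:
    """One row per focus: position (% SC), size group, focus class (1|2), genotype.

    Bivalents with three or more foci are dropped; the dropped-bivalent
    count is logged and attached as ``df.attrs['n_multi_focus_dropped']``.
    """
    cells = ensure_ranked(group_into_meiocytes(dataset.subset(marker=marker)))
    rows = []
    n_dropped = 0
    for cell in cells:
        for biv in cell.bivalents:
            if biv.n_foci == 0:
                continue
            if biv.n_foci > 2:
                n_dropped += 1
                continue
            for p in biv.focus_positions:
                rows.append(dict(
                    position_pct=100.0 * p,
                    group=scheme.group_of(biv.chromosome_rank),
                    rank=biv.chromosome_rank,
                    focus_class=biv.n_foci,
                    genotype=cell.genotype,
                    cell_id=cell.cell_id,
                ))
    if n_dropped:
        logger.info("dropped %d bivalent(s) with >2 foci from positional analysis", n_dropped)
    df = pd.DataFrame(rows, columns=["position_pct", "group", "rank", "focus_class",
                                     "genotype", "cell_id"])
    df.attrs["n_multi_focus_dropped"] = n_dropped
    return df


@dataclass
class RegionFraction:
    region: str
    count: int
    total: int

    @property
    def fraction(self) -> float:
        return self.count / self.total

    @property
    def percent(self) -> float:
        """Percent rounded to one decimal, for report parity."""
        return round(100.0 * self.count / self.total, 1)


def region_fraction(
    positions, region: str, spec: RegionSpec = DEFAULT_REGIONS
) -> RegionFraction:
    """Fraction of foci whose (0.1%-rounded) position falls in the closed region."""
    pos = positions["position_pct"].to_numpy() if isinstance(positions, pd.DataFrame) \
        else np.asarray(positions, dtype=float)
    if len(pos) == 0:
        raise ValueError("empty position table: region fraction undefined")
    lo, hi = spec.bounds(region)
    rounded = np.round(pos, 1)
    count = int(((rounded >= lo) & (rounded <= hi)).sum())
    return RegionFraction(region, count, len(pos))


@dataclass
class OccupancyFold:
    fold: float
    fraction_a: float
    fraction_b: float
    fisher: StatResult


def central_occupancy_fold(
    a: pd.DataFrame,
    b: pd.DataFrame,
    focus_class: int = 2,
    groups: tuple[str, ...] = ("1-2", "3-5"),
    region: str = "central",
    spec: RegionSpec = DEFAULT_REGIONS,
) -> OccupancyFold:
    """Ratio of central-region occupancy between genotypes (a ÷ b) with a
    2×2 Fisher test on (in-region vs not) × genotype.

    Defaults target the two-focus class on the largest chromosomes (size
    ranks 1–5), where relaxed interference shows up as in-filling of the
    normally empty chromosome middle.
    """
    def restrict(df):
        return df[(df["focus_class"] == focus_class) & (df["group"].isin(groups))]

    ra = region_fraction(restrict(a), region, spec)
    rb = region_fraction(restrict(b), region, spec)
    fold = math.inf if rb.fraction == 0 else ra.fraction / rb.fraction
    fisher = fisher_exact_2x2([[ra.count, ra.total - ra.count],
                               [rb.count, rb.total - rb.count]])
    return OccupancyFold(fold=fold, fraction_a=ra.fraction, fraction_b=rb.fraction, fisher=fisher)


def kde_profile(
    positions, bandwidth: float | None = None, grid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of positions on [0, 100], boundary-reflected.

    Mass falling outside the axis is reflected back at 0 and 100, so the
    profile integrates to 1 over the axis.  Bandwidth defaults to
    Silverman's rule; pass a value in % SC to override.
    """
    pos = positions["position_pct"].to_numpy() if isinstance(positions, pd.DataFrame) \
        else np.asarray(positions, dtype=float)
    if len(pos) < 5:
        raise ValueError("need at least 5 positions for a KDE; use a histogram instead")
    if grid is None:
        grid = np.arange(0.0, 100.0 + 1e-9, 0.5)
    sd = pos.std(ddof=1)
    if sd == 0:
        raise ValueError("positions are all identical; KDE bandwidth undefined")
    bw_method = "silverman" if bandwidth is None else bandwidth / sd
    kde = stats.gaussian_kde(pos, bw_method=bw_method)
    density = kde(grid) + kde(-grid) + kde(200.0 - grid)
    return grid, density


# ---------------------------------------------------------------------------
# Anderson–Darling k-sample test (Scholz & Stephens rank statistic)

def ad_k_statistic(samples: list[np.ndarray], midrank: bool = True) -> float:
    """The k-sample Anderson–Darling statistic A²_kN.

    ``midrank=True`` gives the tie-tolerant midrank version; ``False`` the
    continuous-data version (defined only for distinct pooled values).
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    k = len(samples)
    if k < 2 or any(len(s) < 1 for s in samples):
        raise ValueError("need k >= 2 non-empty samples")
    n = np.array([len(s) for s in samples])
    N = int(n.sum())
    pooled = np.concatenate(samples)
    zstar, counts = np.unique(pooled, return_counts=True)
    L = len(zstar)
    if L < 2:
        raise ValueError("pooled data are all identical; statistic degenerate")

    if midrank:
        # B_j: pooled count below z*_j plus half the ties at z*_j
        cum = np.concatenate([[0.0], np.cumsum(counts)])
        B = cum[:-1] + counts / 2.0
        denom = B * (N - B) - N * counts / 4.0
        total = 0.0
        for i in range(k):
            ci = np.zeros(L)
            idx = np.searchsorted(zstar, samples[i])
            np.add.at(ci, idx, 1.0)
            cumi = np.concatenate([[0.0], np.cumsum(ci)])
            M = cumi[:-1] + ci / 2.0
            num = (N * M - n[i] * B) ** 2
            total += (counts / N * num / denom).sum() / n[i]
        return float((N - 1) / N * total)

    if L != N:
        raise ValueError("continuous-version statistic requires distinct pooled values")
    order = np.argsort(pooled, kind="mergesort")
    j = np.arange(1, N)  # over Z_(1)..Z_(N-1)
    total = 0.0
    for i in range(k):
        member = np.zeros(N)
        member[: len(samples[i])] = 1.0  # pooled is samples concatenated
        offs = np.cumsum(np.concatenate([[0], n]))
        member = np.zeros(N)
        member[offs[i]: offs[i + 1]] = 1.0
        Mi = np.cumsum(member[order])[:-1]
        total += ((N * Mi - j * n[i]) ** 2 / (j * (N - j))).sum() / n[i]
    return float(total)


def _ad_variance(n: np.ndarray) -> float:
    """Null variance of A²_kN (Scholz–Stephens)."""
    k = len(n)
    N = int(n.sum())
    H = float((1.0 / n).sum())
    h = float(np.sum(1.0 / np.arange(1, N)))
    i = np.arange(1, N - 1, dtype=float)
    # g = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1} 1/((N-i) j)
    inv_j = 1.0 / np.arange(1, N, dtype=float)
    tail = np.cumsum(inv_j[::-1])[::-1]  # tail[i-1] = sum_{j=i}^{N-1} 1/j
    g = float(np.sum(1.0 / (N - i) * tail[1:]))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return var


# Standardized critical values t_m(α) = b0 + b1/√m + b2/m, m = k−1
_AD_ALPHAS = np.array([0.25, 0.10, 0.05, 0.025, 0.01])
_AD_COEFFS = np.array([
    (0.675, -0.245, -0.105),
    (1.281, 0.250, -0.305),
    (1.645, 0.678, -0.362),
    (1.960, 1.149, -0.391),
    (2.326, 1.822, -0.396),
])


def _ad_asymptotic_p(t: float, k: int) -> float:
    """Interpolate logit(α) against the standardized quantiles, linearly
    extrapolating outside the tabulated 0.01–0.25 range (no capping)."""
    m = k - 1
    tm = _AD_COEFFS[:, 0] + _AD_COEFFS[:, 1] / math.sqrt(m) + _AD_COEFFS[:, 2] / m
    logit = np.log(_AD_ALPHAS / (1.0 - _AD_ALPHAS))
    if t <= tm[0]:
        slope = (logit[1] - logit[0]) / (tm[1] - tm[0])
        y = logit[0] + slope * (t - tm[0])
    elif t >= tm[-1]:
        slope = (logit[-1] - logit[-2]) / (tm[-1] - tm[-2])
        y = logit[-1] + slope * (t - tm[-1])
    else:
        y = float(np.interp(t, tm, logit))
    return float(1.0 / (1.0 + math.exp(-y)))


def ad_k_sample(
    samples: list,
    midrank: bool = True,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> StatResult:
    """Anderson–Darling k-sample comparison of distribution shapes.

    Reports the standardized statistic T = (A² − (k−1))/σ_N with the
    asymptotic p-value; when ``n_permutations`` > 0, a permutation p-value
    (the oracle definition) is added under ``extra['p_permutation']``.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need at least two samples with n >= 2 each")
    n = np.array([len(s) for s in samples])
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0:
        return StatResult("anderson-darling-k", float("nan"), float("nan"),
                          n=tuple(n), extra={"degenerate": True})
    k = len(samples)
    a2 = ad_k_statistic(samples, midrank=midrank)
    sigma = math.sqrt(_ad_variance(n))
    t = (a2 - (k - 1)) / sigma
    p = min(1.0, max(0.0, _ad_asymptotic_p(t, k)))
    extra = {"A2": a2, "sigma": sigma, "midrank": midrank}
    if n_permutations > 0:
        rng = np.random.default_rng() if rng is None else rng
        offs = np.cumsum(np.concatenate([[0], n]))
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            parts = [perm[offs[i]: offs[i + 1]] for i in range(k)]
            if ad_k_statistic(parts, midrank=midrank) >= a2 - 1e-12:
                count += 1
        extra["p_permutation"] = (count + 1) / (n_permutations + 1)
    return StatResult("anderson-darling-k", t, p, n=tuple(n), extra=extra)
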