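"""Gamma-model crossover interference.

Adjacent inter-focus distances on multi-focus bivalents are modelled as the
gaps of a gamma renewal process.  The shape parameter υ measures
interference strength: υ = 1 means no interference (exponential gaps,
Poisson crossovers); larger υ means more regular spacing.

Two fitters are provided.  ``fit_gamma_shape`` is the plain maximum
likelihood estimate, which is biased on cytological data because the
observable distances are limited below by light-microscopy resolution and
above by the finite SC length.  ``fit_truncated_gamma_shape`` corrects for
both: the likelihood is restricted to the observable window [d_lo, d_hi]
and, because a gap of length x between two foci can only be seen when it
fits inside its source bivalent, each observation is weighted by the
stationary-renewal observation probability ∝ (S − x), with S the span of
the source bivalent.  The corrected density is

    g(x) = f(x | υ, μ) (S − x) / ∫_{d_lo}^{min(d_hi, S)} f(u) (S − u) du.

Setting ``finite_length=False`` drops the (S − x) weight and reduces to the
sharply doubly-truncated likelihood, appropriate for data censored to a
window by selection rather than by the geometry of the SC.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_types import FocusTable, StatResult, group_into_meiocytes
from .sc_metrics import DEFAULT_SCHEME, SizeGroupScheme, ensure_ranked

logger = logging.getLogger("meioco")

#: Default lower detection limit, as a fraction of the source span
#: (2% of SC length ≈ the light-microscopy resolution limit).
DEFAULT_D_LO_FRACTION = 0.02

#: Ranks excluded from interference analyses by default: the smallest
#: autosomes rarely carry more than a single MLH1 focus.
DEFAULT_EXCLUDED_RANKS = (17, 18, 19)

#: Shape reported for degenerate (zero log-variance) data.
SHAPE_DEGENERATE = math.inf


@dataclass
class DistanceSet:
    """Adjacent inter-focus distances with their source-bivalent spans."""

    distances: np.ndarray
    unit: str  # "percent_sc" or "um"
    spans: np.ndarray  # observable span of the source bivalent, same unit
    groups: np.ndarray = None  # size-group label per distance
    cells: np.ndarray = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.spans = np.asarray(self.spans, dtype=float)
        if self.unit not in ("percent_sc", "um"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.spans.shape != self.distances.shape:
            raise ValueError("spans must parallel distances")
        if len(self.distances) and (
            (self.distances <= 0).any() or (self.distances > self.spans + 1e-9).any()
        ):
            raise ValueError("distances must lie in (0, source span]")
        if self.groups is None:
            self.groups = np.full(self.distances.shape, "all", dtype=object)
        if self.cells is None:
            self.cells = np.full(self.distances.shape, "", dtype=object)

    def __len__(self) -> int:
        return len(self.distances)

    def restrict(self, mask: np.ndarray) -> "DistanceSet":
        return DistanceSet(self.distances[mask], self.unit, self.spans[mask],
                           self.groups[mask], self.cells[mask])

    def for_group(self, label: str) -> "DistanceSet":
        return self.restrict(self.groups == label)


@dataclass
class GammaInterferenceModel:
    """Fitted gamma interference model: shape υ and mean spacing μ."""

    shape: float
    mean_spacing: float
    unit: str
    window: tuple[float, float] | None = None
    n_intervals: int = 0
    loglik: float = math.nan
    converged: bool = True
    method: str = "mle"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.mean_spacing <= 0:
            raise ValueError("shape and mean_spacing must be positive")
        if self.window is not None and not self.window[0] < self.window[1]:
            raise ValueError("truncation window must satisfy d_lo < d_hi")


def interfocus_distances(
    dataset: FocusTable,
    unit: str = "percent_sc",
    scheme: SizeGroupScheme = DEFAULT_SCHEME,
    exclude_ranks: tuple[int, ...] = DEFAULT_EXCLUDED_RANKS,
    marker: str = "MLH1",
) -> DistanceSet:
    """All adjacent inter-focus gaps on bivalents with ≥2 foci.

    A bivalent with k foci contributes k−1 distances.  In ``percent_sc``
    units distances are normalized per source bivalent (span 100); in
    ``um`` units distances are fractions × the measured SC length.
    """
    if unit not in ("percent_sc", "um"):
        raise ValueError(f"unknown unit {unit!r}")
    cells = ensure_ranked(group_into_meiocytes(dataset.subset(marker=marker)))
    d, spans, groups, cell_ids = [], [], [], []
    for cell in cells:
        for biv in cell.bivalents:
            if biv.chromosome_rank in exclude_ranks or biv.n_foci < 2:
                continue
            gaps = np.diff(biv.focus_positions)
            if unit == "percent_sc":
                gaps, span = gaps * 100.0, 100.0
            else:
                if biv.sc_length is None or biv.sc_length <= 0:
                    raise ValueError("µm distances need a positive sc_length")
                gaps, span = gaps * biv.sc_length, biv.sc_length
            label = scheme.group_of(biv.chromosome_rank)
            for g in gaps:
                d.append(g)
                spans.append(span)
                groups.append(label)
                cell_ids.append(cell.cell_id)
    return DistanceSet(np.asarray(d), unit, np.asarray(spans),
                       np.asarray(groups, dtype=object), np.asarray(cell_ids, dtype=object))


def gamma_curve(
    shape: float, mean_spacing: float, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gamma density (mean μ, shape υ, rate υ/μ) and CDF on a grid.

    υ=1 gives the exponential (no-interference) reference curve.
    Returns (grid_kept, pdf, cdf); non-positive grid points are dropped
    with a warning (x=0 itself is kept — the density there is finite for
    υ ≥ 1).
    """
    if shape <= 0 or mean_spacing <= 0:
        raise ValueError("shape and mean_spacing must be positive")
    grid = np.asarray(grid, dtype=float)
    keep = grid >= 0
    if not keep.all():
        warnings.warn("dropping negative grid points", stacklevel=2)
        grid = grid[keep]
    scale = mean_spacing / shape
    return grid, stats.gamma.pdf(grid, shape, scale=scale), stats.gamma.cdf(grid, shape, scale=scale)


def _as_distances(distances) -> np.ndarray:
    x = distances.distances if isinstance(distances, DistanceSet) else np.asarray(distances, float)
    return x


def fit_gamma_shape(distances, min_n: int = 10) -> GammaInterferenceModel:
    """Untruncated gamma MLE.

    υ̂ solves ln υ − ψ(υ) = ln(mean) − mean(ln x); μ̂ is the arithmetic mean.
    All-equal data have zero log-variance and get the +∞ shape sentinel.
    """
    x = _as_distances(distances)
    unit = distances.unit if isinstance(distances, DistanceSet) else "percent_sc"
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} distances, got {len(x)}")
    if (x <= 0).any():
        raise ValueError("distances must be positive")
    mean = float(x.mean())
    s = math.log(mean) - float(np.mean(np.log(x)))
    if s <= 0:  # all observations equal (up to float noise)
        warnings.warn("degenerate all-equal distances; shape is unbounded", stacklevel=2)
        return GammaInterferenceModel(
            shape=SHAPE_DEGENERATE, mean_spacing=mean, unit=unit,
            n_intervals=len(x), loglik=math.inf, method="mle-naive",
            extra={"degenerate": True},
        )
    f = lambda v: math.log(v) - special.digamma(v) - s
    shape = optimize.brentq(f, 1e-8, 1e8)
    loglik = float(stats.gamma.logpdf(x, shape, scale=mean / shape).sum())
    return GammaInterferenceModel(shape=shape, mean_spacing=mean, unit=unit,
                                  n_intervals=len(x), loglik=loglik, method="mle-naive")


def default_window(distances: DistanceSet) -> tuple[float, float]:
    """Observable-window default: d_lo = 2% of the median span (microscopy
    resolution), d_hi = the 99th percentile of source spans (finite SC)."""
    lo = DEFAULT_D_LO_FRACTION * float(np.median(distances.spans))
    hi = float(np.percentile(distances.spans, 99))
    return lo, hi


def _truncated_nll(x, spans, lo, hi, finite_length):
    hi_i = np.minimum(hi, spans)
    log_weight = np.log(spans - x) if finite_length else 0.0

    def nll(p):
        v, m = math.exp(p[0]), math.exp(p[1])
        if not (1e-8 < v < 1e8 and 1e-12 < m < 1e12):
            return 1e12
        scale = m / v
        if finite_length:
            Z = spans * (stats.gamma.cdf(hi_i, v, scale=scale) - stats.gamma.cdf(lo, v, scale=scale)) \
                - m * (stats.gamma.cdf(hi_i, v + 1.0, scale=scale) - stats.gamma.cdf(lo, v + 1.0, scale=scale))
        else:
            Z = stats.gamma.cdf(hi_i, v, scale=scale) - stats.gamma.cdf(lo, v, scale=scale)
        if np.any(Z <= 0) or not np.all(np.isfinite(Z)):
            return 1e12
        ll = stats.gamma.logpdf(x, v, scale=scale) + log_weight - np.log(Z)
        total = float(ll.sum())
        return -total if math.isfinite(total) else 1e12

    return nll


def fit_truncated_gamma_shape(
    distances: DistanceSet,
    window: tuple[float, float] | None = None,
    finite_length: bool = True,
    min_n: int = 10,
) -> GammaInterferenceModel:
    """Truncation-corrected gamma MLE over the observable distance window.

    Every distance must already lie inside [d_lo, d_hi].  Optimization runs
    on (log υ, log μ) from the untruncated fit as a start point
    (convergence tolerance 1e-8 on the log-likelihood); a non-converged
    optimum is flagged and the naive fit returned alongside the diagnostic.
    """
    x = distances.distances
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} distances, got {len(x)}")
    if window is None:
        window = default_window(distances)
    lo, hi = window
    if not 0 <= lo < hi:
        raise ValueError("window must satisfy 0 <= d_lo < d_hi")
    if (x < lo - 1e-9).any() or (x > hi + 1e-9).any():
        raise ValueError("all distances must lie within the truncation window")

    naive = fit_gamma_shape(distances, min_n=min_n)
    if not math.isfinite(naive.shape):
        return naive
    spans = distances.spans if finite_length else np.full_like(x, hi)
    if finite_length and (x >= spans).any():
        raise ValueError("finite-length weighting requires every distance < its source span")
    nll = _truncated_nll(x, spans, lo, hi, finite_length)
    x0 = np.log([naive.shape, naive.mean_spacing])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options=dict(xatol=1e-7, fatol=1e-8, maxiter=4000, maxfev=6000))
    if not res.success or not math.isfinite(res.fun):
        logger.warning("truncated gamma fit did not converge: %s", res.message)
        return GammaInterferenceModel(
            shape=naive.shape, mean_spacing=naive.mean_spacing, unit=distances.unit,
            window=(lo, hi), n_intervals=len(x), loglik=naive.loglik, converged=False,
            method="mle-truncated", extra={"diagnostic": str(res.message), "naive_shape": naive.shape},
        )
    shape, mean = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    return GammaInterferenceModel(
        shape=shape, mean_spacing=mean, unit=distances.unit, window=(lo, hi),
        n_intervals=len(x), loglik=-float(res.fun), converged=True,
        method="mle-truncated" + ("-length-weighted" if finite_length else ""),
        extra={"naive_shape": naive.shape, "finite_length": finite_length},
    )


def truncated_loglik(
    distances: DistanceSet, model: GammaInterferenceModel,
    window: tuple[float, float], finite_length: bool = True,
) -> float:
    """Log-likelihood of (υ, μ) under the truncation-corrected density."""
    spans = distances.spans if finite_length else np.full_like(distances.distances, window[1])
    nll = _truncated_nll(distances.distances, spans, window[0], window[1], finite_length)
    return -nll(np.log([model.shape, model.mean_spacing]))


def ks_two_sample(a: DistanceSet, b: DistanceSet) -> StatResult:
    """Two-sided two-sample Kolmogorov–Smirnov comparison of distance distributions."""
    xa, xb = _as_distances(a), _as_distances(b)
    if len(xa) < 2 or len(xb) < 2:
        return StatResult("ks", float("nan"), float("nan"), n=(len(xa), len(xb)),
                          extra={"undefined": True})
    r = stats.ks_2samp(xa, xb, method="asymp")
    return StatResult("ks", float(r.statistic), float(r.pvalue), n=(len(xa), len(xb)))


def interference_report(
    a: FocusTable,
    b: FocusTable | None = None,
    scheme: SizeGroupScheme = DEFAULT_SCHEME,
    window: tuple[float, float] | None = None,
    unit: str = "percent_sc",
    d_lo_sensitivity_factor: float = 2.0,
) -> "pd.DataFrame":
    """Per genotype × size group: interval count, corrected υ, and spacing.

    The ``shape_corrected_dlo_x{f}`` column refits with d_lo scaled by the
    sensitivity factor, surfacing how strongly υ̂ depends on the assumed
    microscopy resolution.  An ``all`` row per genotype aggregates every
    group's intervals.
    """
    import pandas as pd

    rows = []
    for table in (a, b):
        if table is None:
            continue
        ds = interfocus_distances(table, unit=unit, scheme=scheme)
        if len(ds) == 0:
            continue
        genotype = table.df["genotype"].iloc[0]
        group_labels = ["all"] + [g for g in scheme.labels if (ds.groups == g).any()]
        for label in group_labels:
            sub = ds if label == "all" else ds.for_group(label)
            if len(sub) < 10:
                rows.append(dict(genotype=genotype, group=label, n_intervals=len(sub)))
                continue
            win = window if window is not None else default_window(sub)
            inside = sub.restrict((sub.distances >= win[0]) & (sub.distances <= win[1]))
            fit = fit_truncated_gamma_shape(inside, window=win)
            win2 = (win[0] * d_lo_sensitivity_factor, win[1])
            inside2 = sub.restrict((sub.distances >= win2[0]) & (sub.distances <= win2[1]))
            fit2 = fit_truncated_gamma_shape(inside2, window=win2) if len(inside2) >= 10 else None
            naive = fit_gamma_shape(sub)
            rows.append(dict(
                genotype=genotype, group=label, n_intervals=len(sub),
                shape_corrected=fit.shape, shape_naive=naive.shape,
                mean_spacing=float(sub.distances.mean()),
                sd_spacing=float(sub.distances.std(ddof=1)),
                converged=fit.converged,
                **{f"shape_corrected_dlo_x{d_lo_sensitivity_factor:g}":
                   fit2.shape if fit2 else float("nan")},
            ))
    return pd.DataFrame(rows)


def shape_recovery_study(
    shapes: tuple[float, ...] = (1.0, 5.0, 10.9, 20.0),
    mean_spacing: float = 0.5,
    n_intervals: int = 300,
    n_replicates: int = 50,
    seed: int = 0,
    rel_tol: float = 0.20,
    d_lo_fraction: float = 0.0,
):
    """Parameter-recovery loop across the simulate → fit pipeline.

    For each true shape υ*, repeatedly simulate stationary gamma-renewal
    crossovers on unit-length bivalents (μ* in SC fractions), collect
    adjacent inter-focus distances until ``n_intervals`` are retained, and
    refit with the truncation-corrected MLE.  The fitting window matches
    the generator's observation model: the generator imposes no
    resolution censoring, so the window is (0, span] and the correction
    consists of the finite-SC-length weighting.  Pass ``d_lo_fraction`` > 0
    to emulate resolution-censored data (gaps below the limit are then
    discarded before fitting, and the window is adjusted to match).

    Returns a DataFrame with one row per (shape, replicate) carrying the
    estimate and whether it fell within ``rel_tol`` of υ*.  Note the
    information limit: with a 2% resolution cut the near-zero gap
    behaviour that identifies small shapes is lost, and υ* = 1 recovery at
    n = 300 drops to the ±20% boundary (~78–81%).
    """
    import pandas as pd

    from .simulate import sample_stationary_gamma_renewal

    d_lo = 100.0 * d_lo_fraction
    rows = []
    for si, shape in enumerate(shapes):
        for rep in range(n_replicates):
            rng = np.random.default_rng(np.random.SeedSequence([seed, si, rep]))
            gaps: list[float] = []
            while len(gaps) < n_intervals:
                pts = sample_stationary_gamma_renewal(1.0, shape, mean_spacing, rng)
                if len(pts) >= 2:
                    g = np.diff(pts) * 100.0
                    gaps.extend(g[(g > d_lo) & (g < 100.0)])
            x = np.asarray(gaps[:n_intervals])
            ds = DistanceSet(x, "percent_sc", np.full_like(x, 100.0))
            fit = fit_truncated_gamma_shape(ds, window=(d_lo, 100.0))
            rows.append(dict(shape_true=shape, replicate=rep, shape_hat=fit.shape,
                             converged=fit.converged,
                             recovered=abs(fit.shape - shape) / shape <= rel_tol))
    return pd.DataFrame(rows)
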