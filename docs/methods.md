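# Methods

## Data model

The pipeline's universal input is a long-format *focus table*: one row per
immunofluorescent focus on a spread-nucleus bivalent, plus one row (with an
empty position field) per bivalent that carries no focus, so that
achiasmate/obligate-crossover statistics remain computable.  Focus positions
are stored as fractions of SC length measured from the centromeric end
(position 0 = centromere; mouse autosomes are telocentric) and converted to
percent of SC length in reporting layers.  Within a cell, bivalents are
rank-ordered by SC length from 1 (largest) to 19 (smallest); rank is a size
proxy, never a chromosome-identity claim.  Sex chromosomes are excluded
everywhere ("autosomal" totals), and output metadata records the exclusion.
Two foci closer than a configurable resolution gap (default 0.005 of SC
length, roughly the light-microscopy limit) are flagged during grouping but
never merged — merging would silently bias inter-focus distances.

## Crossover placement model

Crossover positions along a bivalent are modelled as a **stationary gamma
renewal process**: inter-event gaps are i.i.d. Gamma(shape υ, mean μ), with
υ the interference strength (υ = 1 ⇒ exponential gaps ⇒ Poisson process ⇒
no interference) and μ the mean spacing in fractions of SC length.  The
process starts from the equilibrium forward-recurrence distribution with
density (1 − F(x))/μ — sampled exactly as U·Y with U ~ Uniform(0,1) and Y a
length-biased gap, Gamma(υ+1, μ/υ) — so crossover intensity is uniform
along the SC and the centromeric end introduces no edge artifact.
Interference is thereby treated as a property of spacing, not of an anchor
point.

## Truncation-corrected interference fitting

The untruncated gamma MLE has the closed-form profile condition
ln υ − ψ(υ) = ln x̄ − mean(ln x) (ψ the digamma function), solved by
bisection, with μ̂ = x̄.  On cytological data this estimate is biased: the
observable distances are bounded below by microscopy resolution and above
by the finite SC length.  The corrected fitter maximizes the likelihood of
the *observable* gap distribution.  For interior gaps of a stationary
renewal process on a span S, a gap of length x is observed with probability
∝ (S − x) (its left endpoint must leave room for the gap), so the corrected
density on the observable window [d_lo, d_hi] is

    g(x) = f(x | υ, μ) (S − x) / Z,
    Z = S·[F(d*) − F(d_lo)] − μ·[F₊(d*) − F₊(d_lo)],   d* = min(d_hi, S),

where F is the Gamma(υ, μ/υ) CDF and F₊ the Gamma(υ+1, μ/υ) CDF (the
normalizer is analytic because ∫ u f(u) du = μ F₊(u)).  Setting
`finite_length=False` drops the (S − x) weight and gives the plain doubly
truncated likelihood, which is the right model when data were sharply
censored to a window by selection rather than by SC geometry.  Optimization
is Nelder–Mead on (log υ, log μ) from the untruncated fit (tolerance 1e-8
on the log-likelihood); non-convergence is flagged and the naive fit
returned with a diagnostic.

Why the length weight matters: a validation study fitting stationary-renewal
gaps (μ = 0.5 SC, 300 retained intervals) showed the sharp-truncation-only
likelihood recovers υ* = 1 within ±20% in under half of replicates, while
the length-weighted likelihood is essentially unbiased across
υ* ∈ {1, 5, 10.9, 20} (recovery 96–100%).

Default window for real data: d_lo = 2% of the median source span
(microscopy resolution; configurable, and the report includes a d_lo
sensitivity column), d_hi = the 99th percentile of source spans.  An
information limit is worth knowing: the 2% cut removes exactly the
near-zero gap behaviour that identifies *small* shapes, so with n = 300
window-censored gaps the best possible estimator of υ = 1 has
sd(log υ̂) ≈ 0.15 (Cramér–Rao), i.e. ±20% coverage of only ≈81%.  The
simulator applies no resolution censoring (close pairs are flagged, not
removed), so simulation-recovery studies use d_lo = 0 with the
finite-length correction only, matching the generating observation model;
`shape_recovery_study(d_lo_fraction=...)` reproduces the censored regime
when wanted.

A second caveat, which applies to gamma-shape fits on real cytology as much
as to simulations: centromere-proximal suppression and obligate-crossover
enforcement regularize observed spacings beyond the renewal interference
itself and inflate the fitted shape by roughly 10–20% (measured on the full
generator).  The fitted υ is therefore an *effective* interference
strength of the observed focus pattern, not a pure renewal parameter.

## Synthetic meiocyte generator

Each simulated cell carries 19 bivalents.  Per bivalent, in a documented
draw order from one seeded generator (identical seed ⇒ byte-identical
output): (1) SC length ~ Normal(per-rank mean, SD), resampled until
positive; (2) crossovers from the stationary renewal process on [0, 1];
(3) proximal suppression — events in the centromeric window w_c (default
15% of SC) are retained with probability s; (4) obligate-crossover
enforcement — the placement is resampled (bounded, default 100 retries)
while no crossover survives; (5) detection — each crossover is seen with
probability ε.  The obligate crossover is enforced *before* detection loss
because it is a property of the real crossover complement, not of
immunostaining; zero-focus bivalents then arise at rate ≈ (1 − ε) per
single-crossover bivalent, as observed cytologically.  SC lengths are drawn
independently per bivalent (per-rank marginals are all the data constrain);
an optional per-cell multiplicative size factor (`cell_length_factor_sd`)
adds the cell-to-cell correlation real nuclei show, default off.

Genotype presets (the defaults are the study conditions, fixed once):

| parameter | wild type | mutant (moderate allele) | basis |
|---|---|---|---|
| υ (shape) | 10.9 | 9.2 | corrected interference fits |
| μ (SC fraction) | 0.857 | 0.787 | calibrated: mean observed spacing 60.8% / 56.8% of SC |
| SC length per rank (µm) | group means 12.8/11.1/9.5/7.7/5.8 (SD 1.7/1.2/1.1/0.9/1.3) | 11.0/9.5/8.1/6.8/5.2 (SD 1.0/0.7/0.7/0.6/1.0) | measured size-group summaries |
| proximal window w_c | 0.15 | 0.15 | foci rare in the centromere-proximal ~15% |
| proximal retention s | 0.29 | 0.29 | stationary marginal is uniform, so 15%·s ≈ the observed ~4.3% proximal foci |
| detection ε | 0.99 | 0.962 | observed 0.9% / 3.8% zero-focus bivalents ≈ P(miss a singleton) |
| obligate | yes | yes | obligate-crossover biology |
| n cells | 32 | 20 | study sample sizes |

μ was calibrated by bisection against a fixed-seed 400-cell simulation
(`calibrate_mean_spacing`) so the simulated mean adjacent inter-focus
distance matches the measured genotype means; the calibration helper is
public API.  With a single per-genotype μ in SC fractions — the model's
deliberate simplification — expected focus counts are equal across ranks,
giving ≈22 MLH1 foci/cell (observed: ≈24) and fewer two-focus bivalents on
the largest chromosomes than real spreads show.  Passing tests therefore
demonstrate correctness of the analysis machinery under a faithful
interference/suppression/detection model, not that the generator reproduces
every rank-resolved feature of real data.  Per-stage focus counts
(RAD51/DMC1, DMC1, RPA) are drawn from a negative binomial matched to the
reported (mean, SD) — Poisson when not overdispersed, constant when SD = 0.

## Statistics

* **t comparisons of SC lengths**: Welch by default (pooled optional),
  per size group on per-chromosome units plus a per-cell total-length test.
  Cells with incomplete bivalent complements contribute to group means but
  not to per-cell totals (falling back to all cells only when no complete
  cell exists).
* **Fisher's exact test**: two-sided by the probability-mass convention
  (sum of hypergeometric probabilities ≤ the observed table's); one-sided
  p-values are always reported alongside because published values sometimes
  reflect the other convention.  Zero-margin tables are degenerate (p = 1,
  flagged).
* **G test**: G = 2 Σ O ln(O/E), df = (r−1)(c−1), χ² p; Williams correction
  available, off by default.
* **Mann–Whitney**: exact tie-aware permutation null computed by dynamic
  programming over doubled midranks when n₁·n₂ ≤ 400 (literal split
  enumeration is infeasible there; the DP gives the identical distribution),
  otherwise tie-corrected normal approximation with continuity correction.
  Two-sided exact p = min(1, 2·min(P(U ≤ u), P(U ≥ u))).
* **Anderson–Darling k-sample**: the rank statistic in both the continuous
  and the midrank (tie-tolerant, default) versions, standardized by the
  exact null mean (k−1) and variance.  The asymptotic p interpolates the
  published standardized quantiles on the log-odds scale and extrapolates
  linearly outside the tabulated 0.01–0.25 range rather than capping, which
  keeps it within ~0.01 of the permutation p at n = 50+50; a permutation
  mode (the ground-truth definition) is built in and used as the oracle in
  tests.
* **KDE position profiles**: Gaussian kernel, Silverman bandwidth by
  default, boundary reflection at 0 and 100% so mass is conserved on the
  axis.
* **Region occupancy**: closed intervals on positions pre-rounded to 0.1%,
  so one-decimal printed percentages reproduce exactly.  Defaults: proximal
  [0, 15], central [40, 75], distal [80, 95] % of SC.  The central-occupancy
  fold comparison is defined on two-focus bivalents of size ranks 1–5.
* **Fold changes**: explicit rounding conventions (1-decimal,
  nearest-integer, nearest-ten); rate folds are ratios of the one-decimal
  percent rates, matching how such folds are conventionally quoted, with the
  raw-proportion ratio also reported.
* **Percent-derived counts**: `reconstruct_count` recovers the integer
  count behind "x% of N" and *refuses* any reconstruction that fails to
  reproduce the printed percent at its printed precision.

## Numerical choices and degenerate inputs

Gamma-shape bisection brackets [1e-8, 1e8]; all-equal distance sets have
zero log-variance and return a +∞ shape sentinel with a warning.  Distances
must lie strictly inside (0, span]; fits require ≥10 intervals.
Ranking ties break by input order (stable, idempotent).  Size-group schemes
must partition ranks 1..19.  Ranks 17–19 are excluded from interference
analyses by default (they rarely carry two foci); three-focus bivalents
contribute both intervals to spacing analyses but are excluded from
positional stratifications (one- vs two-focus classes) — the two analyses
deliberately differ.  Empty region tables, < 5-point KDEs, and single-value
pooled AD data raise or flag rather than returning silent numbers.

## Known limitations

* One spacing parameter per genotype (in SC fractions) cannot match focus
  counts and spacings rank by rank; rank-resolved focus-class frequencies
  are compressed relative to real spreads.
* The gamma-renewal model generates three-focus bivalents only through its
  own spacing statistics; no separate cap or promoter of multiplicity
  exists.
* Detection loss is i.i.d. per focus; spatially correlated staining
  artifacts are not modelled.
* The fitted υ is an effective parameter (see above); comparisons between
  genotypes fitted the same way remain meaningful.
* Obligate enforcement by bounded resampling conditions the whole placement
  on ≥1 surviving crossover, which slightly tightens observed spacings; the
  bias is measured in tests rather than corrected analytically.
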