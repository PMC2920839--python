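# meioco — quantitative cytology of meiotic crossovers

`meioco` is a Python toolkit for the quantitative analysis of crossover
cytology in meiotic prophase spreads: immunofluorescent foci (MLH1,
RAD51/DMC1, DMC1, RPA, …) counted and positioned along synaptonemal
complexes (SCs).  It is aimed at meiosis labs and biostatisticians who work
with spread-nucleus measurements — per-bivalent SC lengths and
centromere-anchored focus positions — and need reproducible, tested
implementations of the analyses this literature runs on such data:

* **SC-length metrics** — per-cell size ranking of bivalents (1 = largest …
  19 = smallest mouse autosome), size-group summaries (mean ± SD, percent of
  total SC), and between-genotype *t* comparisons;
* **crossover interference** — gamma-model fits to adjacent inter-focus
  distances with a truncation correction for the observable-distance window;
* **crossover positional distributions** — centromere→telomere histograms and
  boundary-corrected kernel density profiles, region-occupancy fractions,
  and Anderson–Darling *k*-sample shape comparisons;
* **focus-count and contingency statistics** — fold changes with explicit
  rounding conventions, Fisher's exact test, the G test, Mann–Whitney with
  an exact tie-aware null, per-bivalent focus-multiplicity distributions;
* **a synthetic meiocyte simulator** that generates full focus tables with
  known ground truth, so every analysis stage is testable end to end.

## The interference model

Crossover interference — the tendency of crossovers to be spaced farther
apart than chance — is quantified by modelling adjacent inter-focus
distances *x* as the gaps of a stationary gamma renewal process:

    x ~ Gamma(shape υ, mean μ),   i.e. density f(x) = (υ/μ)^υ x^(υ−1) e^(−υx/μ) / Γ(υ)

υ = 1 is a Poisson process (no interference); larger υ means more regular
spacing, hence stronger interference.  Cytological distances are only
observable inside a window: the microscope cannot resolve separations below
d_lo, and no gap can exceed the SC it sits on.  For interior gaps of a
stationary renewal process on a bivalent of span S, a gap of length *x* is
observable with probability ∝ (S − x), so the corrected likelihood is

    g(x) = f(x | υ, μ) (S − x) / ∫_{d_lo}^{min(d_hi, S)} f(u | υ, μ) (S − u) du

and `interference.fit_truncated_gamma_shape` maximizes it numerically,
starting from the closed-form untruncated MLE (`fit_gamma_shape`, where υ̂
solves ln υ − ψ(υ) = ln x̄ − mean(ln x)).

The simulator places crossovers by the same process (equilibrium start, so
intensity is uniform along the SC), then layers on the features spread data
show: rank-dependent SC lengths, centromere-proximal crossover suppression,
per-focus detection efficiency, and obligate-crossover enforcement.

## Worked example

```python
import meioco
from meioco import interference, sc_metrics, simulate

# simulate a wild-type-like experiment: 32 pachytene spermatocytes
params = simulate.wild_type_params(seed=1, n_cells=32)
table = simulate.simulate_dataset(params)

cells = meioco.group_into_meiocytes(table)
totals = [sc_metrics.total_autosomal_sc(c) for c in cells]
print(f"total autosomal SC: {sum(totals)/len(totals):.1f} um/cell")

ds = interference.interfocus_distances(table)           # % of SC length
fit = interference.fit_truncated_gamma_shape(ds, window=(0.0, 100.0))
print(f"{len(ds)} inter-focus intervals, mean {ds.distances.mean():.1f}% of SC")
print(f"corrected interference shape: {fit.shape:.1f}")
```

prints (seed 1):

```
total autosomal SC: 171.8 um/cell
83 inter-focus intervals, mean 60.7% of SC
corrected interference shape: 12.1
```

The mean per-cell SC total sits at the wild-type calibration (≈172 µm); the
mean adjacent MLH1 spacing is ≈61% of bivalent length; and the corrected
gamma shape υ̂ ≈ 12 reflects the strong interference the dataset was
generated with (υ = 10.9 — at 83 intervals the estimate carries a Monte
Carlo error of roughly ±2).

The same stages are available from the shell:

```bash
meioco simulate --genotype wild-type --seed 1 --n-cells 32 --out wt.csv
meioco sc-metrics --table wt.csv --out sc_summary.csv
meioco interference --table-a wt.csv --out interference.csv
meioco co-dist --table wt.csv --out-prefix wt_codist
```

## Input format

A delimited text table (CSV/TSV auto-detected), one row per focus and one
row per focus-less bivalent, with columns
`cell_id, genotype, stage, chromosome_rank, sc_length_um,
focus_position_frac, marker`.  Positions are fractions of SC length from
the centromeric end (mouse autosomes are telocentric); `chromosome_rank`
is 1–19 or 0 for unranked; `stage` is one of the prophase-I substage labels
in `meioco.io_types.STAGES`.  Sex chromosomes are excluded throughout.

## Documentation

`docs/methods.md` describes the statistical model, the simulator and its
calibration, numerical choices, and known limitations.
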