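"""Synthetic meiocyte generator.

Crossover (MLH1-focus) placement follows a *stationary gamma renewal
process* along each bivalent: inter-event gaps are i.i.d. gamma with shape
``υ`` (interference strength; υ=1 is a Poisson process, i.e. no
interference) and mean spacing ``μ`` expressed as a fraction of SC length.
The process starts from the equilibrium forward-recurrence distribution, so
crossover intensity is uniform along the SC and there is no artifact at the
centromeric end.  On top of the renewal skeleton the generator applies the
features the cytology shows:

* rank-dependent SC lengths (normal per rank, truncated at >0);
* centromere-proximal crossover suppression: events in the proximal window
  ``w_c`` are retained only with probability ``s``;
* imperfect immunodetection: each surviving event is seen with probability
  ``ε``;
* optional obligate-crossover enforcement by bounded resampling.

Per-stage focus-count samples (for RAD51/DMC1, DMC1, RPA-style counts) are
drawn from a negative-binomial law matched to a (mean, SD) pair, falling
back to Poisson when the data are not overdispersed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .io_types import Bivalent, FocusTable, Meiocyte, STAGES, meiocytes_to_table

logger = logging.getLogger("meioco")

# Per-rank SC length means/SDs (µm), expanded from the five size-group
# summaries measured on spread pachytene spermatocytes.
_WT_GROUP_LENGTHS = [((1, 2), 12.8, 1.7), ((3, 5), 11.1, 1.2), ((6, 11), 9.5, 1.1),
                     ((12, 16), 7.7, 0.9), ((17, 19), 5.8, 1.3)]
_MOD_GROUP_LENGTHS = [((1, 2), 11.0, 1.0), ((3, 5), 9.5, 0.7), ((6, 11), 8.1, 0.7),
                      ((12, 16), 6.8, 0.6), ((17, 19), 5.2, 1.0)]


def _expand(groups) -> tuple[np.ndarray, np.ndarray]:
    mean = np.empty(19)
    sd = np.empty(19)
    for (lo, hi), m, s in groups:
        mean[lo - 1 : hi] = m
        sd[lo - 1 : hi] = s
    return mean, sd


@dataclass
class SimulationParams:
    """Full generative description of one genotype."""

    genotype: str
    sc_length_mean: np.ndarray  # µm, ranks 1..19
    sc_length_sd: np.ndarray
    shape: float  # gamma shape υ (>0)
    mean_spacing: float  # μ, fraction of SC (>0)
    detection_efficiency: float = 1.0
    proximal_window: float = 0.15
    proximal_retention: float = 1.0
    obligate: bool = True
    n_cells: int = 32
    seed: int = 0
    stage: str = "pachynema"
    marker: str = "MLH1"
    cell_length_factor_sd: float = 0.0  # optional per-cell multiplicative size factor
    max_obligate_retries: int = 100

    def __post_init__(self) -> None:
        self.sc_length_mean = np.asarray(self.sc_length_mean, dtype=float)
        self.sc_length_sd = np.asarray(self.sc_length_sd, dtype=float)
        if self.sc_length_mean.shape != (19,) or self.sc_length_sd.shape != (19,):
            raise ValueError("sc_length_mean and sc_length_sd must have one entry per rank 1..19")
        if (self.sc_length_mean <= 0).any() or (self.sc_length_sd < 0).any():
            raise ValueError("SC length means must be positive and SDs non-negative")
        if self.shape <= 0 or self.mean_spacing <= 0:
            raise ValueError("shape and mean_spacing must be positive")
        for name in ("detection_efficiency", "proximal_retention"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 <= self.proximal_window <= 1.0:
            raise ValueError("proximal_window must be a fraction of SC")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


# Mean spacings below were calibrated once with calibrate_mean_spacing() so
# the simulated mean adjacent inter-focus distance matches the measured
# 60.8% (wild type) / 56.8% (Trip13 mod/mod) of bivalent length.
def wild_type_params(seed: int = 0, n_cells: int = 32) -> SimulationParams:
    mean, sd = _expand(_WT_GROUP_LENGTHS)
    return SimulationParams(
        genotype="wild-type", sc_length_mean=mean, sc_length_sd=sd,
        shape=10.9, mean_spacing=0.857, detection_efficiency=0.99,
        proximal_retention=0.29, obligate=True, n_cells=n_cells, seed=seed,
    )


def trip13_mod_params(seed: int = 0, n_cells: int = 20) -> SimulationParams:
    mean, sd = _expand(_MOD_GROUP_LENGTHS)
    return SimulationParams(
        genotype="Trip13-mod", sc_length_mean=mean, sc_length_sd=sd,
        shape=9.2, mean_spacing=0.787, detection_efficiency=0.962,
        proximal_retention=0.29, obligate=True, n_cells=n_cells, seed=seed,
    )


def default_params(genotype: str, seed: int = 0, **overrides) -> SimulationParams:
    factories = {"wild-type": wild_type_params, "Trip13-mod": trip13_mod_params}
    if genotype not in factories:
        raise ValueError(f"no preset for genotype {genotype!r}; choose from {sorted(factories)}")
    params = factories[genotype](seed=seed)
    return replace(params, **overrides) if overrides else params


def params_from_config(cfg: dict) -> SimulationParams:
    """Build SimulationParams from a config mapping (preset plus overrides)."""
    cfg = dict(cfg)
    genotype = cfg.pop("genotype")
    preset = cfg.pop("preset", genotype)
    for key in ("sc_length_mean", "sc_length_sd"):
        if key in cfg:
            cfg[key] = np.asarray(cfg[key], dtype=float)
    try:
        return default_params(preset, **cfg)
    except ValueError:
        return SimulationParams(genotype=genotype, **cfg)


def sample_stationary_gamma_renewal(
    L: float, shape: float, mean_spacing: float, rng: np.random.Generator
) -> np.ndarray:
    """One realization of the equilibrium gamma renewal process on [0, L].

    The first event offset is drawn from the forward-recurrence density
    (1−F(x))/μ, sampled exactly as U·Y with U~Uniform(0,1) and Y a
    length-biased gap, i.e. Y~Gamma(υ+1, μ/υ); subsequent gaps are i.i.d.
    Gamma(υ, μ/υ).  The expected event count is L/μ.
    """
    if L <= 0 or shape <= 0 or mean_spacing <= 0:
        raise ValueError("L, shape and mean_spacing must all be positive")
    scale = mean_spacing / shape
    events = []
    x = rng.uniform() * rng.gamma(shape + 1.0, scale)
    while x <= L:
        events.append(x)
        x += rng.gamma(shape, scale)
    return np.asarray(events)


def _place_crossovers(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Renewal events after centromere-proximal suppression (true crossovers)."""
    pos = sample_stationary_gamma_renewal(1.0, params.shape, params.mean_spacing, rng)
    if params.proximal_retention < 1.0 and len(pos):
        proximal = pos <= params.proximal_window
        keep = ~proximal | (rng.uniform(size=len(pos)) < params.proximal_retention)
        pos = pos[keep]
    return pos


def simulate_bivalent(
    params: SimulationParams, rank: int, rng: np.random.Generator, length_factor: float = 1.0
) -> Bivalent:
    """Simulate one bivalent of the given size rank.

    Draw order (fixed for reproducibility): SC length, then renewal events,
    then proximal thinning, then — under ``obligate`` — bounded resampling of
    the placement while no crossover survives, then detection thinning.  The
    obligate crossover is a property of the real crossover complement, so it
    is enforced before imaging loss: zero-focus bivalents then arise at rate
    ≈(1−ε) per singleton bivalent, as observed cytologically.
    """
    if not 1 <= rank <= 19:
        raise ValueError("rank must be in 1..19")
    mean = params.sc_length_mean[rank - 1] * length_factor
    sd = params.sc_length_sd[rank - 1]
    sc = rng.normal(mean, sd)
    while sc <= 0:
        sc = rng.normal(mean, sd)
    pos = _place_crossovers(params, rng)
    if params.obligate:
        tries = 0
        while len(pos) == 0 and tries < params.max_obligate_retries:
            pos = _place_crossovers(params, rng)
            tries += 1
        if len(pos) == 0:
            logger.warning(
                "obligate crossover not achieved on rank %d after %d retries; keeping zero-focus bivalent",
                rank, params.max_obligate_retries,
            )
    if params.detection_efficiency < 1.0 and len(pos):
        pos = pos[rng.uniform(size=len(pos)) < params.detection_efficiency]
    return Bivalent(chromosome_rank=rank, sc_length=float(sc), focus_positions=tuple(pos))


def simulate_meiocyte(params: SimulationParams, cell_id: str, rng: np.random.Generator) -> Meiocyte:
    factor = 1.0
    if params.cell_length_factor_sd > 0:
        factor = max(rng.normal(1.0, params.cell_length_factor_sd), 0.05)
    bivalents = [simulate_bivalent(params, rank, rng, factor) for rank in range(1, 20)]
    return Meiocyte(cell_id, params.genotype, params.stage, bivalents)


def simulate_dataset(params: SimulationParams) -> FocusTable:
    """Simulate ``n_cells`` meiocytes × 19 bivalents as a validated FocusTable.

    The single generator seeded with ``params.seed`` drives every draw in a
    documented order, so an identical seed yields an identical table.
    """
    rng = np.random.default_rng(params.seed)
    cells = [simulate_meiocyte(params, f"cell_{i + 1:03d}", rng) for i in range(params.n_cells)]
    return meiocytes_to_table(cells, marker=params.marker)


@dataclass
class CountModel:
    """Per-stage focus-count law matched to a reported mean ± SD."""

    stage: str
    marker: str
    mean: float
    sd: float
    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.mean < 0 or self.sd < 0:
            raise ValueError("mean and sd must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


#: Reported per-cell focus counts (mean, SD) by protein, stage and genotype.
STAGE_COUNT_TABLE: dict[tuple[str, str, str], tuple[float, float]] = {
    ("RPA", "leptonema", "wild-type"): (27.6, 22.0),
    ("RPA", "leptonema", "Trip13-mod"): (52.1, 20.9),
    ("RPA", "leptonema", "Trip13-sev"): (70.2, 26.9),
    ("RAD51/DMC1", "early-leptonema", "wild-type"): (130.7, 60.4),
    ("RAD51/DMC1", "early-leptonema", "Trip13-mod"): (82.3, 52.0),
    ("RAD51/DMC1", "early-leptonema", "Trip13-sev"): (33.3, 43.3),
    ("RAD51/DMC1", "late-leptonema", "wild-type"): (179.3, 45.3),
    ("RAD51/DMC1", "late-leptonema", "Trip13-mod"): (146.9, 50.4),
    ("RAD51/DMC1", "late-leptonema", "Trip13-sev"): (99.5, 35.5),
    ("RAD51/DMC1", "early-zygonema", "wild-type"): (219.7, 49.1),
    ("RAD51/DMC1", "early-zygonema", "Trip13-mod"): (189.9, 36.4),
    ("RAD51/DMC1", "early-zygonema", "Trip13-sev"): (144.5, 22.7),
    ("RAD51/DMC1", "late-zygonema", "wild-type"): (133.3, 43.7),
    ("RAD51/DMC1", "late-zygonema", "Trip13-mod"): (156.3, 34.8),
    ("RAD51/DMC1", "late-zygonema", "Trip13-sev"): (136.9, 21.6),
    ("RAD51/DMC1", "pachynema", "wild-type"): (18.2, 7.0),
    ("RAD51/DMC1", "pachynema", "Trip13-mod"): (131.0, 14.5),
    ("RAD51/DMC1", "pachynema", "Trip13-sev"): (99.0, 42.6),
    ("RAD51/DMC1", "diplonema", "wild-type"): (6.0, 6.2),
    ("RAD51/DMC1", "diplonema", "Trip13-mod"): (13.0, 8.9),
    ("DMC1", "early-leptonema", "wild-type"): (33.7, 17.0),
    ("DMC1", "early-leptonema", "Trip13-sev"): (45.5, 22.2),
    ("DMC1", "late-leptonema", "wild-type"): (147.8, 50.7),
    ("DMC1", "late-leptonema", "Trip13-sev"): (147.8, 38.1),
    ("DMC1", "early-zygonema", "wild-type"): (141.8, 31.1),
    ("DMC1", "early-zygonema", "Trip13-sev"): (169.7, 21.9),
    ("DMC1", "late-zygonema", "wild-type"): (77.2, 27.0),
    ("DMC1", "late-zygonema", "Trip13-sev"): (166.0, 19.2),
    ("DMC1", "pachynema", "wild-type"): (0.4, 0.7),
    ("DMC1", "pachynema", "Trip13-sev"): (147.8, 23.5),
}


def count_model(marker: str, stage: str, genotype: str, n_cells: int = 100) -> CountModel:
    mean, sd = STAGE_COUNT_TABLE[(marker, stage, genotype)]
    return CountModel(stage=stage, marker=marker, mean=mean, sd=sd, n_cells=n_cells)


def simulate_stage_counts(model: CountModel, rng: np.random.Generator) -> np.ndarray:
    """Per-cell focus counts matched to (mean, SD): negative binomial when
    overdispersed, Poisson otherwise, constant when sd == 0."""
    m, v = model.mean, model.sd**2
    if model.sd == 0:
        return np.full(model.n_cells, round(model.mean), dtype=int)
    if m == 0:
        return np.zeros(model.n_cells, dtype=int)
    if v <= m:
        return rng.poisson(m, size=model.n_cells)
    k = m * m / (v - m)
    p = k / (k + m)
    return rng.negative_binomial(k, p, size=model.n_cells)


def observed_interfocus_mean(params: SimulationParams, n_cells: int = 400, seed: int = 12345) -> float:
    """Simulated mean adjacent inter-focus distance, as a fraction of SC."""
    sim = replace(params, n_cells=n_cells, seed=seed)
    rng = np.random.default_rng(sim.seed)
    gaps: list[float] = []
    for i in range(sim.n_cells):
        cell = simulate_meiocyte(sim, f"c{i}", rng)
        for biv in cell.bivalents:
            if biv.n_foci >= 2:
                gaps.extend(np.diff(biv.focus_positions))
    if not gaps:
        raise RuntimeError("no multi-focus bivalents produced; cannot measure spacing")
    return float(np.mean(gaps))


def calibrate_mean_spacing(
    params: SimulationParams, target_fraction: float, n_cells: int = 400,
    seed: int = 12345, tol: float = 2e-3, max_iter: int = 40,
) -> float:
    """Find μ so the simulated mean inter-focus distance hits ``target_fraction``.

    The observed mean spacing is monotone in μ, so a bisection on μ against
    a fixed-seed simulation converges quickly; used once to fix the preset
    spacings for each genotype.
    """
    lo, hi = 0.05, 3.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        got = observed_interfocus_mean(replace(params, mean_spacing=mid), n_cells=n_cells, seed=seed)
        if abs(got - target_fraction) < tol:
            return mid
        if got < target_fraction:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def true_params_sidecar(params: SimulationParams) -> dict:
    """JSON-serializable record of the generating parameters (for recovery tests)."""
    d = {k: v for k, v in params.__dict__.items()}
    d["sc_length_mean"] = params.sc_length_mean.tolist()
    d["sc_length_sd"] = params.sc_length_sd.tolist()
    d["sex_chromosomes_excluded"] = True
    return d
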