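"""Shared data model and tabular I/O for cytological focus measurements.

The universal input of the pipeline is a *focus table*: delimited text with
one row per immunofluorescent focus, or one row per bivalent for bivalents
without any focus (so that achiasmate/obligate-crossover statistics remain
computable).  Positions along the synaptonemal complex (SC) are stored as
fractions of SC length measured from the centromeric end (mouse autosomes
are telocentric, so position 0 is the centromere); reporting layers convert
to percent of SC length.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("meioco")

#: Closed vocabulary of meiotic prophase I substages.
STAGES = (
    "early-leptonema",
    "late-leptonema",
    "early-zygonema",
    "late-zygonema",
    "pachynema",
    "diplonema",
)

#: Sentinel chromosome_rank for bivalents that have not been size-ranked.
UNRANKED = 0

#: Documented, fixed column order of the on-disk focus-table format.
COLUMNS = (
    "cell_id",
    "genotype",
    "stage",
    "chromosome_rank",
    "sc_length_um",
    "focus_position_frac",
    "marker",
)

#: Two foci closer than this fraction of the SC are at the light-microscopy
#: resolution limit; they are flagged (never merged) during grouping.
RESOLUTION_GAP = 0.005


class FocusTableError(Exception):
    """Base class for focus-table problems."""


class FormatError(FocusTableError):
    """The file does not have the documented layout (e.g. missing column)."""


class ValidationError(FocusTableError):
    """A row violates a data-model invariant."""


class ConsistencyError(FocusTableError):
    """Rows that should describe one object disagree with each other."""


@dataclass(frozen=True)
class Bivalent:
    """A pair of synapsed homologs: SC length plus sorted focus positions."""

    chromosome_rank: int
    sc_length: float
    focus_positions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.sc_length <= 0:
            raise ValidationError(f"sc_length must be positive, got {self.sc_length}")
        if any(p < 0 or p > 1 for p in self.focus_positions):
            raise ValidationError("focus positions must lie in [0, 1]")
        object.__setattr__(self, "focus_positions", tuple(sorted(self.focus_positions)))

    @property
    def n_foci(self) -> int:
        return len(self.focus_positions)

    def close_pairs(self, gap: float = RESOLUTION_GAP) -> list[tuple[int, int]]:
        """Indices of adjacent focus pairs closer than ``gap`` (flag, don't merge)."""
        p = self.focus_positions
        return [(i, i + 1) for i in range(len(p) - 1) if p[i + 1] - p[i] < gap]


@dataclass
class Meiocyte:
    """One spread nucleus: up to 19 autosomal bivalents."""

    cell_id: str
    genotype: str
    stage: str
    bivalents: list[Bivalent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.bivalents) > 19:
            raise ValidationError(
                f"cell {self.cell_id}: {len(self.bivalents)} bivalents exceeds the 19 mouse autosomes"
            )
        ranks = [b.chromosome_rank for b in self.bivalents if b.chromosome_rank != UNRANKED]
        if len(ranks) != len(set(ranks)):
            raise ValidationError(f"cell {self.cell_id}: duplicate chromosome ranks")
        if any(r < 0 or r > 19 for r in ranks):
            raise ValidationError(f"cell {self.cell_id}: ranks must be in 1..19")

    @property
    def n_foci(self) -> int:
        return sum(b.n_foci for b in self.bivalents)


@dataclass
class StatResult:
    """A named test statistic with its p-value, uniform across the package."""

    name: str
    statistic: float
    pvalue: float
    df: float | None = None
    n: tuple[int, ...] | None = None
    sided: str = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isnan(self.pvalue) or 0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value out of [0,1]: {self.pvalue}")


class FocusTable:
    """Validated long-format table of focus measurements.

    Thin wrapper around a :class:`pandas.DataFrame` with the fixed columns
    of :data:`COLUMNS`.  ``focus_position_frac`` is NaN on zero-focus
    bivalent rows; ``chromosome_rank`` uses 0 for "unranked".
    """

    def __init__(self, df: pd.DataFrame, strict: bool = True):
        df, n_dropped = _validate(df, strict=strict)
        self.df = df
        self.n_dropped = n_dropped

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FocusTable):
            return NotImplemented
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        if len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True

    @classmethod
    def from_rows(cls, rows: Iterable[dict], strict: bool = True) -> "FocusTable":
        return cls(pd.DataFrame(list(rows), columns=list(COLUMNS)), strict=strict)

    def subset(self, **conditions) -> "FocusTable":
        """Rows matching every ``column=value`` (or ``column=list``) condition."""
        df = self.df
        for col, val in conditions.items():
            if isinstance(val, (list, tuple, set, frozenset, np.ndarray)):
                df = df[df[col].isin(list(val))]
            else:
                df = df[df[col] == val]
        return FocusTable(df.reset_index(drop=True))


def _validate(df: pd.DataFrame, strict: bool) -> tuple[pd.DataFrame, int]:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["genotype"] = df["genotype"].astype(str)
    df["stage"] = df["stage"].astype(str)
    df["marker"] = df["marker"].astype(str)
    df["chromosome_rank"] = pd.to_numeric(df["chromosome_rank"], errors="coerce")
    df["sc_length_um"] = pd.to_numeric(df["sc_length_um"], errors="coerce")
    df["focus_position_frac"] = pd.to_numeric(df["focus_position_frac"], errors="coerce")

    pos = df["focus_position_frac"]
    bad = pd.Series(False, index=df.index)
    problems: list[str] = []

    m = ~df["stage"].isin(STAGES)
    if m.any():
        problems.append(f"unknown stage label(s) {sorted(df.loc[m, 'stage'].unique())} in rows {list(df.index[m])}")
        bad |= m
    m = df["chromosome_rank"].isna() | (df["chromosome_rank"] % 1 != 0) | (df["chromosome_rank"] < 0) | (df["chromosome_rank"] > 19)
    if m.any():
        problems.append(f"chromosome_rank outside 0..19 in rows {list(df.index[m])}")
        bad |= m
    m = df["sc_length_um"].isna() | (df["sc_length_um"] <= 0)
    if m.any():
        problems.append(f"non-positive or missing sc_length_um in rows {list(df.index[m])}")
        bad |= m
    m = pos.notna() & ((pos < 0) | (pos > 1))
    if m.any():
        problems.append(f"focus_position_frac outside [0,1] in rows {list(df.index[m])}")
        bad |= m

    if problems and strict:
        raise ValidationError("; ".join(problems))
    n_dropped = int(bad.sum())
    if n_dropped:
        logger.warning("dropped %d invalid row(s): %s", n_dropped, "; ".join(problems))
        df = df[~bad]
    df = df.reset_index(drop=True)
    df["chromosome_rank"] = df["chromosome_rank"].astype(int)
    return df, n_dropped


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_focus_table(path: str | Path, strict: bool = True) -> FocusTable:
    """Read a delimited focus table (comma or tab, auto-detected).

    In strict mode any invariant violation raises :class:`ValidationError`
    naming the offending rows; in lenient mode offending rows are dropped
    and counted in ``FocusTable.n_dropped``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_delimiter(path), float_precision="round_trip")
    return FocusTable(df, strict=strict)


def write_focus_table(table: FocusTable, path: str | Path) -> None:
    """Write the documented CSV layout; floats serialize with full round-trip precision."""
    table.df.to_csv(path, index=False, float_format="%.17g")


def group_into_meiocytes(table: FocusTable) -> list[Meiocyte]:
    """Group focus rows into per-cell :class:`Meiocyte` objects.

    Rows sharing (cell_id, chromosome_rank) describe one bivalent when the
    rank is assigned; unranked rows (rank 0) are grouped by their exact SC
    length within the cell.  Focus positions come out sorted ascending.
    Conflicting SC lengths for one ranked bivalent raise
    :class:`ConsistencyError`.
    """
    cells: list[Meiocyte] = []
    n_flagged = 0
    for cell_id, cdf in table.df.groupby("cell_id", sort=False):
        genotypes = cdf["genotype"].unique()
        stages = cdf["stage"].unique()
        if len(genotypes) > 1 or len(stages) > 1:
            raise ConsistencyError(f"cell {cell_id}: conflicting genotype or stage labels")
        bivalents = []
        for key, bdf in cdf.groupby(
            cdf["chromosome_rank"].where(cdf["chromosome_rank"] > 0, -cdf["sc_length_um"]), sort=False
        ):
            lengths = bdf["sc_length_um"].unique()
            if len(lengths) > 1:
                raise ConsistencyError(
                    f"cell {cell_id}, rank {int(bdf['chromosome_rank'].iloc[0])}: "
                    f"conflicting sc_length values {sorted(lengths)}"
                )
            positions = bdf["focus_position_frac"].dropna().tolist()
            biv = Bivalent(
                chromosome_rank=int(bdf["chromosome_rank"].iloc[0]),
                sc_length=float(lengths[0]),
                focus_positions=tuple(positions),
            )
            n_flagged += len(biv.close_pairs())
            bivalents.append(biv)
        cells.append(Meiocyte(str(cell_id), str(genotypes[0]), str(stages[0]), bivalents))
    if n_flagged:
        logger.warning(
            "%d focus pair(s) closer than the %.3f resolution gap were flagged", n_flagged, RESOLUTION_GAP
        )
    return cells


def meiocytes_to_table(cells: Sequence[Meiocyte], marker: str = "MLH1") -> FocusTable:
    """Inverse of :func:`group_into_meiocytes` (zero-focus bivalents get one NaN row)."""
    rows = []
    for cell in cells:
        for biv in cell.bivalents:
            base = dict(
                cell_id=cell.cell_id,
                genotype=cell.genotype,
                stage=cell.stage,
                chromosome_rank=biv.chromosome_rank,
                sc_length_um=biv.sc_length,
                marker=marker,
            )
            if biv.n_foci == 0:
                rows.append({**base, "focus_position_frac": float("nan")})
            else:
                for p in biv.focus_positions:
                    rows.append({**base, "focus_position_frac": p})
    return FocusTable.from_rows(rows)


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (genotype labels, size groups, regions, windows, seeds)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"configuration {path} must be a YAML mapping")
    return cfg
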