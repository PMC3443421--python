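"""Two-condition differential miRNA calling by abundance and fold thresholds.

Folds follow the signed-reciprocal convention used in the source tables:
with condition A (adult peripheral blood) as reference and condition B
(cord blood) as comparison, ``fold = rpkm_b / rpkm_a`` when B >= A, and
``fold = -(rpkm_a / rpkm_b)`` otherwise, so ``|fold| >= 1`` always and the
sign names the enriched side.  A zero denominator is reported as the
finite sentinel ``9.90e307`` (the convention the tables print) and
flagged so downstream code never mistakes it for a real ratio.

A miRNA is called differential when (i) its RPKM exceeds the abundance
threshold in at least one condition (max over conditions — rows with one
near-zero condition are exactly the strongest calls) and (ii) the fold
magnitude meets the fold threshold, inclusively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .quantify import MiRNAQuant

__all__ = [
    "DiffConfig",
    "DiffRecord",
    "signed_fold",
    "call_differential",
    "rank_mirnas",
    "write_diff_tables",
    "read_diff_table",
]

B_ENRICHED = "B_ENRICHED"
A_ENRICHED = "A_ENRICHED"
NONE = "NONE"

#: fold value printed when the reference-condition RPKM is zero
ZERO_SENTINEL = 9.90e307


@dataclass(frozen=True)
class DiffConfig:
    rpkm_threshold: float = 100.0
    fold_threshold: float = 1.5
    zero_sentinel: float = ZERO_SENTINEL

    def __post_init__(self) -> None:
        if self.rpkm_threshold <= 0:
            raise ValueError("rpkm_threshold must be positive")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")


@dataclass
class DiffRecord:
    name: str
    rpkm_a: float
    rpkm_b: float
    fold: float
    is_sentinel: bool
    passes_abundance: bool
    passes_fold: bool
    side: str
    rank_a: int = 0
    rank_b: int = 0

    @property
    def called(self) -> bool:
        return self.side != NONE

    @property
    def log2_fold(self) -> float:
        """Plain log2(B/A); +/-inf on a zero condition."""
        if self.rpkm_a == 0:
            return math.inf
        if self.rpkm_b == 0:
            return -math.inf
        return math.log2(self.rpkm_b / self.rpkm_a)


def signed_fold(
    rpkm_a: float, rpkm_b: float, sentinel: float = ZERO_SENTINEL
) -> tuple[float, bool]:
    """Signed-reciprocal fold (B/A convention); returns (fold, is_sentinel).

    Undefined when both RPKMs are zero.
    """
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValueError("RPKM values must be non-negative")
    if rpkm_a == 0 and rpkm_b == 0:
        raise ValueError("fold undefined when both RPKMs are zero")
    if rpkm_b >= rpkm_a:
        if rpkm_a == 0:
            return sentinel, True
        return rpkm_b / rpkm_a, False
    if rpkm_b == 0:
        return -sentinel, True
    return -(rpkm_a / rpkm_b), False


def rank_mirnas(quants: Iterable[MiRNAQuant]) -> dict[str, int]:
    """Ordinal rank by descending RPKM, rank 1 highest; ties by name."""
    ordered = sorted(quants, key=lambda q: (-q.rpkm, q.name))
    if not ordered:
        raise ValueError("cannot rank an empty quantification set")
    return {q.name: i for i, q in enumerate(ordered, start=1)}


def call_differential(
    quants_a: list[MiRNAQuant],
    quants_b: list[MiRNAQuant],
    cfg: "DiffConfig | None" = None,
) -> list[DiffRecord]:
    """Compare two samples over a shared miRNA universe.

    Records for miRNAs with zero RPKM in both conditions are returned
    uncalled (their fold is undefined and excluded from calling).
    Output is sorted by name.
    """
    cfg = cfg or DiffConfig()
    a_by_name = {q.name: q for q in quants_a}
    b_by_name = {q.name: q for q in quants_b}
    if set(a_by_name) != set(b_by_name):
        only_a = sorted(set(a_by_name) - set(b_by_name))
        only_b = sorted(set(b_by_name) - set(a_by_name))
        raise ValueError(
            f"miRNA universes differ: only in A: {only_a}; only in B: {only_b}"
        )
    ranks_a = rank_mirnas(quants_a)
    ranks_b = rank_mirnas(quants_b)

    records = []
    for name in sorted(a_by_name):
        ra, rb = a_by_name[name].rpkm, b_by_name[name].rpkm
        if ra == 0 and rb == 0:
            records.append(
                DiffRecord(name, ra, rb, math.nan, False, False, False, NONE,
                           ranks_a[name], ranks_b[name])
            )
            continue
        fold, is_sentinel = signed_fold(ra, rb, cfg.zero_sentinel)
        passes_abundance = max(ra, rb) > cfg.rpkm_threshold
        passes_fold = abs(fold) >= cfg.fold_threshold
        if passes_abundance and passes_fold:
            side = B_ENRICHED if fold > 0 else A_ENRICHED
        else:
            side = NONE
        records.append(
            DiffRecord(name, ra, rb, fold, is_sentinel, passes_abundance,
                       passes_fold, side, ranks_a[name], ranks_b[name])
        )
    return records


_COLUMNS = ["name", "rpkm_a", "rpkm_b", "fold", "rank_a", "rank_b"]


def _write_one(records: list[DiffRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_COLUMNS) + "\n")
        for r in records:
            fold = f"{r.fold:.10g}" if not r.is_sentinel else f"{r.fold:.2E}"
            fh.write(
                f"{r.name}\t{r.rpkm_a!r}\t{r.rpkm_b!r}\t{fold}\t"
                f"{r.rank_a}\t{r.rank_b}\n"
            )


def write_diff_tables(records: Iterable[DiffRecord], b_path, a_path) -> None:
    """Write the two called-miRNA tables.

    The B-enriched table is sorted by descending fold (sentinel rows
    first), the A-enriched table ascending (most negative first) — the
    ordering the printed tables use.
    """
    records = list(records)
    b_rows = sorted(
        (r for r in records if r.side == B_ENRICHED), key=lambda r: (-r.fold, r.name)
    )
    a_rows = sorted(
        (r for r in records if r.side == A_ENRICHED), key=lambda r: (r.fold, r.name)
    )
    _write_one(b_rows, b_path)
    _write_one(a_rows, a_path)


def read_diff_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", header=None, names=_COLUMNS)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_COLUMNS)
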