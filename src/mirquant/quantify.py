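"""Per-miRNA abundance as a multi-mapping-corrected RPKM.

The statistic is ``RPKM = C / (L * M * N) * 1e9`` with

* ``C`` — reads aligned to the miRNA (summed tag counts),
* ``L`` — mature length in nt,
* ``M`` — multi-mapping number: distinct genomic loci encoding the
  mature sequence, so a two-locus miRNA at equal coverage scores half
  the RPKM of a single-locus one,
* ``N`` — total mapped reads in the sample.

``N`` is a library-size proxy chosen by policy: ``"aligned"`` (default)
counts admitted reads assigned to any reference sequence, miRNA or exon;
``"admitted"`` counts all reads surviving preprocessing.  Genome-wide
mapping totals are not computable from reference sequences alone, so the
policy in force is recorded in the output metadata of every run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .align import EXCLUDED_MRNA, MIRNA, TagAssignment, mirna_hit_multiplicity
from .reference import ReferenceBundle

__all__ = ["MiRNAQuant", "compute_rpkm", "compute_n", "quantify_sample"]

N_POLICIES = ("aligned", "admitted")


@dataclass(frozen=True)
class MiRNAQuant:
    """One miRNA's quantification record in one sample."""

    name: str
    C: float
    L: int
    M: int
    N: int
    rpkm: float


def compute_rpkm(C: float, L: int, M: int, N: int) -> float:
    """Evaluate C/(L*M*N) * 1e9; undefined when any divisor is zero."""
    if L <= 0 or M <= 0 or N <= 0:
        raise ValueError(f"RPKM undefined for L={L}, M={M}, N={N}")
    if C < 0:
        raise ValueError("negative read count")
    return C / (L * M * N) * 1e9


def compute_n(
    assignments: Iterable[TagAssignment],
    n_admitted: int,
    policy: str = "aligned",
    count_tags: bool = False,
) -> int:
    """Library size N under the configured policy.

    ``count_tags`` switches from read units to collapsed-tag units.
    """
    if policy not in N_POLICIES:
        raise ValueError(f"unknown N policy {policy!r}; choose from {N_POLICIES}")
    if policy == "admitted":
        return n_admitted
    total = 0
    for a in assignments:
        if a.status in (MIRNA, EXCLUDED_MRNA):
            total += 1 if count_tags else a.tag.count
    return total


def quantify_sample(
    assignments: list[TagAssignment],
    ref: ReferenceBundle,
    n_admitted: int,
    n_policy: str = "aligned",
    split_multi_hits: bool = False,
    count_tags: bool = False,
) -> list[MiRNAQuant]:
    """Quantify every annotated miRNA in one sample (C=0 rows included).

    Returns records sorted by RPKM descending, ties by name.
    """
    N = compute_n(assignments, n_admitted, n_policy, count_tags)
    stats = mirna_hit_multiplicity(assignments, ref, split_multi_hits)
    quants = []
    for name in stats:
        m = ref.mirnas[name]
        C = stats[name]["C"]
        M = int(stats[name]["M"])
        rpkm = compute_rpkm(C, m.length, M, N) if N > 0 else 0.0
        quants.append(
            MiRNAQuant(name=name, C=C, L=m.length, M=M, N=max(N, 0), rpkm=rpkm)
        )
    quants.sort(key=lambda q: (-q.rpkm, q.name))
    return quants


def quants_to_frame(quants: list[MiRNAQuant]) -> pd.DataFrame:
    return pd.DataFrame(
        [(q.name, q.C, q.L, q.M, q.N, q.rpkm) for q in quants],
        columns=["name", "C", "L", "M", "N", "RPKM"],
    )


def write_quant_tsv(quants: list[MiRNAQuant], path) -> None:
    df = quants_to_frame(quants)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
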