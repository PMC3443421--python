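"""Tag classification: mRNA exclusion first, then mature-miRNA assignment.

The pipeline's classification order is fixed: a tag whose sequence occurs
anywhere in the mRNA exon database is discarded as a degraded-mRNA
fragment *even if* it would also match a miRNA; only tags that escape
exclusion are matched against the mature-miRNA catalogue.  Matching is
substring containment in either direction (tag within mature sequence,
or mature sequence within tag) at zero mismatches by default, which
covers exact mature reads and modestly extended isomiRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .preprocess import ReadTag
from .reference import ReferenceBundle

__all__ = ["TagAssignment", "classify_tag", "classify_tags", "mirna_hit_multiplicity"]

EXCLUDED_MRNA = "EXCLUDED_MRNA"
MIRNA = "MIRNA"
UNALIGNED = "UNALIGNED"


@dataclass
class TagAssignment:
    tag: ReadTag
    status: str
    hits: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.status == MIRNA) != bool(self.hits):
            raise ValueError("hits must be non-empty exactly when status is MIRNA")

    @property
    def n_mirna_hits(self) -> int:
        return len(self.hits)


def _hamming_le(a: str, b: str, limit: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return False
    return True


def _matches_with_mismatch(tag: str, mature: str, max_mismatch: int) -> bool:
    """Containment in either direction allowing up to max_mismatch substitutions."""
    short, long_ = (tag, mature) if len(tag) <= len(mature) else (mature, tag)
    for i in range(len(long_) - len(short) + 1):
        if _hamming_le(long_[i : i + len(short)], short, max_mismatch):
            return True
    return False


def classify_tag(
    tag: ReadTag, ref: ReferenceBundle, max_mismatch: int = 0
) -> TagAssignment:
    """Classify one tag as EXCLUDED_MRNA, MIRNA (with hit set) or UNALIGNED."""
    seq = tag.seq
    if ref.exon_index.contains_substring(seq):
        return TagAssignment(tag=tag, status=EXCLUDED_MRNA)
    if max_mismatch == 0:
        # tag contained in a mature sequence (index lookup) ...
        hits = set(ref.mature_index.find(seq))
        # ... or a mature sequence contained in the tag
        for m in ref.mirnas.values():
            if m.mature_seq in seq:
                hits.add(m.name)
    else:
        hits = {
            m.name
            for m in ref.mirnas.values()
            if _matches_with_mismatch(seq, m.mature_seq, max_mismatch)
        }
    if hits:
        return TagAssignment(tag=tag, status=MIRNA, hits=frozenset(hits))
    return TagAssignment(tag=tag, status=UNALIGNED)


def classify_tags(
    tags: Iterable[ReadTag], ref: ReferenceBundle, max_mismatch: int = 0
) -> list[TagAssignment]:
    return [classify_tag(t, ref, max_mismatch) for t in tags]


def mirna_hit_multiplicity(
    assignments: Iterable[TagAssignment],
    ref: ReferenceBundle,
    split_multi_hits: bool = False,
) -> dict[str, dict[str, float]]:
    """Aggregate per-miRNA read counts (C) and multi-mapping numbers (M).

    For each annotated miRNA the returned record carries:

    * ``C``  — summed read counts of all tags hitting it.  With
      ``split_multi_hits`` a tag matching several distinct miRNAs
      contributes ``count / n_hits`` to each instead of its full count.
    * ``M``  — the multi-mapping number: the count of distinct annotated
      genomic loci encoding the mature sequence (2 for a mature miRNA
      annotated at two loci), never less than 1.
    * ``n_tags`` — number of distinct tags contributing to C.

    Every annotated miRNA appears in the result, with C = 0 when no tag
    matched it.
    """
    stats: dict[str, dict[str, float]] = {
        m.name: {"C": 0.0, "M": float(m.n_loci), "n_tags": 0}
        for m in ref.mirnas.values()
    }
    for a in assignments:
        if a.status != MIRNA:
            continue
        weight = a.tag.count / a.n_mirna_hits if split_multi_hits else a.tag.count
        for name in a.hits:
            stats[name]["C"] += weight
            stats[name]["n_tags"] += 1
    return stats


def write_assignment_tsv(assignments: Iterable[TagAssignment], path) -> None:
    """Optional per-tag TSV: tag, count, status, hits, n_hits."""
    with open(path, "w") as fh:
        fh.write("#tag\tcount\tstatus\thits\tn_hits\n")
        for a in assignments:
            fh.write(
                f"{a.tag.seq}\t{a.tag.count}\t{a.status}\t"
                f"{','.join(sorted(a.hits))}\t{a.n_mirna_hits}\n"
            )
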