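"""Read admission, 3'-adapter trimming and collapsing to unique tags.

Four admission rules are applied per read, in a fixed order so that every
read receives exactly one fate:

1. poly-A: drop reads with a long A homopolymer run or an extreme
   A fraction (library-prep poly-A artefacts);
2. ambiguous: drop reads containing any ``N``;
3. 5' adapter: drop reads containing the 5'-adapter probe (adapter
   carry-over products have no usable insert);
4. 3' adapter: the insert must be flanked by 6-18 nt of 3'-adapter
   sequence; the flank is trimmed and the remaining insert must fall in
   the configured length window, otherwise the read is rejected.

Admitted inserts are collapsed to unique tags with multiplicity counts.
Quality strings are carried but never used: no base-quality threshold is
applied beyond what the sequencer already enforced.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "RawRead",
    "FilterReport",
    "ReadTag",
    "PreprocessConfig",
    "filter_ambiguous",
    "filter_polyA",
    "filter_5p_adapter",
    "trim_3p_adapter",
    "collapse",
    "preprocess_reads",
    "preprocess_fastq",
    "read_fastq",
    "write_tag_fasta",
]

#: Illumina v1.5 small-RNA adapters, shipped as *replaceable* defaults —
#: the correct adapters depend on the library-prep kit and must be set
#: per dataset.
DEFAULT_ADAPTER3 = "ATCTCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclass(frozen=True)
class RawRead:
    id: str
    seq: str
    qual: str = ""

    def __post_init__(self) -> None:
        if self.qual and len(self.qual) != len(self.seq):
            raise ValueError(f"{self.id}: quality/sequence length mismatch")


@dataclass
class FilterReport:
    """Read-fate accounting: every input read lands in exactly one bucket."""

    n_input: int = 0
    n_polyA_removed: int = 0
    n_ambiguous_removed: int = 0
    n_5p_adapter_removed: int = 0
    n_no_3p_adapter_removed: int = 0
    n_admitted: int = 0

    def check(self) -> None:
        removed = (
            self.n_polyA_removed
            + self.n_ambiguous_removed
            + self.n_5p_adapter_removed
            + self.n_no_3p_adapter_removed
        )
        if self.n_input != self.n_admitted + removed:
            raise AssertionError(
                f"fate partition broken: {self.n_input} != "
                f"{self.n_admitted} + {removed}"
            )

    def to_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass(frozen=True)
class ReadTag:
    """A collapsed unique insert with its per-sample multiplicity."""

    seq: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")


@dataclass
class PreprocessConfig:
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    min_flank: int = 6
    max_flank: int = 18
    insert_min: int = 15
    insert_max: int = 30
    polyA_min_run: int = 10
    polyA_max_frac: float = 0.8
    probe_len: int = 8
    max_mismatch_5p: int = 0

    def __post_init__(self) -> None:
        if len(self.adapter5) < self.probe_len:
            raise ValueError("5' adapter shorter than probe length")
        if len(self.adapter3) < self.min_flank:
            raise ValueError("3' adapter shorter than minimum flank")
        if not (0 < self.min_flank <= self.max_flank):
            raise ValueError("need 0 < min_flank <= max_flank")


def filter_ambiguous(read: RawRead) -> bool:
    """True iff the read is kept (contains no ambiguous base)."""
    return "N" not in read.seq


def filter_polyA(read: RawRead, min_run: int = 10, max_frac_A: float = 0.8) -> bool:
    """True iff the read is kept (no poly-A run and moderate A content)."""
    seq = read.seq
    if "A" * min_run in seq:
        return False
    if seq and seq.count("A") / len(seq) >= max_frac_A:
        return False
    return True


def _contains_approx(seq: str, probe: str, max_mismatch: int) -> bool:
    if max_mismatch == 0:
        return probe in seq
    lp = len(probe)
    for i in range(len(seq) - lp + 1):
        window = seq[i : i + lp]
        mm = sum(a != b for a, b in zip(window, probe))
        if mm <= max_mismatch:
            return True
    return False


def filter_5p_adapter(
    read: RawRead, adapter5: str, probe_len: int = 8, max_mismatch: int = 0
) -> bool:
    """True iff the read is kept (5'-adapter probe not found anywhere)."""
    if len(adapter5) < probe_len:
        raise ValueError("5' adapter shorter than probe length")
    return not _contains_approx(read.seq, adapter5[:probe_len], max_mismatch)


def trim_3p_adapter(
    read: RawRead,
    adapter3: str,
    min_flank: int = 6,
    max_flank: int = 18,
    insert_min: int = 15,
    insert_max: int = 30,
) -> "str | None":
    """Trim the 3'-adapter flank; return the insert, or None to reject.

    The flank is the longest suffix of the read equal to a prefix of the
    adapter.  The read is admitted only when that flank is 6-18 nt
    (configurable) *and* the remaining insert falls inside the insert
    length window.
    """
    seq = read.seq
    upper = min(len(adapter3), len(seq))
    flank = 0
    for lf in range(upper, 0, -1):
        if seq.endswith(adapter3[:lf]):
            flank = lf
            break
    if not (min_flank <= flank <= max_flank):
        return None
    insert = seq[: len(seq) - flank]
    if not (insert_min <= len(insert) <= insert_max):
        return None
    return insert


def collapse(inserts: Iterable[str]) -> list[ReadTag]:
    """Collapse identical inserts into counted tags, lexicographic order."""
    counts = Counter(inserts)
    return [ReadTag(seq=s, count=c) for s, c in sorted(counts.items())]


def _classify_unique(seq: str, cfg: PreprocessConfig) -> tuple[str, "str | None"]:
    """Fate of one (already uppercased) sequence: (bucket, insert-or-None)."""
    read = RawRead("u", seq)
    if not filter_polyA(read, cfg.polyA_min_run, cfg.polyA_max_frac):
        return "polyA", None
    if not filter_ambiguous(read):
        return "ambiguous", None
    if not filter_5p_adapter(read, cfg.adapter5, cfg.probe_len, cfg.max_mismatch_5p):
        return "adapter5", None
    insert = trim_3p_adapter(
        read, cfg.adapter3, cfg.min_flank, cfg.max_flank, cfg.insert_min, cfg.insert_max
    )
    if insert is None:
        return "no_adapter3", None
    return "admitted", insert


def preprocess_reads(
    reads: Iterable[RawRead], cfg: "PreprocessConfig | None" = None
) -> tuple[list[ReadTag], FilterReport]:
    """Apply the admission rules, trim, and collapse a read stream.

    Identical raw sequences necessarily share a fate, so the stream is
    collapsed up front and each distinct sequence is judged once; the
    report weights every fate by multiplicity.  Output is therefore
    independent of input order.
    """
    cfg = cfg or PreprocessConfig()
    raw_counts = Counter(r.seq.upper() for r in reads)
    report = FilterReport(n_input=sum(raw_counts.values()))
    bucket_attr = {
        "polyA": "n_polyA_removed",
        "ambiguous": "n_ambiguous_removed",
        "adapter5": "n_5p_adapter_removed",
        "no_adapter3": "n_no_3p_adapter_removed",
    }
    insert_counts: Counter[str] = Counter()
    for seq, n in raw_counts.items():
        fate, insert = _classify_unique(seq, cfg)
        if fate == "admitted":
            report.n_admitted += n
            insert_counts[insert] += n
        else:
            setattr(report, bucket_attr[fate], getattr(report, bucket_attr[fate]) + n)
    report.check()
    tags = [ReadTag(seq=s, count=c) for s, c in sorted(insert_counts.items())]
    return tags, report


def read_fastq(path) -> Iterator[RawRead]:
    """Stream a FASTQ file (plain or gzip) as RawRead records."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # '+'
            qual = fh.readline().strip()
            yield RawRead(id=header.strip().lstrip("@"), seq=seq.upper(), qual=qual)


def preprocess_fastq(
    path, cfg: "PreprocessConfig | None" = None
) -> tuple[list[ReadTag], FilterReport]:
    return preprocess_reads(read_fastq(path), cfg)


def write_tag_fasta(tags: list[ReadTag], path) -> None:
    """Write collapsed tags in the ``>tag_<i>_x<count>`` FASTA dialect."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag_{i}_x{tag.count}\n{tag.seq}\n")
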