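"""Mature-miRNA annotation, sequence databases and exact-substring indexing.

The quantification pipeline needs three reference objects:

* the catalogue of mature miRNAs (name, one or more genomic loci, mature
  sequence) against which trimmed read tags are matched;
* an mRNA exon sequence set used to *exclude* degraded-mRNA fragments
  before miRNA assignment;
* optionally the genome itself, used only to extract mature sequences
  when no mature-sequence FASTA is supplied.

All sequences are normalised to the uppercase DNA alphabet (U -> T) on
load, and all comparisons happen in DNA space.  Genomic coordinates are
stored 0-based half-open; 1-based inclusive coordinates (GFF3, printed
browser-style strings such as ``chr9:21512157-21512177``) are converted
on input.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicInterval",
    "MatureMiRNA",
    "SubstringIndex",
    "ReferenceBundle",
    "load_mirna_annotation",
    "load_exclusion_db",
    "parse_location",
]

#: longest span accepted for a mature-miRNA locus (mature miRNAs are
#: 18-24 nt; a little slack is left for annotation quirks).
MAX_MIRNA_SPAN = 35

_LOCATION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def normalize_seq(seq: str) -> str:
    """Uppercase and map RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open, stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def as_printed(self) -> str:
        """Render as a 1-based inclusive browser-style string."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"


def parse_location(text: str, strand: str = "+") -> GenomicInterval:
    """Parse a browser-style ``chrom:start-end`` string (1-based inclusive)."""
    m = _LOCATION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed location string: {text!r}")
    return GenomicInterval(
        m["chrom"], int(m["start"]) - 1, int(m["end"]), strand
    )


@dataclass
class MatureMiRNA:
    """A named mature miRNA with its mature sequence and >=1 genomic loci.

    The mature length supplies ``L`` in the RPKM statistic and the locus
    count supplies the multi-mapping number ``M``: a mature sequence
    encoded at two loci (e.g. hsa-mir-29b on chr7 and chr1) is one entry
    with ``n_loci == 2``.
    """

    name: str
    mature_seq: str
    loci: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mature_seq = normalize_seq(self.mature_seq)
        if not self.loci:
            raise ValueError(f"{self.name}: at least one locus required")
        for iv in self.loci:
            if len(iv) > MAX_MIRNA_SPAN:
                raise ValueError(
                    f"{self.name}: locus {iv.as_printed()} longer than "
                    f"{MAX_MIRNA_SPAN} nt"
                )
            if abs(len(iv) - len(self.mature_seq)) > 2:
                raise ValueError(
                    f"{self.name}: locus span {len(iv)} inconsistent with "
                    f"mature length {len(self.mature_seq)}"
                )

    @property
    def length(self) -> int:
        return len(self.mature_seq)

    @property
    def n_loci(self) -> int:
        return len(self.loci)


class SubstringIndex:
    """Exact-substring lookup over a set of named sequences.

    Seeds queries with a k-mer hash (default k=12) and verifies candidate
    positions by direct slicing, so lookups are exactly equivalent to a
    brute-force scan; queries shorter than k fall back to the scan.
    """

    def __init__(self, k: int = 12) -> None:
        self.k = k
        self._seqs: dict[str, str] = {}
        self._kmers: dict[str, list[tuple[str, int]]] = {}

    def add(self, name: str, seq: str) -> None:
        seq = normalize_seq(seq)
        self._seqs[name] = seq
        k = self.k
        for i in range(len(seq) - k + 1):
            self._kmers.setdefault(seq[i : i + k], []).append((name, i))

    def __len__(self) -> int:
        return len(self._seqs)

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def sequences(self) -> dict[str, str]:
        return dict(self._seqs)

    def find(self, query: str) -> set[str]:
        """Names of all indexed sequences containing ``query`` as a substring."""
        query = normalize_seq(query)
        if not query:
            return set()
        if len(query) < self.k:
            return {n for n, s in self._seqs.items() if query in s}
        hits: set[str] = set()
        for name, pos in self._kmers.get(query[: self.k], ()):
            if name in hits:
                continue
            if self._seqs[name][pos : pos + len(query)] == query:
                hits.add(name)
        return hits

    def contains_substring(self, query: str) -> bool:
        return bool(self.find(query))


@dataclass
class ReferenceBundle:
    """The indexed reference state the aligner classifies tags against."""

    mirnas: dict[str, MatureMiRNA]
    exon_index: SubstringIndex
    mature_index: SubstringIndex
    genome_seqs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        mirnas: dict[str, MatureMiRNA],
        exon_seqs: dict[str, str] | None = None,
        genome_seqs: dict[str, str] | None = None,
        k: int = 12,
    ) -> "ReferenceBundle":
        exon_index = SubstringIndex(k=k)
        for name, seq in (exon_seqs or {}).items():
            exon_index.add(name, seq)
        mature_index = SubstringIndex(k=k)
        for m in mirnas.values():
            mature_index.add(m.name, m.mature_seq)
        return cls(mirnas, exon_index, mature_index, dict(genome_seqs or {}))


def _read_fasta(path) -> dict[str, str]:
    return {
        rec.id: normalize_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    }


def _parse_gff3(path) -> list[tuple[str, GenomicInterval]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for feat in db.all_features():
        attrs = feat.attributes
        name = (attrs.get("Name") or attrs.get("ID") or [None])[0]
        if name is None:
            raise ValueError(f"GFF3 feature without Name/ID at line: {feat}")
        # GFF3 is 1-based inclusive
        out.append(
            (name, GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand))
        )
    return out


def _parse_bed(path) -> list[tuple[str, GenomicInterval]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED needs 6 columns, got {len(fields)}"
                )
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
            out.append((fields[3], iv))
    return out


def load_mirna_annotation(
    annotation_path,
    mature_fasta: "str | None" = None,
    genome_fasta: "str | None" = None,
) -> dict[str, MatureMiRNA]:
    """Load a mature-miRNA catalogue from GFF3/BED plus sequence FASTA.

    Records sharing a name are merged into one :class:`MatureMiRNA` with
    multiple loci.  Mature sequences come from ``mature_fasta`` (record id
    == miRNA name) when given; otherwise they are extracted from
    ``genome_fasta`` at the annotated interval, reverse-complemented on
    the minus strand.  A miRNA whose sequence cannot be resolved is a
    hard error.
    """
    path = str(annotation_path)
    if path.endswith((".gff", ".gff3")):
        records = _parse_gff3(path)
    elif path.endswith(".bed"):
        records = _parse_bed(path)
    else:
        raise ValueError(f"unrecognised annotation format: {path}")

    mature_seqs = _read_fasta(mature_fasta) if mature_fasta else {}
    genome = _read_fasta(genome_fasta) if genome_fasta else {}

    loci_by_name: dict[str, list[GenomicInterval]] = {}
    for name, iv in records:
        loci_by_name.setdefault(name, []).append(iv)

    mirnas: dict[str, MatureMiRNA] = {}
    for name, loci in loci_by_name.items():
        loci = sorted(set(loci))
        if name in mature_seqs:  # mature FASTA takes precedence
            seq = mature_seqs[name]
        else:
            iv = loci[0]
            if iv.chrom not in genome:
                raise ValueError(
                    f"no mature sequence for {name!r}: not in mature FASTA and "
                    f"chromosome {iv.chrom!r} not in genome FASTA"
                )
            seq = genome[iv.chrom][iv.start : iv.end]
            if iv.strand == "-":
                seq = str(Seq(seq).reverse_complement())
        mirnas[name] = MatureMiRNA(name=name, mature_seq=seq, loci=loci)
    return mirnas


def load_exclusion_db(fasta_path, k: int = 12) -> SubstringIndex:
    """Load the mRNA exon exclusion database into a substring index.

    An empty FASTA produces an empty index (the exclusion step becomes a
    no-op) with a warning rather than an error.
    """
    idx = SubstringIndex(k=k)
    for name, seq in _read_fasta(fasta_path).items():
        idx.add(name, seq)
    if len(idx) == 0:
        warnings.warn(
            f"exclusion database {fasta_path} is empty; mRNA exclusion disabled",
            stacklevel=2,
        )
    return idx


def write_mirna_annotation(mirnas: dict[str, MatureMiRNA], bed_path, fasta_path) -> None:
    """Serialise a catalogue back to 6-column BED plus mature FASTA."""
    rows = []
    for m in sorted(mirnas.values(), key=lambda x: x.name):
        for iv in m.loci:
            rows.append((iv.chrom, iv.start, iv.end, m.name, 0, iv.strand))
    pd.DataFrame(rows).to_csv(bed_path, sep="\t", header=False, index=False)
    with open(fasta_path, "w") as fh:
        for m in sorted(mirnas.values(), key=lambda x: x.name):
            fh.write(f">{m.name}\n{m.mature_seq}\n")
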