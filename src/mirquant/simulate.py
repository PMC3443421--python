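"""Synthetic smRNA-seq data with known truth for end-to-end validation.

The generator builds a toy reference (random mature miRNAs, some encoded
at two genomic loci, plus decoy-free exon sequences) and then samples
reads from the library classes the preprocessing filters target:

* miRNA reads — exact mature sequence followed by a uniform-random
  6-18 nt prefix of the 3' adapter (the admissible flank range);
* poly-A contaminants — reads dominated by adenine runs;
* ambiguous reads — reads containing at least one ``N``;
* 5'-adapter carry-over — reads containing the 5'-adapter probe;
* degraded-mRNA fragments — exon substrings with a valid 3' flank,
  admitted by preprocessing but excluded at alignment;
* unaligned filler — random inserts matching nothing.

Read classes are drawn from one multinomial per sample and generated
mutually exclusively (a poly-A read never also carries an ``N``), so the
filter report can be predicted exactly from the truth table.  Qualities
are constant high values; the pipeline never reads them.

Everything is driven by a single integer seed: the same config and seed
reproduce byte-identical FASTQ, annotation and truth files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5, PreprocessConfig
from .reference import GenomicInterval, MatureMiRNA, ReferenceBundle

__all__ = ["SimConfig", "SimTruth", "make_reference", "simulate_fastq", "simulate_pair"]

_BASES = np.array(list("ACGT"))

READ_CLASS_MIRNA = "mirna"
READ_CLASS_POLYA = "polyA"
READ_CLASS_AMBIG = "ambiguous"
READ_CLASS_5P = "adapter5"
READ_CLASS_MRNA = "mrna_fragment"
READ_CLASS_UNALIGNED = "unaligned"
READ_CLASS_BAD_FLANK = "bad_flank"


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic generator.

    Defaults model a small-RNA library in which three quarters of the
    reads are genuine miRNA inserts and one fifth are the contaminant
    classes the admission filters remove or the exclusion step discards.
    """

    n_mirnas: int = 20
    n_multilocus: int = 2
    n_exons: int = 30
    exon_len: int = 120
    reads_per_sample: int = 50_000
    abundance_a: "np.ndarray | None" = None
    abundance_b: "np.ndarray | None" = None
    mirna_fraction: float = 0.75
    contaminant_fractions: dict = field(
        default_factory=lambda: {
            READ_CLASS_POLYA: 0.05,
            READ_CLASS_AMBIG: 0.03,
            READ_CLASS_5P: 0.04,
            READ_CLASS_MRNA: 0.08,
        }
    )
    bad_flank_fraction: float = 0.0  # adversarial: flanks of 5 or 19 nt
    flank_min: int = 6
    flank_max: int = 18
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_multilocus <= self.n_mirnas):
            raise ValueError("need 0 <= n_multilocus <= n_mirnas")
        total = (
            self.mirna_fraction
            + sum(self.contaminant_fractions.values())
            + self.bad_flank_fraction
        )
        if total > 1 + 1e-9:
            raise ValueError(f"class fractions sum to {total} > 1")

    def class_probs(self) -> dict[str, float]:
        probs = {READ_CLASS_MIRNA: self.mirna_fraction}
        probs.update(self.contaminant_fractions)
        if self.bad_flank_fraction:
            probs[READ_CLASS_BAD_FLANK] = self.bad_flank_fraction
        probs[READ_CLASS_UNALIGNED] = max(0.0, 1.0 - sum(probs.values()))
        return probs


@dataclass
class SimTruth:
    """Ground truth for one simulated sample."""

    mirna_counts: dict[str, int]
    class_counts: dict[str, int]
    read_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [("mirna:" + k, v) for k, v in sorted(self.mirna_counts.items())]
        rows += [("class:" + k, v) for k, v in sorted(self.class_counts.items())]
        return pd.DataFrame(rows, columns=["key", "count"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _acceptable_insert(seq: str, cfg: SimConfig, pre: PreprocessConfig) -> bool:
    """True when a sequence survives the admission rules as an insert."""
    if "A" * pre.polyA_min_run in seq:
        return False
    if seq.count("A") / len(seq) >= pre.polyA_max_frac:
        return False
    if cfg.adapter5[: pre.probe_len] in seq:
        return False
    return True


def make_reference(
    cfg: SimConfig,
    rng: "np.random.Generator | None" = None,
    decoy: bool = False,
    max_tries: int = 10_000,
) -> ReferenceBundle:
    """Build a toy reference bundle under the simulation config.

    Mature sequences (18-24 nt) are rejection-sampled to be pairwise
    non-substring, free of admission-filter trigger motifs and absent
    from every exon; the first ``n_multilocus`` miRNAs are planted at two
    genomic loci.  With ``decoy=True`` one extra exon embedding the first
    mature sequence is added, for exclusion-precedence experiments.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    pre = PreprocessConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5)

    matures: list[str] = []
    tries = 0
    while len(matures) < cfg.n_mirnas:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "rejection sampling budget exhausted; lower n_mirnas/n_exons"
            )
        cand = _random_seq(rng, int(rng.integers(18, 25)))
        if not _acceptable_insert(cand, cfg, pre):
            continue
        if any(cand in m or m in cand for m in matures):
            continue
        matures.append(cand)

    exons: dict[str, str] = {}
    tries = 0
    while len(exons) < cfg.n_exons:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("rejection sampling budget exhausted for exons")
        seq = _random_seq(rng, cfg.exon_len)
        if any(m in seq for m in matures):
            continue
        exons[f"exon_{len(exons) + 1}"] = seq

    mirnas: dict[str, MatureMiRNA] = {}
    pos = 1000
    for i, seq in enumerate(matures):
        name = f"sim-mir-{i + 1}"
        n_loci = 2 if i < cfg.n_multilocus else 1
        loci = []
        for j in range(n_loci):
            chrom = f"chrS{j + 1}"
            loci.append(GenomicInterval(chrom, pos, pos + len(seq), "+"))
            pos += 100
        mirnas[name] = MatureMiRNA(name=name, mature_seq=seq, loci=loci)

    if decoy:
        host = _random_seq(rng, cfg.exon_len)
        mid = cfg.exon_len // 2
        exons["exon_decoy"] = host[:mid] + matures[0] + host[mid:]

    return ReferenceBundle.build(mirnas, exon_seqs=exons)


def _default_abundance(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal relative abundances normalised to the miRNA fraction."""
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_mirnas)
    return raw / raw.sum() * cfg.mirna_fraction


def _make_read(
    cls: str,
    cfg: SimConfig,
    pre: PreprocessConfig,
    bundle: ReferenceBundle,
    mature_names: list[str],
    mirna_idx: int,
    rng: np.random.Generator,
) -> str:
    adapter3 = cfg.adapter3
    if cls == READ_CLASS_MIRNA:
        flank = int(rng.integers(cfg.flank_min, cfg.flank_max + 1))
        return bundle.mirnas[mature_names[mirna_idx]].mature_seq + adapter3[:flank]
    if cls == READ_CLASS_BAD_FLANK:
        name = mature_names[int(rng.integers(len(mature_names)))]
        flank = cfg.flank_min - 1 if rng.random() < 0.5 else cfg.flank_max + 1
        return bundle.mirnas[name].mature_seq + adapter3[:flank]
    if cls == READ_CLASS_POLYA:
        n_tail = int(rng.integers(12, 20))
        head = _random_seq(rng, int(rng.integers(10, 20)))
        return head + "A" * n_tail
    if cls == READ_CLASS_AMBIG:
        while True:
            seq = list(_random_seq(rng, int(rng.integers(25, 40))))
            seq[int(rng.integers(len(seq)))] = "N"
            seq = "".join(seq)
            if "A" * pre.polyA_min_run not in seq:
                return seq
    if cls == READ_CLASS_5P:
        probe = cfg.adapter5[: pre.probe_len]
        while True:
            tail = _random_seq(rng, int(rng.integers(15, 25)))
            seq = probe + tail
            if "A" * pre.polyA_min_run not in seq:
                return seq
    if cls == READ_CLASS_MRNA:
        exon_names = sorted(bundle.exon_index.sequences())
        while True:
            exon = bundle.exon_index.sequences()[
                exon_names[int(rng.integers(len(exon_names)))]
            ]
            ln = int(rng.integers(18, 25))
            start = int(rng.integers(0, len(exon) - ln + 1))
            frag = exon[start : start + ln]
            if _acceptable_insert(frag, cfg, pre):
                flank = int(rng.integers(cfg.flank_min, cfg.flank_max + 1))
                return frag + adapter3[:flank]
    if cls == READ_CLASS_UNALIGNED:
        matures = [m.mature_seq for m in bundle.mirnas.values()]
        while True:
            ins = _random_seq(rng, int(rng.integers(18, 25)))
            if not _acceptable_insert(ins, cfg, pre):
                continue
            if bundle.exon_index.contains_substring(ins):
                continue
            if any(ins in m or m in ins for m in matures):
                continue
            flank = int(rng.integers(cfg.flank_min, cfg.flank_max + 1))
            return ins + adapter3[:flank]
    raise ValueError(f"unknown read class {cls!r}")


def simulate_sample(
    cfg: SimConfig,
    bundle: ReferenceBundle,
    abundance: "np.ndarray | None",
    rng: np.random.Generator,
) -> tuple[list[str], SimTruth]:
    """Draw one sample's reads; returns (sequences, truth)."""
    pre = PreprocessConfig(adapter3=cfg.adapter3, adapter5=cfg.adapter5)
    mature_names = sorted(bundle.mirnas)
    if abundance is None:
        abundance = _default_abundance(cfg, rng)
    abundance = np.asarray(abundance, dtype=float)
    if len(abundance) != cfg.n_mirnas:
        raise ValueError("abundance vector length != n_mirnas")
    mirna_total = float(abundance.sum())

    class_probs = cfg.class_probs()
    class_probs[READ_CLASS_MIRNA] = mirna_total
    class_probs[READ_CLASS_UNALIGNED] = max(
        0.0, 1.0 - sum(v for k, v in class_probs.items() if k != READ_CLASS_UNALIGNED)
    )
    classes = sorted(class_probs)
    probs = np.array([class_probs[c] for c in classes])
    probs = probs / probs.sum()

    labels: list[str] = []
    seqs: list[str] = []
    mirna_counts = {n: 0 for n in mature_names}
    class_counts = {c: 0 for c in classes}
    draw = rng.choice(len(classes), size=cfg.reads_per_sample, p=probs)
    p_mirna = abundance / mirna_total if mirna_total > 0 else abundance
    which_mirna = rng.choice(cfg.n_mirnas, size=cfg.reads_per_sample, p=p_mirna if mirna_total > 0 else None)
    for i in range(cfg.reads_per_sample):
        cls = classes[draw[i]]
        idx = int(which_mirna[i])
        seqs.append(_make_read(cls, cfg, pre, bundle, mature_names, idx, rng))
        labels.append(cls)
        class_counts[cls] += 1
        if cls == READ_CLASS_MIRNA:
            mirna_counts[mature_names[idx]] += 1
    return seqs, SimTruth(mirna_counts, class_counts, labels)


def write_fastq(seqs: list[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(seqs, start=1):
            fh.write(f"@{prefix}_{i}\n{s}\n+\n{'I' * len(s)}\n")


def simulate_fastq(
    cfg: SimConfig,
    bundle: ReferenceBundle,
    rng: "np.random.Generator | None" = None,
    abundance: "np.ndarray | None" = None,
    fastq_path=None,
    truth_path=None,
) -> tuple[list[str], SimTruth]:
    """Simulate one sample, optionally writing FASTQ and truth TSV."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    seqs, truth = simulate_sample(cfg, bundle, abundance, rng)
    if fastq_path is not None:
        write_fastq(seqs, fastq_path)
    if truth_path is not None:
        truth.write(truth_path)
    return seqs, truth


def simulate_pair(
    cfg: SimConfig,
    outdir=None,
    abundance_a: "np.ndarray | None" = None,
    abundance_b: "np.ndarray | None" = None,
) -> dict:
    """Simulate a two-condition experiment (A and B) from one seed.

    Returns a dict with the bundle, per-sample sequences and truths, and
    the file paths when ``outdir`` is given.
    """
    rng = np.random.default_rng(cfg.seed)
    bundle = make_reference(cfg, rng)
    if abundance_a is None:
        abundance_a = cfg.abundance_a
    if abundance_b is None:
        abundance_b = cfg.abundance_b
    if abundance_a is None:
        abundance_a = _default_abundance(cfg, rng)
    if abundance_b is None:
        abundance_b = _default_abundance(cfg, rng)
    out: dict = {"bundle": bundle}
    for label, ab in (("a", abundance_a), ("b", abundance_b)):
        seqs, truth = simulate_sample(cfg, bundle, ab, rng)
        out[f"seqs_{label}"] = seqs
        out[f"truth_{label}"] = truth
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .reference import write_mirna_annotation

        write_mirna_annotation(
            bundle.mirnas, outdir / "mirnas.bed", outdir / "mature.fa"
        )
        with open(outdir / "exons.fa", "w") as fh:
            for name, seq in sorted(bundle.exon_index.sequences().items()):
                fh.write(f">{name}\n{seq}\n")
        for label in ("a", "b"):
            write_fastq(out[f"seqs_{label}"], outdir / f"sample_{label}.fastq")
            out[f"truth_{label}"].write(outdir / f"truth_{label}.tsv")
        out["outdir"] = outdir
    return out


def truth_quants(
    truth: SimTruth, bundle: ReferenceBundle, n_policy: str = "aligned"
):
    """Truth-derived per-miRNA quantification via the quantification module.

    Under the default ``aligned`` N policy the truth library size is the
    number of reads drawn from reference sequences: miRNA reads plus
    degraded-mRNA fragments.
    """
    from .quantify import MiRNAQuant, compute_rpkm

    n_mirna = sum(truth.mirna_counts.values())
    if n_policy == "aligned":
        N = n_mirna + truth.class_counts.get(READ_CLASS_MRNA, 0)
    else:
        N = (
            n_mirna
            + truth.class_counts.get(READ_CLASS_MRNA, 0)
            + truth.class_counts.get(READ_CLASS_UNALIGNED, 0)
        )
    quants = []
    for name, C in truth.mirna_counts.items():
        m = bundle.mirnas[name]
        rpkm = compute_rpkm(C, m.length, m.n_loci, N) if N else 0.0
        quants.append(MiRNAQuant(name, float(C), m.length, m.n_loci, N, rpkm))
    quants.sort(key=lambda q: (-q.rpkm, q.name))
    return quants
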