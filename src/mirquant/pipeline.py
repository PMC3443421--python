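"""End-to-end orchestration: reference load, preprocess, align, quantify, call.

One :func:`run_pipeline` call takes a two-condition experiment (one
FASTQ per condition plus reference files) to the pair of differential
tables, writing per-sample filter reports, quantification tables, both
differential tables and a metadata sidecar recording every threshold and
policy in force, so any run is reproducible from its output directory
alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .align import classify_tags
from .differential import DiffConfig, call_differential, write_diff_tables
from .preprocess import PreprocessConfig, preprocess_fastq
from .quantify import quantify_sample, write_quant_tsv
from .reference import ReferenceBundle, load_exclusion_db, load_mirna_annotation

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    fastq_a: str
    fastq_b: str
    annotation: str
    mature_fasta: "str | None" = None
    genome_fasta: "str | None" = None
    exon_fasta: "str | None" = None
    outdir: str = "mirquant_out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)
    n_policy: str = "aligned"
    split_multi_hits: bool = False
    count_tags: bool = False
    max_mismatch: int = 0
    seed: "int | None" = None

    def validate(self) -> None:
        for attr in ("fastq_a", "fastq_b", "annotation", "mature_fasta",
                     "genome_fasta", "exon_fasta"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{attr}: {path} does not exist")
        if self.mature_fasta is None and self.genome_fasta is None:
            raise ValueError("need a mature-sequence FASTA or a genome FASTA")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        diff = DiffConfig(**raw.pop("diff", {}))
        return cls(preprocess=pre, diff=diff, **raw)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _process_sample(label: str, fastq, bundle, cfg: RunConfig, outdir: Path):
    tags, report = preprocess_fastq(fastq, cfg.preprocess)
    assignments = classify_tags(tags, bundle, cfg.max_mismatch)
    quants = quantify_sample(
        assignments,
        bundle,
        report.n_admitted,
        n_policy=cfg.n_policy,
        split_multi_hits=cfg.split_multi_hits,
        count_tags=cfg.count_tags,
    )
    with open(outdir / f"filter_report_{label}.tsv", "w") as fh:
        fh.write("#metric\tcount\n")
        for k, v in report.to_dict().items():
            fh.write(f"{k}\t{v}\n")
    write_quant_tsv(quants, outdir / f"quant_{label}.tsv")
    return tags, report, assignments, quants


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full two-condition analysis; returns the in-memory results.

    Side effects: filter reports, per-sample quantification TSVs, the two
    differential tables and ``run_metadata.json`` under ``cfg.outdir``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mirnas = load_mirna_annotation(cfg.annotation, cfg.mature_fasta, cfg.genome_fasta)
    exon_index_seqs = {}
    if cfg.exon_fasta is not None:
        exon_index_seqs = load_exclusion_db(cfg.exon_fasta).sequences()
    bundle = ReferenceBundle.build(mirnas, exon_seqs=exon_index_seqs)

    results: dict = {"bundle": bundle}
    for label, fastq in (("a", cfg.fastq_a), ("b", cfg.fastq_b)):
        tags, report, assignments, quants = _process_sample(
            label, fastq, bundle, cfg, outdir
        )
        results[f"tags_{label}"] = tags
        results[f"report_{label}"] = report
        results[f"assignments_{label}"] = assignments
        results[f"quants_{label}"] = quants

    records = call_differential(results["quants_a"], results["quants_b"], cfg.diff)
    results["diff_records"] = records
    write_diff_tables(
        records,
        outdir / "diff_b_enriched.tsv",
        outdir / "diff_a_enriched.tsv",
    )

    meta = {
        "mirquant_version": __version__,
        "config": cfg.to_jsonable(),
        "n_mirnas": len(bundle.mirnas),
        "N_a": results["quants_a"][0].N if results["quants_a"] else 0,
        "N_b": results["quants_b"][0].N if results["quants_b"] else 0,
        "n_called": sum(r.called for r in records),
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    results["metadata"] = meta
    return results
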