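"""End-to-end orchestration: model build → scan → link → filter → profile.

The run report mirrors the stage-wise bookkeeping of the analysis: raw
hit counts, promoter-restricted counts, phylum-filtered counts, gene and
COG tallies, and the final list of prototypical regulon COGs, together
with every effective parameter.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .annotation import (
    DEFAULT_ALLOWED_PHYLA,
    AnnotationTable,
    attach_cogs,
    filter_by_phylum,
)
from .genes import (
    filter_promoter_sites,
    infer_operons,
    link_sites_to_genes,
    read_genes_gff3,
    read_genes_tsv,
    write_links_tsv,
)
from .motif import ScoringModel, SiteCollection, build_scoring_model
from .regulon import ClassifierConfig, profile_cogs, profiles_to_frame
from .scan import read_contigs, scan_metagenome, write_hits_gff3, write_hits_tsv

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    sites_path: str
    contigs_path: str
    genes_path: str
    out_dir: str = "metaregulon_out"
    annotations_path: str | None = None  # defaults to gene-table labels
    pseudocount: float = 0.0
    small_sample_correction: bool = False
    sd_mode: str = "population"
    threshold: float | str = "auto"  # auto = collection mean − 1.5 SD
    upstream: int = 300
    downstream: int = 50
    gap_max: int = 100
    allowed_phyla: tuple[str, ...] = tuple(sorted(DEFAULT_ALLOWED_PHYLA))
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cls_kwargs = dict(raw)
        if "classifier" in cls_kwargs:
            cls_kwargs["classifier"] = ClassifierConfig(**cls_kwargs["classifier"])
        if "allowed_phyla" in cls_kwargs:
            cls_kwargs["allowed_phyla"] = tuple(cls_kwargs["allowed_phyla"])
        return cls(**cls_kwargs)

    def validate(self) -> None:
        for name in ("sites_path", "contigs_path", "genes_path"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such file {p!r}")
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ValueError(f"threshold must be 'auto' or a number")


@dataclass
class RunReport:
    params: dict[str, Any]
    threshold: float
    counts: dict[str, int]
    prototypical_cogs: list[str]
    outputs: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    def to_text(self) -> str:
        lines = ["metaregulon run report", "=" * 30]
        lines.append(f"scan threshold: {self.threshold:.4f} bits")
        for k, v in self.counts.items():
            lines.append(f"{k:>28s}: {v}")
        lines.append(
            "prototypical COGs: "
            + (", ".join(self.prototypical_cogs) or "(none)")
        )
        return "\n".join(lines) + "\n"


def run_all(cfg: RunConfig) -> RunReport:
    """Execute the whole pipeline; any stage error aborts with its name."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            raise StageError(name, exc) from exc

    collection = stage(
        "load-sites",
        lambda p: SiteCollection.from_fasta(p)
        if Path(p).suffix in (".fa", ".fasta", ".fna")
        else SiteCollection.from_text(p),
        cfg.sites_path,
    )
    model = stage(
        "build-model",
        build_scoring_model,
        collection,
        pseudocount=cfg.pseudocount,
        small_sample_correction=cfg.small_sample_correction,
        sd_mode=cfg.sd_mode,
    )
    model.write(out / "model_matrix.tsv", out / "model_meta.json")

    threshold = (
        model.threshold if cfg.threshold == "auto" else float(cfg.threshold)
    )
    contigs = stage("load-contigs", read_contigs, cfg.contigs_path)
    contig_lengths = {c.id: len(c.seq) for c in contigs}
    scan_result = stage("scan", scan_metagenome, model, contigs, threshold)
    write_hits_tsv(scan_result.hits, out / "hits.tsv")
    write_hits_gff3(scan_result.hits, out / "hits.gff3")

    genes = stage(
        "load-genes",
        read_genes_gff3 if str(cfg.genes_path).endswith(("gff", "gff3")) else read_genes_tsv,
        cfg.genes_path,
    )
    operons = stage("infer-operons", infer_operons, genes, cfg.gap_max)
    links = stage(
        "link",
        link_sites_to_genes,
        scan_result.hits,
        genes,
        upstream=cfg.upstream,
        downstream=cfg.downstream,
        contig_lengths=contig_lengths,
    )
    promoter_links = stage("promoter-filter", filter_promoter_sites, links)

    table = (
        stage("load-annotations", AnnotationTable.from_tsv, cfg.annotations_path)
        if cfg.annotations_path
        else AnnotationTable.from_genes(genes)
    )
    phylum_result = stage(
        "phylum-filter",
        filter_by_phylum,
        promoter_links,
        table,
        set(cfg.allowed_phyla),
    )
    decorated = stage("attach-cogs", attach_cogs, phylum_result.kept, table)
    write_links_tsv(decorated.links, out / "filtered_links.tsv")

    profiles = stage("profile", profile_cogs, decorated.links, cfg.classifier)
    profiles_to_frame(profiles).to_csv(out / "cog_profiles.tsv", sep="\t", index=False)
    prototypical = sorted(
        cog for cog, p in profiles.items() if p.prototypical
    )

    counts = {
        "contigs": len(contigs),
        "genes": len(genes),
        "operons": len(operons),
        "raw_sites": len(scan_result.hits),
        "windows_skipped": scan_result.summary.windows_skipped,
        "linked_sites": len(links),
        "promoter_sites": len(promoter_links),
        "phylum_filtered_sites": len(phylum_result.kept),
        "cog_annotated_sites": sum(1 for ln in decorated.links if ln.cog_id),
        "cogs_profiled": len(profiles),
        "prototypical_cogs": len(prototypical),
    }
    params = {
        "pseudocount": cfg.pseudocount,
        "small_sample_correction": cfg.small_sample_correction,
        "sd_mode": cfg.sd_mode,
        "threshold_mode": cfg.threshold,
        "upstream": cfg.upstream,
        "downstream": cfg.downstream,
        "gap_max": cfg.gap_max,
        "allowed_phyla": list(cfg.allowed_phyla),
        "classifier": asdict(cfg.classifier),
        "seed": cfg.seed,
    }
    report = RunReport(
        params=params,
        threshold=float(threshold),
        counts=counts,
        prototypical_cogs=prototypical,
        outputs={
            "model_matrix": str(out / "model_matrix.tsv"),
            "hits_tsv": str(out / "hits.tsv"),
            "filtered_links": str(out / "filtered_links.tsv"),
            "cog_profiles": str(out / "cog_profiles.tsv"),
        },
    )
    report.to_json(out / "report.json")
    (out / "report.txt").write_text(report.to_text())
    logger.info("run complete: %s", counts)
    return report
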