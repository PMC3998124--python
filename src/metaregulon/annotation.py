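"""Taxonomic filtering and COG decoration of site–gene links.

The annotation table plays the role of a homology-based typing step: it
maps each gene id to a best-hit protein, a COG id, a one-letter COG
functional category and a phylum.  Links are kept only when the gene's
phylum belongs to the allowed set (by default the Gram-positive phyla
Firmicutes and Actinobacteria, where the scanned motif is conserved);
genes absent from the table count as unannotated and are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genes import GeneRecord, SiteGeneLink

logger = logging.getLogger(__name__)

DEFAULT_ALLOWED_PHYLA = frozenset({"Firmicutes", "Actinobacteria"})

#: Controlled vocabulary for phylum labels.
KNOWN_PHYLA = (
    "Firmicutes",
    "Actinobacteria",
    "Bacteroidetes",
    "Proteobacteria",
    "Verrucomicrobia",
    "Fusobacteria",
)

#: One-letter COG functional categories.
COG_CATEGORIES = "ABCDEFGHIJKLMNOPQRSTUVWYZ"


@dataclass(frozen=True)
class AnnotationTable:
    """gene_id → (best_hit_protein, cog_id, cog_category, phylum)."""

    frame: pd.DataFrame  # indexed by gene_id

    COLUMNS = ("gene_id", "best_hit_protein", "cog_id", "cog_category", "phylum")

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()][:5]
            raise ValueError(f"duplicate gene ids in annotation table: {list(dupes)}")

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str, str, str]]
    ) -> "AnnotationTable":
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(df.set_index("gene_id"))

    @classmethod
    def from_genes(cls, genes: Iterable[GeneRecord]) -> "AnnotationTable":
        """Derive the table from gene records that already carry labels."""
        return cls.from_records(
            (g.gene_id, "", g.cog_id, g.cog_category, g.phylum) for g in genes
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        return cls(df.set_index("gene_id"))

    def to_tsv(self, path: str | Path) -> None:
        self.frame.reset_index().to_csv(path, sep="\t", index=False)

    def phylum_of(self, gene_id: str) -> str | None:
        if gene_id in self.frame.index:
            return str(self.frame.at[gene_id, "phylum"])
        return None


@dataclass(frozen=True)
class PhylumFilterResult:
    kept: list[SiteGeneLink]
    n_dropped: int       # annotated, but phylum outside the allowed set
    n_unannotated: int   # gene absent from the table


def filter_by_phylum(
    links: Sequence[SiteGeneLink],
    table: AnnotationTable,
    allowed: frozenset[str] | set[str] = DEFAULT_ALLOWED_PHYLA,
) -> PhylumFilterResult:
    """Keep links whose gene's phylum is in ``allowed``.

    Unannotated genes (absent from the table) are excluded and counted
    separately; ``len(kept) + n_dropped + n_unannotated`` always equals
    the input size.
    """
    phyla = table.frame["phylum"]
    kept: list[SiteGeneLink] = []
    n_dropped = n_unannotated = 0
    for ln in links:
        if ln.gene_id not in phyla.index:
            n_unannotated += 1
        elif phyla[ln.gene_id] in allowed:
            kept.append(ln)
        else:
            n_dropped += 1
    return PhylumFilterResult(kept, n_dropped, n_unannotated)


@dataclass(frozen=True)
class CogAttachResult:
    links: list[SiteGeneLink]
    n_missing: int  # gene ids absent from the table (left undecorated)


def attach_cogs(
    links: Sequence[SiteGeneLink], table: AnnotationTable
) -> CogAttachResult:
    """Decorate links with cog_id / cog_category / phylum from the table.

    Genes absent from the table are counted and left with empty labels;
    links with an empty ``cog_id`` are later excluded from COG-level
    statistics.
    """
    frame = table.frame
    out: list[SiteGeneLink] = []
    n_missing = 0
    for ln in links:
        if ln.gene_id in frame.index:
            row = frame.loc[ln.gene_id]
            out.append(
                replace(
                    ln,
                    cog_id=str(row["cog_id"]),
                    cog_category=str(row["cog_category"]),
                    phylum=str(row["phylum"]),
                )
            )
        else:
            n_missing += 1
            out.append(replace(ln, cog_id="", cog_category="", phylum=""))
    if n_missing:
        logger.info("%d links reference genes missing from the table", n_missing)
    return CogAttachResult(out, n_missing)
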