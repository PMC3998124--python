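"""Gene context for motif hits: operons, promoter windows, site–gene links.

Genes arrive as stranded intervals with optional COG and phylum labels.
Adjacent same-strand genes closer than ``gap_max`` (default 100 bp) are
grouped into operons.  A promoter window spans a fixed region around the
translational start (default −300/+50 bp, strand-aware).  Each motif hit
is associated with the single gene whose translational start is nearest
to the site midpoint; the ``in_promoter`` flag marks hits lying entirely
inside the associated gene's promoter window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scan import SiteHit

logger = logging.getLogger(__name__)

GENE_TSV_COLUMNS = [
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "cog_id",
    "cog_category",
    "phylum",
]


@dataclass(frozen=True)
class GeneRecord:
    """A stranded gene interval; coordinates 0-based half-open."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    cog_id: str = ""
    cog_category: str = ""
    phylum: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Translational start coordinate (start for '+', end for '−')."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class OperonAssignment:
    operon_id: str
    gene_ids: tuple[str, ...]
    strand: str


@dataclass(frozen=True)
class SiteGeneLink:
    """A motif hit associated with its nearest gene.

    ``distance_to_start`` is signed and strand-aware: negative means the
    site midpoint lies upstream of the gene's translational start.
    """

    site: SiteHit
    gene_id: str
    distance_to_start: float
    in_promoter: bool
    cog_id: str = ""
    cog_category: str = ""
    phylum: str = ""


def read_genes_tsv(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GENE_TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        GeneRecord(
            gene_id=r.gene_id,
            contig_id=r.contig_id,
            start=int(r.start),
            end=int(r.end),
            strand=r.strand,
            cog_id=getattr(r, "cog_id", ""),
            cog_category=getattr(r, "cog_category", ""),
            phylum=getattr(r, "phylum", ""),
        )
        for r in df.itertuples()
    ]


def write_genes_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (g.gene_id, g.contig_id, g.start, g.end, g.strand,
             g.cog_id, g.cog_category, g.phylum)
            for g in genes
        ],
        columns=GENE_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_genes_gff3(path: str | Path) -> list[GeneRecord]:
    """Read gene records from GFF3; COG/phylum from the attribute column."""
    genes = []
    for ln in Path(path).read_text().splitlines():
        if not ln or ln.startswith("#"):
            continue
        f = ln.split("\t")
        if len(f) != 9 or f[2] not in ("gene", "CDS"):
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        genes.append(
            GeneRecord(
                gene_id=attrs.get("ID", f"{f[0]}:{f[3]}"),
                contig_id=f[0],
                start=int(f[3]) - 1,
                end=int(f[4]),
                strand=f[6],
                cog_id=attrs.get("cog_id", ""),
                cog_category=attrs.get("cog_category", ""),
                phylum=attrs.get("phylum", ""),
            )
        )
    return genes


def write_genes_gff3(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.cog_id:
                attrs += f";cog_id={g.cog_id}"
            if g.cog_category:
                attrs += f";cog_category={g.cog_category}"
            if g.phylum:
                attrs += f";phylum={g.phylum}"
            fh.write(
                "\t".join(
                    [g.contig_id, "metaregulon", "gene", str(g.start + 1),
                     str(g.end), ".", g.strand, ".", attrs]
                )
                + "\n"
            )


def infer_operons(
    genes: Sequence[GeneRecord], gap_max: int = 100
) -> list[OperonAssignment]:
    """Partition genes into operons.

    Maximal runs of consecutive same-contig, same-strand genes whose
    intergenic gap (next.start − prev.end) is strictly below ``gap_max``
    form one operon; every other gene is a singleton operon.
    """
    operons: list[OperonAssignment] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)
    counter = 0
    for contig_id in sorted(by_contig):
        ordered = sorted(by_contig[contig_id], key=lambda g: (g.start, g.end))
        chain: list[GeneRecord] = []
        for g in ordered:
            if (
                chain
                and g.strand == chain[-1].strand
                and g.start - chain[-1].end < gap_max
            ):
                chain.append(g)
            else:
                if chain:
                    counter += 1
                    operons.append(
                        OperonAssignment(
                            f"operon_{counter:05d}",
                            tuple(x.gene_id for x in chain),
                            chain[0].strand,
                        )
                    )
                chain = [g]
        if chain:
            counter += 1
            operons.append(
                OperonAssignment(
                    f"operon_{counter:05d}",
                    tuple(x.gene_id for x in chain),
                    chain[0].strand,
                )
            )
    return operons


def promoter_window(
    gene: GeneRecord,
    upstream: int = 300,
    downstream: int = 50,
    contig_len: int | None = None,
) -> tuple[int, int]:
    """Strand-aware promoter interval around the translational start.

    For a '+' gene starting at ``s``: ``[s − upstream, s + downstream)``.
    For a '−' gene ending at ``e``: ``[e − downstream, e + upstream)``.
    Clipped to ``[0, contig_len)`` when the contig length is given.
    """
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream
    else:
        lo, hi = gene.end - downstream, gene.end + upstream
    lo = max(lo, 0)
    if contig_len is not None:
        hi = min(hi, contig_len)
    return lo, hi


def link_sites_to_genes(
    hits: Sequence[SiteHit],
    genes: Sequence[GeneRecord],
    upstream: int = 300,
    downstream: int = 50,
    contig_lengths: dict[str, int] | None = None,
) -> list[SiteGeneLink]:
    """Associate each hit with the gene whose translational start is
    closest to the site midpoint on the same contig.

    Midpoint distances are compared exactly (in half-bp units).  Exact
    ties are broken toward the gene whose promoter window fully contains
    the site; if that still ties (or no window contains it), toward the
    gene with the lower start coordinate, then lexicographic gene id.
    Hits on contigs without genes are dropped and counted in the log.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    links: list[SiteGeneLink] = []
    dropped = 0
    for hit in hits:
        cands = by_contig.get(hit.contig_id)
        if not cands:
            dropped += 1
            continue
        mid2 = hit.start + hit.end  # midpoint in half-bp units
        best: tuple[int, int, int, str] | None = None
        best_gene: GeneRecord | None = None
        clen = contig_lengths.get(hit.contig_id) if contig_lengths else None
        for g in cands:
            d2 = abs(mid2 - 2 * g.tss)
            lo, hi = promoter_window(g, upstream, downstream, clen)
            contained = lo <= hit.start and hit.end <= hi
            key = (d2, 0 if contained else 1, g.start, g.gene_id)
            if best is None or key < best:
                best, best_gene = key, g
        assert best_gene is not None
        lo, hi = promoter_window(best_gene, upstream, downstream, clen)
        in_promoter = lo <= hit.start and hit.end <= hi
        signed = (mid2 - 2 * best_gene.tss) / 2.0
        if best_gene.strand == "-":
            signed = -signed
        links.append(
            SiteGeneLink(
                site=hit,
                gene_id=best_gene.gene_id,
                distance_to_start=signed,
                in_promoter=in_promoter,
                cog_id=best_gene.cog_id,
                cog_category=best_gene.cog_category,
                phylum=best_gene.phylum,
            )
        )
    if dropped:
        logger.info("dropped %d hits on contigs without genes", dropped)
    return links


def filter_promoter_sites(links: Iterable[SiteGeneLink]) -> list[SiteGeneLink]:
    """Keep only links whose site lies fully inside the promoter window."""
    return [ln for ln in links if ln.in_promoter]


def propagate_links_to_operons(
    links: Sequence[SiteGeneLink],
    operons: Sequence[OperonAssignment],
    genes: Sequence[GeneRecord],
) -> list[SiteGeneLink]:
    """Opt-in: extend each link to the downstream members of its gene's
    operon (a promoter site regulates the whole transcription unit).

    The default analysis associates each site with a single gene; this
    helper produces the expanded link set for COG counting when operon
    co-regulation should be credited.  Added links copy the site and
    promoter flag but point at the downstream gene.
    """
    by_id = {g.gene_id: g for g in genes}
    operon_of: dict[str, OperonAssignment] = {}
    for op in operons:
        for gid in op.gene_ids:
            operon_of[gid] = op
    out = list(links)
    for ln in links:
        op = operon_of.get(ln.gene_id)
        if op is None:
            continue
        members = list(op.gene_ids)
        if op.strand == "-":
            members = members[::-1]  # transcription order for '-' operons
        try:
            pos = members.index(ln.gene_id)
        except ValueError:
            continue
        for gid in members[pos + 1 :]:
            g = by_id[gid]
            out.append(
                replace(
                    ln,
                    gene_id=gid,
                    cog_id=g.cog_id,
                    cog_category=g.cog_category,
                    phylum=g.phylum,
                )
            )
    return out


def links_to_frame(links: Iterable[SiteGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                ln.site.contig_id,
                ln.site.start,
                ln.site.end,
                ln.site.strand,
                ln.site.score,
                ln.site.site_seq,
                ln.gene_id,
                ln.distance_to_start,
                ln.in_promoter,
                ln.cog_id,
                ln.cog_category,
                ln.phylum,
            )
            for ln in links
        ],
        columns=[
            "contig_id", "start", "end", "strand", "score", "site_seq",
            "gene_id", "distance_to_start", "in_promoter", "cog_id",
            "cog_category", "phylum",
        ],
    )


def write_links_tsv(links: Iterable[SiteGeneLink], path: str | Path) -> None:
    df = links_to_frame(links)
    df["start"] = df["start"] + 1  # 1-based inclusive on export
    df.to_csv(path, sep="\t", index=False)
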