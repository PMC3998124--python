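"""Both-strand sliding-window scanning of contigs with an Ri model.

Every window of the motif width is scored on both strands; windows with a
score strictly above the threshold are reported.  Windows containing
non-ACGT bases (assembly Ns and IUPAC ambiguity codes) are skipped and
counted.  When the forward and reverse-strand windows at the same
coordinates both pass — common for near-palindromic motifs — only the
higher-scoring strand is kept, so a physical site is never counted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .motif import BASES, MotifError, ScoringModel

logger = logging.getLogger(__name__)

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Contig:
    id: str
    seq: str


@dataclass(frozen=True)
class SiteHit:
    """A scored motif occurrence; coordinates 0-based, half-open."""

    contig_id: str
    start: int
    end: int
    strand: str
    score: float
    site_seq: str  # as matched: reverse-complemented for '-' strand


@dataclass
class ScanSummary:
    windows_scored: int = 0
    windows_skipped: int = 0
    n_hits: int = 0

    def update(self, other: "ScanSummary") -> None:
        self.windows_scored += other.windows_scored
        self.windows_skipped += other.windows_skipped
        self.n_hits += other.n_hits


@dataclass
class ScanResult:
    hits: list[SiteHit]
    summary: ScanSummary

    def to_frame(self) -> pd.DataFrame:
        return hits_to_frame(self.hits)


def read_contigs(path: str | Path) -> list[Contig]:
    from Bio import SeqIO

    return [
        Contig(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def scan_contig(
    model: ScoringModel,
    contig: Contig,
    threshold: float,
    summary: ScanSummary | None = None,
) -> list[SiteHit]:
    """All windows with Ri > ``threshold`` on either strand of one contig.

    Returns hits sorted by start; a contig shorter than the motif yields
    an empty list.
    """
    if model is None:
        raise MotifError("no scoring model supplied")
    if not np.isfinite(threshold):
        raise MotifError("scan threshold must be finite")
    L = model.width
    n = len(contig.seq)
    if n < L:
        return []

    code = _CODE[np.frombuffer(contig.seq.encode("ascii"), dtype=np.uint8)]
    windows = np.lib.stride_tricks.sliding_window_view(code, L)
    valid = (windows >= 0).all(axis=1)

    safe = np.where(windows >= 0, windows, 0)
    pos = np.arange(L)
    # Reverse-strand score of a window equals the forward score under the
    # reverse-complemented weight matrix.
    fwd = model.riw[pos, safe].sum(axis=1)
    rev = model.riw[::-1, ::-1][pos, safe].sum(axis=1)
    fwd[~valid] = -np.inf
    rev[~valid] = -np.inf

    if summary is not None:
        summary.windows_scored += int(valid.sum())
        summary.windows_skipped += int((~valid).sum())

    hits: list[SiteHit] = []
    passing = np.flatnonzero((fwd > threshold) | (rev > threshold))
    for i in passing:
        # same-coordinate double-strand pass: keep the better strand,
        # ties resolved to '+'
        if fwd[i] >= rev[i]:
            strand, score = "+", float(fwd[i])
            site = contig.seq[i : i + L]
        else:
            strand, score = "-", float(rev[i])
            site = revcomp(contig.seq[i : i + L])
        hits.append(
            SiteHit(contig.id, int(i), int(i) + L, strand, score, site)
        )
    if summary is not None:
        summary.n_hits += len(hits)
    return hits


def scan_metagenome(
    model: ScoringModel,
    contigs: Sequence[Contig],
    threshold: float,
) -> ScanResult:
    """Scan a collection of contigs; hit order is (contig order, start)."""
    ids = [c.id for c in contigs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    summary = ScanSummary()
    hits: list[SiteHit] = []
    for contig in contigs:
        hits.extend(scan_contig(model, contig, threshold, summary))
    hits.sort(key=lambda h: (h.contig_id, h.start))
    logger.info(
        "scanned %d windows (%d skipped), %d hits above %.3f bits",
        summary.windows_scored,
        summary.windows_skipped,
        summary.n_hits,
        threshold,
    )
    return ScanResult(hits=hits, summary=summary)


def hits_to_frame(hits: Iterable[SiteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.contig_id, h.start, h.end, h.strand, h.score, h.site_seq)
            for h in hits
        ],
        columns=["contig_id", "start", "end", "strand", "score", "site_seq"],
    )


def write_hits_tsv(hits: Iterable[SiteHit], path: str | Path) -> None:
    """1-based inclusive coordinates in the exported table."""
    df = hits_to_frame(hits)
    df["start"] = df["start"] + 1  # 1-based inclusive for interchange
    df.to_csv(path, sep="\t", index=False)


def write_hits_gff3(hits: Iterable[SiteHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits, 1):
            fh.write(
                "\t".join(
                    [
                        h.contig_id,
                        "metaregulon",
                        "TF_binding_site",
                        str(h.start + 1),
                        str(h.end),
                        f"{h.score:.4f}",
                        h.strand,
                        ".",
                        f"ID=site{i};site_seq={h.site_seq}",
                    ]
                )
                + "\n"
            )
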