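"""Synthetic metagenomes with planted regulon binding sites.

The generator emulates the statistical structure the analysis assumes:
contigs of background sequence carrying non-overlapping, strand-annotated
genes grouped into operons; per-contig phylum labels (a contig stands for
one species, so taxonomic filtering has block structure); COG identifiers
and one-letter functional categories per gene; and, for a designated set
of "regulon" COGs, motif instances sampled from a scoring model and
planted inside the promoter windows of operon-head genes carrying those
COGs.  Sites sampled from the default motif score approximately normally
around 16.3 bits, emulating the score spectrum of genuinely regulated
promoters.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
seed reproduces the metagenome byte for byte.  A ground-truth manifest
records every planted site and the designated regulon COGs for recovery
tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import KNOWN_PHYLA
from .genes import GeneRecord, write_genes_tsv
from .motif import (
    BASES,
    ScoringModel,
    SiteCollection,
    sample_site,
    sample_sites,
    score_sequence,
)
from .scan import Contig, revcomp

__all__ = [
    "LEXA_LIKE_FREQS",
    "lexa_like_model",
    "SimConfig",
    "PlantedSite",
    "SyntheticTruth",
    "SyntheticMetagenome",
    "generate_metagenome",
    "recovery_fixture_config",
]

# A 16-bp near-palindromic motif in the style of the Gram-positive LexA
# operator (CGAAC-n4-GTTCG consensus with an AT-rich spacer).  Columns are
# A, C, G, T.  Information content ~16.3 bits; scores of sampled sites are
# approximately N(16.3, 2.9).  This is a synthetic stand-in matrix with
# the qualitative shape of the real motif, not a published matrix.
_S, _m = 0.99, 0.01 / 3
_A = (_S, _m, _m, _m)
_C = (_m, _S, _m, _m)
_G = (_m, _m, _S, _m)
_T = (_m, _m, _m, _S)
_MODC = (0.12, 0.58, 0.18, 0.12)
_MODG = (0.12, 0.18, 0.58, 0.12)
_AT = (0.32, 0.18, 0.18, 0.32)

LEXA_LIKE_FREQS = np.array(
    [_AT, _MODC, _G, _A, _A, _C, _AT, _AT, _AT, _AT, _G, _T, _T, _C, _MODG, _AT]
)


def lexa_like_model() -> ScoringModel:
    """Scoring model for the default synthetic motif."""
    return ScoringModel.from_frequencies(LEXA_LIKE_FREQS)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic metagenome.

    Defaults describe the standard recovery setting: ~2 Mb of sequence in
    50-kb contigs, gene-dense contigs with operons inferred at a 100-bp
    gap, five regulon COGs with 15 planted promoter sites each over a
    background of 50 unrelated COGs, and a gut-like phylum mix dominated
    by Firmicutes and Bacteroidetes.
    """

    seed: int = 0
    n_contigs: int = 40
    contig_len: int = 50_000
    gc_content: float = 0.45
    gene_len_range: tuple[int, int] = (500, 1500)
    operon_gap_range: tuple[int, int] = (20, 95)     # within operons (< gap_max)
    intergenic_gap_range: tuple[int, int] = (320, 470)  # between operons
    plant_max_offset: int = 140  # planted sites end within this of the TSS
    operon_size_mean: float = 2.0
    max_operon_size: int = 5
    gap_max: int = 100
    upstream: int = 300
    downstream: int = 50
    motif_freqs: np.ndarray = field(default_factory=lambda: LEXA_LIKE_FREQS)
    n_collection_sites: int = 60
    # A multispecies collection of validated sites is more heterogeneous
    # than sites of any single regulon: a fraction of collection members is
    # drawn from a temperature-softened matrix (freq**beta, renormalised),
    # which widens the collection score spread so that the derived
    # mean − 1.5·SD threshold falls well below the 12–20 bit profiling
    # range, as it does for real validated collections.
    collection_weak_fraction: float = 0.25
    collection_weak_beta: float = 0.5
    regulon_cogs: tuple[str, ...] = (
        "COG1974",  # LexA/UmuD-like
        "COG0468",  # RecA-like
        "COG0556",  # UvrB-like
        "COG0389",  # DinB-like
        "COG0210",  # UvrD-like
    )
    sites_per_cog: int = 15
    n_background_cogs: int = 50
    unannotated_fraction: float = 0.10
    phylum_mix: tuple[tuple[str, float], ...] = (
        ("Firmicutes", 0.45),
        ("Bacteroidetes", 0.30),
        ("Actinobacteria", 0.15),
        ("Proteobacteria", 0.10),
    )
    allowed_phyla: tuple[str, ...] = ("Firmicutes", "Actinobacteria")

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.phylum_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"phylum proportions sum to {total}, not 1")
        if self.sites_per_cog < 0:
            raise ValueError("sites_per_cog must be >= 0")
        for phylum, _ in self.phylum_mix:
            if phylum not in KNOWN_PHYLA:
                raise ValueError(f"unknown phylum {phylum!r}")


@dataclass(frozen=True)
class PlantedSite:
    contig_id: str
    start: int
    end: int
    strand: str
    site_seq: str  # motif-oriented (as sampled)
    score: float   # under the true generating model
    gene_id: str
    cog_id: str


@dataclass(frozen=True)
class SyntheticTruth:
    planted_sites: tuple[PlantedSite, ...]
    regulon_cogs: tuple[str, ...]
    gene_cog: dict[str, str]
    gene_phylum: dict[str, str]
    n_filtered_expected: int  # planted sites surviving the phylum filter

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regulon_cogs": list(self.regulon_cogs),
            "n_filtered_expected": self.n_filtered_expected,
            "planted_sites": [
                {
                    "contig_id": p.contig_id,
                    "start": p.start,
                    "end": p.end,
                    "strand": p.strand,
                    "site_seq": p.site_seq,
                    "score": p.score,
                    "gene_id": p.gene_id,
                    "cog_id": p.cog_id,
                }
                for p in self.planted_sites
            ],
            "gene_cog": self.gene_cog,
            "gene_phylum": self.gene_phylum,
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


@dataclass
class SyntheticMetagenome:
    contigs: list[Contig]
    genes: list[GeneRecord]
    collection: SiteCollection
    model: ScoringModel  # the true generating model
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write contigs FASTA, gene TSV, site-collection FASTA and the
        truth manifest; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": out / "contigs.fasta",
            "genes": out / "genes.tsv",
            "sites": out / "site_collection.fasta",
            "truth": out / "truth.json",
        }
        with open(paths["contigs"], "w") as fh:
            for c in self.contigs:
                fh.write(f">{c.id}\n")
                for i in range(0, len(c.seq), 70):
                    fh.write(c.seq[i : i + 70] + "\n")
        write_genes_tsv(self.genes, paths["genes"])
        self.collection.to_fasta(paths["sites"])
        self.truth.to_json(paths["truth"])
        return paths


_COG_CATEGORY_POOL = "CDEFGHIJKMNOPQRSTUV"
_REGULON_CATEGORIES = ("L", "T", "K", "L", "L")  # SOS-like: repair-heavy


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def generate_metagenome(cfg: SimConfig) -> SyntheticMetagenome:
    """Build the full synthetic dataset described by ``cfg``.

    Layout per contig: operons of 1–``max_operon_size`` same-strand genes
    separated by sub-``gap_max`` gaps inside an operon and by large
    intergenic gaps between operons, so every operon head has room for a
    full promoter window.  Regulon COGs are assigned only to operon-head
    genes on contigs of the allowed (Gram-positive) phyla — the simulated
    regulator is phylum-restricted, as the taxonomic filter assumes — and
    one sampled motif instance is planted in each such gene's promoter,
    strictly upstream of the translational start.
    """
    rng = np.random.default_rng(cfg.seed)
    model = ScoringModel.from_frequencies(np.asarray(cfg.motif_freqs, dtype=float))
    L = model.width

    phyla = [p for p, _ in cfg.phylum_mix]
    probs = np.array([w for _, w in cfg.phylum_mix])

    contig_codes: list[np.ndarray] = []
    contig_ids: list[str] = []
    genes: list[GeneRecord] = []
    head_flags: list[bool] = []  # parallel to genes: operon head?
    contig_phylum: dict[str, str] = {}

    for ci in range(cfg.n_contigs):
        contig_id = f"contig_{ci + 1:04d}"
        contig_ids.append(contig_id)
        contig_phylum[contig_id] = phyla[rng.choice(len(phyla), p=probs)]
        codes = _random_sequence(rng, cfg.contig_len, cfg.gc_content)
        contig_codes.append(codes)

        pos = int(rng.integers(*cfg.intergenic_gap_range))
        gi = 0
        while True:
            strand = "+" if rng.random() < 0.5 else "-"
            size = min(
                1 + rng.poisson(cfg.operon_size_mean - 1.0), cfg.max_operon_size
            )
            lengths = rng.integers(*cfg.gene_len_range, size=size)
            gaps = rng.integers(*cfg.operon_gap_range, size=size - 1) if size > 1 else []
            span = int(lengths.sum()) + int(np.sum(gaps))
            if pos + span + cfg.intergenic_gap_range[1] > cfg.contig_len:
                break
            starts = []
            p = pos
            for k in range(size):
                starts.append(p)
                p += int(lengths[k])
                if k < size - 1:
                    p += int(gaps[k])
            for k in range(size):
                gi += 1
                genes.append(
                    GeneRecord(
                        gene_id=f"{contig_id}_g{gi:03d}",
                        contig_id=contig_id,
                        start=starts[k],
                        end=starts[k] + int(lengths[k]),
                        strand=strand,
                        phylum=contig_phylum[contig_id],
                    )
                )
                # transcriptional head: leftmost gene on '+', rightmost on '-'
                head_flags.append(k == 0 if strand == "+" else k == size - 1)
            pos += span + int(rng.integers(*cfg.intergenic_gap_range))

    # --- COG assignment -------------------------------------------------
    background_cogs = [f"COG9{i:03d}" for i in range(cfg.n_background_cogs)]
    bg_categories = {
        cog: _COG_CATEGORY_POOL[int(rng.integers(len(_COG_CATEGORY_POOL)))]
        for cog in background_cogs
    }
    regulon_categories = {
        cog: _REGULON_CATEGORIES[i % len(_REGULON_CATEGORIES)]
        for i, cog in enumerate(cfg.regulon_cogs)
    }

    allowed = set(cfg.allowed_phyla)
    eligible_heads = [
        i
        for i, g in enumerate(genes)
        if head_flags[i] and g.phylum in allowed
    ]
    need = len(cfg.regulon_cogs) * cfg.sites_per_cog
    if need > len(eligible_heads):
        raise ValueError(
            f"layout infeasible: need {need} operon-head genes on allowed "
            f"phyla, only {len(eligible_heads)} available"
        )
    chosen = rng.choice(len(eligible_heads), size=need, replace=False)
    regulon_gene_idx: dict[str, list[int]] = {}
    for j, cog in enumerate(cfg.regulon_cogs):
        sel = chosen[j * cfg.sites_per_cog : (j + 1) * cfg.sites_per_cog]
        regulon_gene_idx[cog] = [eligible_heads[int(s)] for s in sel]

    regulon_idx_all = {i for idxs in regulon_gene_idx.values() for i in idxs}
    for i, g in enumerate(genes):
        if i in regulon_idx_all:
            continue
        if rng.random() < cfg.unannotated_fraction:
            continue  # stays unannotated (empty cog_id)
        cog = background_cogs[int(rng.integers(len(background_cogs)))]
        genes[i] = GeneRecord(
            gene_id=g.gene_id, contig_id=g.contig_id, start=g.start,
            end=g.end, strand=g.strand, cog_id=cog,
            cog_category=bg_categories[cog], phylum=g.phylum,
        )
    for cog, idxs in regulon_gene_idx.items():
        for i in idxs:
            g = genes[i]
            genes[i] = GeneRecord(
                gene_id=g.gene_id, contig_id=g.contig_id, start=g.start,
                end=g.end, strand=g.strand, cog_id=cog,
                cog_category=regulon_categories[cog], phylum=g.phylum,
            )

    # --- site planting --------------------------------------------------
    contig_index = {cid: k for k, cid in enumerate(contig_ids)}
    code_of = {b: i for i, b in enumerate(BASES)}
    planted: list[PlantedSite] = []
    for cog in cfg.regulon_cogs:
        for i in regulon_gene_idx[cog]:
            g = genes[i]
            site = sample_site(model, rng)
            # strictly upstream of the translational start and close to it,
            # so the site is unambiguously nearest its own gene even when
            # two operon heads face each other across an intergenic gap
            offset = int(rng.integers(L + 20, cfg.plant_max_offset))
            if g.strand == "+":
                start = g.start - offset
                inserted = site
            else:
                start = g.end + offset - L
                inserted = revcomp(site)
            codes = contig_codes[contig_index[g.contig_id]]
            codes[start : start + L] = [code_of[c] for c in inserted]
            planted.append(
                PlantedSite(
                    contig_id=g.contig_id,
                    start=start,
                    end=start + L,
                    strand=g.strand,
                    site_seq=site,
                    score=score_sequence(model, site),
                    gene_id=g.gene_id,
                    cog_id=cog,
                )
            )

    base_arr = np.frombuffer(BASES.encode(), dtype=np.uint8)
    contigs = [
        Contig(cid, base_arr[contig_codes[k]].tobytes().decode())
        for k, cid in enumerate(contig_ids)
    ]

    n_weak = int(round(cfg.n_collection_sites * cfg.collection_weak_fraction))
    soft = np.asarray(cfg.motif_freqs, dtype=float) ** cfg.collection_weak_beta
    soft /= soft.sum(axis=1, keepdims=True)
    weak_model = ScoringModel.from_frequencies(soft)
    collection = SiteCollection.from_sequences(
        sample_sites(model, cfg.n_collection_sites - n_weak, rng)
        + sample_sites(weak_model, n_weak, rng)
    )

    truth = SyntheticTruth(
        planted_sites=tuple(planted),
        regulon_cogs=tuple(cfg.regulon_cogs),
        gene_cog={g.gene_id: g.cog_id for g in genes},
        gene_phylum={g.gene_id: g.phylum for g in genes},
        n_filtered_expected=len(planted),
    )
    return SyntheticMetagenome(
        contigs=contigs, genes=genes, collection=collection, model=model,
        truth=truth,
    )


def recovery_fixture_config(seed: int = 0) -> SimConfig:
    """The standard parameter-recovery setting (~2 Mb, 5 regulon COGs ×
    15 planted sites, 50 background COGs)."""
    return SimConfig(seed=seed)
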