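import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_link, oracle_operons
from metaregulon import (
    GeneRecord,
    SiteHit,
    filter_promoter_sites,
    infer_operons,
    link_sites_to_genes,
    promoter_window,
)


def _gene(gid, start, end, strand="+", contig="c1", **kw):
    return GeneRecord(gid, contig, start, end, strand, **kw)


def _hit(start, end, contig="c1", score=15.0):
    return SiteHit(contig, start, end, "+", score, "N" * (end - start))


class TestInferOperons:
    def test_small_gap_merges_genes(self):
        genes = [_gene("a", 0, 900), _gene("b", 950, 1800)]
        ops = infer_operons(genes, gap_max=100)
        assert len(ops) == 1
        assert ops[0].gene_ids == ("a", "b")

    def test_gap_equal_to_limit_splits(self):
        # the rule is strictly < gap_max
        genes = [_gene("a", 0, 900), _gene("b", 1000, 1800)]
        ops = infer_operons(genes, gap_max=100)
        assert [o.gene_ids for o in ops] == [("a",), ("b",)]

    def test_strand_switch_breaks_chain(self):
        genes = [_gene("a", 0, 900), _gene("b", 950, 1800, strand="-")]
        ops = infer_operons(genes, gap_max=100)
        assert len(ops) == 2

    def test_twenty_gene_contig_matches_chain_scan_oracle(self):
        rng = np.random.default_rng(5)
        genes, pos = [], 100
        for i in range(20):
            length = int(rng.integers(300, 900))
            strand = "+" if rng.random() < 0.6 else "-"
            genes.append(_gene(f"g{i:02d}", pos, pos + length, strand))
            pos += length + int(rng.integers(10, 250))
        ops = infer_operons(genes, gap_max=100)
        expected = oracle_operons(
            [(g.gene_id, g.contig_id, g.start, g.end, g.strand) for g in genes],
            gap_max=100,
        )
        assert [o.gene_ids for o in ops] == expected

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_operon_partition_properties(self, seed):
        rng = np.random.default_rng(seed)
        genes, pos = [], 0
        for i in range(int(rng.integers(1, 15))):
            length = int(rng.integers(100, 500))
            genes.append(
                _gene(f"g{i}", pos, pos + length,
                      "+" if rng.random() < 0.5 else "-")
            )
            pos += length + int(rng.integers(0, 200))
        ops = infer_operons(genes, gap_max=100)
        # every gene appears in exactly one operon
        members = [gid for o in ops for gid in o.gene_ids]
        assert sorted(members) == sorted(g.gene_id for g in genes)
        by_id = {g.gene_id: g for g in genes}
        for o in ops:
            chain = [by_id[g] for g in o.gene_ids]
            assert all(g.strand == o.strand for g in chain)
            for prev, nxt in zip(chain, chain[1:]):
                assert nxt.start - prev.end < 100


class TestPromoterWindow:
    def test_forward_strand_window(self):
        g = _gene("a", 1000, 2000)
        assert promoter_window(g, 300, 50, contig_len=5000) == (700, 1050)

    def test_reverse_strand_window(self):
        g = _gene("a", 200, 1000, strand="-")
        assert promoter_window(g, 300, 50, contig_len=5000) == (950, 1300)

    def test_clipping_at_contig_edges(self):
        g = _gene("a", 100, 800)
        assert promoter_window(g, 300, 50, contig_len=5000) == (0, 150)
        g2 = _gene("b", 100, 4990, strand="-")
        assert promoter_window(g2, 300, 50, contig_len=5000) == (4940, 5000)

    def test_window_length_bounded(self):
        g = _gene("a", 2000, 3000)
        lo, hi = promoter_window(g, 300, 50, contig_len=10_000)
        assert hi - lo == 350  # full length away from edges


class TestLinkSites:
    def test_upstream_site_linked_in_promoter(self):
        genes = [_gene("a", 1000, 2000)]
        links = link_sites_to_genes([_hit(892, 908)], genes)
        assert len(links) == 1
        ln = links[0]
        assert ln.gene_id == "a"
        assert ln.in_promoter is True
        assert ln.distance_to_start == pytest.approx(-100.0)

    def test_reverse_gene_distance_sign(self):
        genes = [_gene("a", 1000, 2000, strand="-")]
        # site 100 bp beyond the gene end = upstream for a '-' gene
        links = link_sites_to_genes([_hit(2092, 2108)], genes)
        assert links[0].distance_to_start == pytest.approx(-100.0)
        assert links[0].in_promoter is True

    def test_equidistant_tie_prefers_promoter_containing_gene(self):
        # midpoint 1060: 60 bp from both starts; the site pokes past
        # gene a's +50 promoter edge but sits inside gene b's window,
        # so the tie resolves to b even though a has the lower start
        genes = [_gene("a", 1000, 1900), _gene("b", 1120, 2100)]
        hit = _hit(1052, 1068)
        links = link_sites_to_genes([hit], genes)
        assert links[0].gene_id == "b"
        assert links[0].in_promoter is True

    def test_equidistant_tie_without_promoter_takes_lower_coordinate(self):
        genes = [_gene("a", 1000, 1900), _gene("b", 2000, 3000)]
        # midpoint 1500: 500 from both starts, in neither promoter window
        # (site overlaps gene a's interior)
        hit = _hit(1492, 1508)
        links = link_sites_to_genes([hit], genes)
        assert links[0].gene_id == "a"
        assert links[0].in_promoter is False

    def test_hits_on_geneless_contigs_dropped(self):
        genes = [_gene("a", 1000, 2000, contig="other")]
        assert link_sites_to_genes([_hit(10, 26)], genes) == []

    def test_random_fixture_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(29)
        genes = []
        pos = 400
        for i in range(30):
            length = int(rng.integers(400, 1200))
            genes.append(
                _gene(f"g{i:02d}", pos, pos + length,
                      "+" if rng.random() < 0.5 else "-")
            )
            pos += length + int(rng.integers(50, 500))
        hits = []
        for j in range(50):
            start = int(rng.integers(0, pos - 16))
            hits.append(_hit(start, start + 16))
        links = link_sites_to_genes(hits, genes, upstream=300, downstream=50)
        tuples = [
            (g.gene_id, g.contig_id, g.start, g.end, g.strand) for g in genes
        ]
        for hit, ln in zip(hits, links):
            gene_id, contained = oracle_link(
                (hit.contig_id, hit.start, hit.end), tuples, 300, 50
            )
            assert ln.gene_id == gene_id
            assert ln.in_promoter == contained


class TestFilterPromoterSites:
    def test_keeps_only_promoter_links(self):
        genes = [_gene("a", 1000, 2000)]
        hits = [_hit(892, 908), _hit(1500, 1516)]  # promoter vs intragenic
        links = link_sites_to_genes(hits, genes)
        kept = filter_promoter_sites(links)
        assert [ln.site.start for ln in kept] == [892]
        assert all(ln.in_promoter for ln in kept)


class TestOperonPropagation:
    def test_site_credited_to_downstream_members(self):
        from metaregulon import propagate_links_to_operons

        genes = [
            _gene("head", 1000, 1900),
            _gene("mid", 1950, 2800),
            _gene("tail", 2850, 3600),
        ]
        ops = infer_operons(genes, gap_max=100)
        assert len(ops) == 1
        links = link_sites_to_genes([_hit(892, 908)], genes)
        assert links[0].gene_id == "head"
        expanded = propagate_links_to_operons(links, ops, genes)
        assert [ln.gene_id for ln in expanded] == ["head", "mid", "tail"]
        assert all(ln.site is links[0].site for ln in expanded)

    def test_reverse_operon_propagates_in_transcription_order(self):
        from metaregulon import propagate_links_to_operons

        genes = [
            _gene("tail", 1000, 1900, strand="-"),
            _gene("head", 1950, 2800, strand="-"),
        ]
        ops = infer_operons(genes, gap_max=100)
        links = link_sites_to_genes([_hit(2892, 2908)], genes)
        assert links[0].gene_id == "head"
        expanded = propagate_links_to_operons(links, ops, genes)
        assert [ln.gene_id for ln in expanded] == ["head", "tail"]

    def test_mid_operon_link_only_reaches_downstream(self):
        from metaregulon import propagate_links_to_operons

        genes = [
            _gene("a", 1000, 1900),
            _gene("b", 1950, 2800),
            _gene("c", 2850, 3600),
        ]
        ops = infer_operons(genes, gap_max=100)
        links = link_sites_to_genes([_hit(1920, 1936)], genes)
        assert links[0].gene_id == "b"
        expanded = propagate_links_to_operons(links, ops, genes)
        assert [ln.gene_id for ln in expanded] == ["b", "c"]
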