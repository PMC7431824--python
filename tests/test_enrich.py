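import math
from types import SimpleNamespace

import numpy as np
import pytest

from methage.enrich import (
    benjamini_hochberg,
    cytoband_enrichment,
    directional_overlap,
    fisher_or_ci,
    gene_to_band_map,
    geneset_enrichment,
)
from methage.meth_io import GeneModel, GenomicInterval

from oracles import bh_stepup, fisher_p_enumeration


class TestFisherOrCi:
    def test_woolf_interval_closed_form(self):
        res = fisher_or_ci(20, 80, 10, 190)
        assert res.odds_ratio == pytest.approx(4.75)
        se = math.sqrt(1 / 20 + 1 / 80 + 1 / 10 + 1 / 190)
        assert res.ci_low == pytest.approx(math.exp(math.log(4.75) - 1.96 * se))
        assert res.ci_low == pytest.approx(2.13, abs=0.01)
        assert res.ci_high == pytest.approx(10.60, abs=0.01)

    def test_symmetric_table(self):
        res = fisher_or_ci(5, 5, 5, 5)
        assert res.odds_ratio == 1.0 and res.p_value == 1.0

    def test_perfect_separation(self):
        res = fisher_or_ci(10, 0, 0, 10)
        assert res.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        # Haldane-Anscombe correction on all cells
        assert res.odds_ratio == pytest.approx((10.5 * 10.5) / (0.5 * 0.5))
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fisher_or_ci(0, 0, 0, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
        if a + b + c + d == 0:
            a = 1
        res = fisher_or_ci(a, b, c, d)
        assert res.p_value == pytest.approx(
            fisher_p_enumeration(a, b, c, d), rel=1e-9
        )


class TestGenesetEnrichment:
    def test_disjoint_split_is_depleted(self):
        universe = {f"g{i}" for i in range(100)}
        query = {f"g{i}" for i in range(50)}
        target = universe - query
        res = geneset_enrichment(query, target, universe)
        assert res.a == 0 and res.odds_ratio < 1

    def test_nested_query_is_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        target = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(10)}
        res = geneset_enrichment(query, target, universe)
        assert res.a == 10 and res.odds_ratio > 1 and res.p_value < 0.05

    def test_sets_clipped_to_universe(self):
        res = geneset_enrichment({"A", "X"}, {"A", "Y"}, {"A", "B", "C"})
        assert (res.a, res.b, res.c, res.d) == (1, 0, 0, 2)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            geneset_enrichment({"A"}, {"A"}, set())

    def test_planted_overlap_detected_and_monotone(self):
        """Planted overlap f=0.5 vs background 0.1 in a 5000-gene universe is
        significantly enriched in >=95% of 100 seeded replicates."""
        universe = [f"g{i}" for i in range(5000)]
        hits = 0
        ors = {0.1: [], 0.5: []}
        for seed in range(100):
            rng = np.random.default_rng(seed)
            query = set(rng.choice(universe, size=200, replace=False))
            rest = sorted(set(universe) - query)
            for f in (0.1, 0.5):
                n_in = int(f * 100)
                target = set(rng.choice(sorted(query), size=n_in, replace=False))
                target |= set(rng.choice(rest, size=100 - n_in, replace=False))
                res = geneset_enrichment(query, target, universe)
                ors[f].append(res.odds_ratio)
                if f == 0.5 and res.odds_ratio > 1 and res.p_value <= 0.05:
                    hits += 1
        assert hits >= 95
        assert np.mean(ors[0.5]) > np.mean(ors[0.1]) > 1


def annotated_stub(direction, genes):
    return SimpleNamespace(dmr=SimpleNamespace(direction=direction),
                           genes=frozenset(genes))


class TestDirectionalOverlap:
    UNIVERSE = {f"g{i}" for i in range(96)} | {"A", "B", "C", "D"}

    def test_set_arithmetic(self):
        sperm = [annotated_stub("hyper", {"A", "B", "C"})]
        blast = [annotated_stub("hyper", {"B", "C", "D"})]
        res, overlap = directional_overlap(sperm, blast, self.UNIVERSE)["hyper"]
        assert (res.a, res.b, res.c, res.d) == (2, 1, 1, 96)
        assert overlap == {"B", "C"}

    def test_identical_sets_maximal(self):
        sperm = [annotated_stub("hypo", {"A", "B"})]
        res, overlap = directional_overlap(sperm, sperm, self.UNIVERSE)["hypo"]
        assert res.a == 2 and overlap == {"A", "B"}

    def test_disjoint_sets_depleted(self):
        # sets large enough that the corrected OR reflects the depletion
        sperm = [annotated_stub("hyper", {f"g{i}" for i in range(40)})]
        blast = [annotated_stub("hyper", {f"g{i}" for i in range(40, 80)})]
        res, overlap = directional_overlap(sperm, blast, self.UNIVERSE)["hyper"]
        assert res.a == 0 and overlap == set() and res.odds_ratio < 1

    def test_any_ignores_direction_and_directions_not_deduplicated(self):
        sperm = [annotated_stub("hyper", {"A", "B"}), annotated_stub("hypo", {"B"})]
        blast = [annotated_stub("hyper", {"B"}), annotated_stub("hypo", {"B", "C"})]
        out = directional_overlap(sperm, blast, self.UNIVERSE)
        # gene B overlaps in both directions and is counted in each
        assert out["hyper"][1] == {"B"} and out["hypo"][1] == {"B"}
        assert out["any"][0].a >= max(out["hyper"][0].a, out["hypo"][0].a)


class TestBenjaminiHochberg:
    def test_stepup_hand_example(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(size=50)
        assert np.allclose(benjamini_hochberg(p), bh_stepup(p), atol=1e-12)


def band_genes(n_bands=20, genes_per_band=25, band_len=10_000):
    bands, genes = [], []
    for b in range(n_bands):
        start = b * band_len
        bands.append(GenomicInterval("chr1", start, start + band_len, name=f"p{b}"))
        for j in range(genes_per_band):
            s = start + 100 + j * 300
            genes.append(
                GeneModel(GenomicInterval("chr1", s, s + 200, strand="+"), f"B{b}G{j}")
            )
    return bands, genes


class TestCytobandEnrichment:
    def test_gene_outside_bands_is_an_error(self):
        bands, genes = band_genes(2, 2)
        stray = GeneModel(
            GenomicInterval("chr1", 10**6, 10**6 + 100, strand="+"), "FAR"
        )
        with pytest.raises(ValueError, match="outside all cytobands"):
            gene_to_band_map(genes + [stray], bands)

    def test_planted_band_detected(self):
        """A band holding 5% of the universe but 30% of DMR genes reaches
        q <= .05 in >=95% of 100 seeded replicates."""
        bands, genes = band_genes(20, 25)   # each band holds 5% of 500 genes
        target_band_genes = [g.symbol for g in genes[:25]]
        other_genes = [g.symbol for g in genes[25:]]
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            dmr = set(rng.choice(target_band_genes, size=15, replace=False))
            dmr |= set(rng.choice(other_genes, size=35, replace=False))
            table = cytoband_enrichment(dmr, genes, bands)
            row = table[table.band == "chr1:p0"].iloc[0]
            if row.significant:
                hits += 1
        assert hits >= 95

    def test_proportional_null_rarely_flags(self):
        bands, genes = band_genes(20, 25)
        symbols = [g.symbol for g in genes]
        any_flagged = 0
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            dmr = set(rng.choice(symbols, size=50, replace=False))
            table = cytoband_enrichment(dmr, genes, bands)
            if table.significant.any():
                any_flagged += 1
        # BH at q<=.05 over 20 bands: expect flags in <=~5% of null replicates
        assert any_flagged <= 10

    def test_single_band_degenerate(self):
        bands, genes = band_genes(1, 10)
        table = cytoband_enrichment({genes[0].symbol}, genes, bands)
        assert table.p_value.iloc[0] == 1.0
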