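"""LD computation, greedy index selection against a brute-force oracle,
clumped regions and gene-interval overlap."""

import numpy as np
import pandas as pd
import pytest

from countgwas import (
    GeneSet,
    clump_region,
    pairwise_r2,
    region_overlaps_genes,
    select_index_snps,
    simulate_genotypes,
)
from countgwas.clump import ClumpedRegion
from .conftest import make_genotypes, single_trait_config


def greedy_oracle(pvals, bp, r2, window_bp, r2_max):
    """Literal re-execution of the definition: smallest p first (ties to
    smaller coordinate), absorb unassigned SNPs within the window with
    r^2 > r2_max."""
    m = len(pvals)
    assigned = {}
    order = sorted(range(m), key=lambda j: (pvals[j], bp[j]))
    for i in order:
        if i in assigned:
            continue
        assigned[i] = i
        for j in order:
            if j in assigned:
                continue
            if abs(bp[j] - bp[i]) <= window_bp and r2[i, j] > r2_max:
                assigned[j] = i
    return assigned


def assoc_table(G, pvals):
    return pd.DataFrame(
        {
            "snp_id": G.snp_map["snp_id"],
            "chr": G.snp_map["chrom"],
            "bp": G.snp_map["bp"],
            "p_gc": pvals,
            "p": pvals,
        }
    )


class TestPairwiseR2:
    def test_self_and_flip_are_one(self):
        rng = np.random.default_rng(71)
        a = rng.binomial(2, 0.4, size=50).astype(float)
        G = make_genotypes(np.column_stack([a, 2.0 - a]))
        assert pairwise_r2(G, 0, 0) == pytest.approx(1.0)
        assert pairwise_r2(G, 0, 1) == pytest.approx(1.0)

    def test_hand_computed_six_sample_vectors(self):
        a = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        b = np.array([1.0, 1.0, 2.0, 0.0, 0.0, 2.0])
        G = make_genotypes(np.column_stack([a, b]))
        r = np.corrcoef(a, b)[0, 1]
        assert pairwise_r2(G, "s1", "s2") == pytest.approx(r * r, rel=1e-12)

    def test_monomorphic_rejected(self):
        G = make_genotypes(np.column_stack([np.full(6, 1.0), np.arange(6) % 3]).astype(float))
        with pytest.raises(ValueError, match="monomorphic"):
            pairwise_r2(G, 0, 1)


class TestIndexSelection:
    def test_unlinked_snps_all_become_indices(self):
        cfg = single_trait_config(n=300, m=30, h2=0.0, seed=72, within_block_rho=0.0)
        G = simulate_genotypes(cfg)
        pv = np.random.default_rng(73).uniform(size=30)
        idx = select_index_snps(assoc_table(G, pv), G, window_kb=1e-3, r2_max=0.3)
        assert len(idx.snp_ids) == 30

    def test_three_snp_worked_example(self):
        """p = (0.01, 0.001, 0.5) with strong LD between 1 and 2 only:
        SNP2 indexes first and absorbs SNP1; SNP3 stands alone."""
        rng = np.random.default_rng(74)
        n = 400
        s2 = rng.binomial(2, 0.4, size=n).astype(float)
        flip = rng.random(n) < 0.12
        s1 = np.where(flip, np.abs(2 - s2 - rng.integers(0, 2, n)), s2)  # high LD
        s3 = rng.binomial(2, 0.4, size=n).astype(float)                 # unlinked
        G = make_genotypes(np.column_stack([s1, s2, s3]), bp=[1000, 2000, 3000])
        assert pairwise_r2(G, 0, 1) > 0.3
        assert pairwise_r2(G, 1, 2) <= 0.3
        table = assoc_table(G, [0.01, 0.001, 0.5])
        idx = select_index_snps(table, G, window_kb=500, r2_max=0.3)
        assert idx.snp_ids == ["s2", "s3"]
        assert idx.assignment["s1"] == "s2"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(75)
        for rep in range(50):
            cfg = single_trait_config(
                n=120, m=20, h2=0.0, seed=1000 + rep, within_block_rho=0.7,
                block_size=4, chrom_length_bp=3_000_000,
            )
            G = simulate_genotypes(cfg)
            pv = rng.uniform(size=20)
            window_kb, r2_max = 400, 0.25
            got = select_index_snps(assoc_table(G, pv), G, window_kb, r2_max)
            bp = G.snp_map["bp"].to_numpy(dtype=float)
            r2 = np.zeros((20, 20))
            for i in range(20):
                for j in range(i + 1, 20):
                    try:
                        r2[i, j] = r2[j, i] = pairwise_r2(G, i, j)
                    except ValueError:
                        pass
            expect = greedy_oracle(pv, bp, r2, window_kb * 1000, r2_max)
            snp_ids = G.snp_map["snp_id"].to_numpy()
            assert got.assignment == {
                snp_ids[j]: snp_ids[i] for j, i in expect.items()
            }

    def test_partition_and_row_order_invariance(self):
        cfg = single_trait_config(n=200, m=40, h2=0.0, seed=76, within_block_rho=0.8,
                                  block_size=5, chrom_length_bp=2_000_000)
        G = simulate_genotypes(cfg)
        pv = np.random.default_rng(77).uniform(size=40)
        table = assoc_table(G, pv)
        idx = select_index_snps(table, G)
        assert set(idx.assignment) == set(G.snp_map["snp_id"])
        assert set(idx.assignment.values()) == set(idx.snp_ids)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        idx2 = select_index_snps(shuffled, G)
        assert idx2.assignment == idx.assignment

    def test_sliding_window_mode_ignores_p_and_partitions(self):
        from countgwas.clump import prune_sliding_window

        cfg = single_trait_config(n=250, m=40, h2=0.0, seed=84, within_block_rho=0.9,
                                  block_size=5, chrom_length_bp=2_000_000)
        G = simulate_genotypes(cfg)
        idx = prune_sliding_window(G, window_kb=500, r2_max=0.3)
        assert set(idx.assignment) == set(G.snp_map["snp_id"])
        assert set(idx.assignment.values()) == set(idx.snp_ids)
        # retained set is mutually below-threshold within the window
        bp = dict(zip(G.snp_map["snp_id"], G.snp_map["bp"]))
        kept = idx.snp_ids
        for a in range(len(kept)):
            for b in range(a + 1, len(kept)):
                if abs(bp[kept[a]] - bp[kept[b]]) <= 500_000:
                    assert pairwise_r2(G, kept[a], kept[b]) <= 0.3

    def test_index_count_monotone_in_r2_threshold(self):
        cfg = single_trait_config(n=300, m=60, h2=0.0, seed=78, within_block_rho=0.9,
                                  block_size=6, chrom_length_bp=2_000_000)
        G = simulate_genotypes(cfg)
        table = assoc_table(G, np.random.default_rng(79).uniform(size=60))
        counts = [
            len(select_index_snps(table, G, r2_max=r2).snp_ids)
            for r2 in (0.1, 0.3, 0.5, 0.8)
        ]
        assert counts == sorted(counts)


class TestRegions:
    def test_isolated_snp_has_point_span(self):
        cfg = single_trait_config(n=200, m=5, h2=0.0, seed=80, within_block_rho=0.0,
                                  chrom_length_bp=100_000_000)
        G = simulate_genotypes(cfg)
        region = clump_region(0, G, window_kb=1e-3, r2_min=0.3)
        bp0 = int(G.snp_map.loc[0, "bp"])
        assert (region.start_bp, region.end_bp) == (bp0, bp0)
        assert region.members == [G.snp_map.loc[0, "snp_id"]]

    def test_perfect_ld_block_spans_block(self):
        rng = np.random.default_rng(81)
        base = rng.binomial(2, 0.4, size=200).astype(float)
        dos = np.column_stack([base, base, 2 - base, base, base])
        G = make_genotypes(dos, bp=[100, 200, 300, 400, 500])
        region = clump_region(2, G, window_kb=1.0, r2_min=0.3)
        assert (region.start_bp, region.end_bp) == (100, 500)
        assert len(region.members) == 5

    def test_membership_matches_exhaustive_threshold(self):
        cfg = single_trait_config(n=250, m=30, h2=0.0, seed=82, within_block_rho=0.8,
                                  block_size=5, chrom_length_bp=1_000_000)
        G = simulate_genotypes(cfg)
        bp = G.snp_map["bp"].to_numpy(dtype=float)
        i = 12
        region = clump_region(i, G, window_kb=200, r2_min=0.3)
        expect = {G.snp_map.loc[i, "snp_id"]}
        for j in range(30):
            if j != i and abs(bp[j] - bp[i]) <= 200_000 and pairwise_r2(G, i, j) > 0.3:
                expect.add(G.snp_map.loc[j, "snp_id"])
        assert set(region.members) == expect


class TestGeneOverlap:
    def _genes(self, rows):
        return GeneSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                                   "is_candidate"]))

    def test_containment_and_halfopen_boundary(self):
        genes = self._genes([("1", 100, 200, "g1", True)])
        inside = ClumpedRegion("s", "1", 150, 160, ["s"])
        assert region_overlaps_genes(inside, genes)[0]
        # region starting exactly at the gene end does not overlap
        abutting = ClumpedRegion("s", "1", 201, 300, ["s"])
        flag, names = region_overlaps_genes(abutting, genes)
        assert not flag and names == []
        touching = ClumpedRegion("s", "1", 200, 300, ["s"])
        assert region_overlaps_genes(touching, genes)[0]

    def test_candidate_only_filtering_and_chrom_mismatch(self):
        genes = self._genes([("1", 100, 200, "g1", False), ("2", 100, 200, "g2", True)])
        region = ClumpedRegion("s", "1", 120, 180, ["s"])
        assert not region_overlaps_genes(region, genes, candidate_only=True)[0]
        assert region_overlaps_genes(region, genes, candidate_only=False)[0]
        region2 = ClumpedRegion("s", "3", 120, 180, ["s"])
        with pytest.warns(UserWarning, match="chromosome"):
            flag, _ = region_overlaps_genes(region2, genes, candidate_only=False)
        assert not flag

    def test_random_overlap_fraction_matches_interval_oracle(self):
        rng = np.random.default_rng(83)
        genes = self._genes(
            [("1", int(s), int(s + rng.integers(50, 500)), f"g{k}", True)
             for k, s in enumerate(rng.integers(0, 100_000, size=60))]
        )
        hits = 0
        oracle_hits = 0
        for k in range(200):
            a = int(rng.integers(0, 100_000))
            b = a + int(rng.integers(1, 2000))
            region = ClumpedRegion("s", "1", a + 1, b, ["s"])
            flag, _ = region_overlaps_genes(region, genes)
            hits += flag
            oracle_hits += any(
                max(a, s) < min(b, e)
                for s, e in zip(genes.intervals["start"], genes.intervals["end"])
            )
        assert hits == oracle_hits
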