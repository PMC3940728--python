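"""Generator checks: LD structure, MAF spectrum, count-model moments and
gene annotation geometry."""

import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import spearmanr

from countgwas import (
    SimConfig,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotype_panel,
)
from .conftest import single_trait_config


def adjacent_r2(G):
    d = G.dosages
    out = []
    for j in range(d.shape[1] - 1):
        r = np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
        out.append(r * r)
    return np.array(out)


class TestGenotypes:
    def test_independent_snps_have_negligible_ld(self):
        cfg = single_trait_config(n=2000, m=100, h2=0.0, seed=1, within_block_rho=0.0)
        G = simulate_genotypes(cfg)
        assert adjacent_r2(G).mean() < 0.01

    def test_block_r2_matches_thresholded_gaussian_oracle(self):
        """Within-block dosage r^2 agrees with direct Monte-Carlo integration
        of the thresholded exchangeable bivariate normal."""
        rho, maf = 0.9, 0.3
        cfg = single_trait_config(
            n=2000, m=10, h2=0.0, seed=2, within_block_rho=rho, block_size=10,
            maf_range=(maf, maf),
        )
        G = simulate_genotypes(cfg)
        observed = adjacent_r2(G).mean()

        rng = np.random.default_rng(12345)
        n_hap = 1_000_000
        shared = rng.standard_normal(n_hap)
        z1 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n_hap)
        z2 = np.sqrt(rho) * shared + np.sqrt(1 - rho) * rng.standard_normal(n_hap)
        t = ndtri(maf)
        r = np.corrcoef(z1 < t, z2 < t)[0, 1]
        oracle = r * r  # dosage corr equals haplotype allele corr for iid haplotypes
        assert observed == pytest.approx(oracle, abs=0.05)

    def test_observed_maf_within_binomial_bounds(self):
        cfg = single_trait_config(n=1500, m=300, h2=0.0, seed=3, maf_range=(0.1, 0.4))
        G = simulate_genotypes(cfg)
        se = np.sqrt(0.4 * 0.6 / (2 * cfg.n_individuals))
        maf = G.maf()
        assert maf.min() >= 0.1 - 3 * se
        assert maf.max() <= 0.4 + 3 * se

    def test_positions_strictly_increasing_and_deterministic(self):
        cfg = single_trait_config(n=50, m=80, h2=0.0, seed=4)
        G1 = simulate_genotypes(cfg)
        G2 = simulate_genotypes(cfg)
        assert np.all(np.diff(G1.snp_map["bp"]) > 0)
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        assert G1.snp_map.equals(G2.snp_map)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_individuals=0)
        with pytest.raises(ValueError):
            single_trait_config(n=10, m=10, h2=0.0, seed=0, within_block_rho=1.0)
        with pytest.raises(ValueError):
            single_trait_config(n=10, m=10, h2=1.0, seed=0)
        with pytest.raises(ValueError):
            SimConfig(rg_matrix=((1.0, 0.5), (0.4, 1.0)), timepoints=(8.0, 11.0),
                      h2_by_timepoint=(0.2, 0.2),
                      re_matrix=((1.0, 0.3), (0.3, 1.0)))


class TestPhenotypes:
    def test_poisson_limit_variance_equals_mean(self):
        """With vanishing frailty variance and no latent heterogeneity the
        counts are plain Poisson: variance/mean near 1 on 1e5 draws."""
        cfg = single_trait_config(
            n=100_000, m=20, h2=0.0, seed=5, n_causal=0,
            dispersion_theta=1e6, latent_sd=0.0,
            covar_effects={"age": 0.0, "sex": 0.0, "pc1": 0.0, "pc2": 0.0},
        )
        G = simulate_genotypes(cfg)
        panel = simulate_phenotype_panel(G, cfg)
        s = panel.scores(8.0)
        assert s.var() / s.mean() == pytest.approx(1.0, abs=0.1)

    def test_gamma_frailty_overdispersion_matches_nb_moments(self):
        """Marginal variance of the mixed Poisson follows the
        negative-binomial moment formula m + m^2*((1+1/theta)*e^{s2}-1)."""
        theta, lsd, b0 = 2.0, 0.5, 0.3
        cfg = single_trait_config(
            n=100_000, m=20, h2=0.0, seed=6, n_causal=0,
            dispersion_theta=theta, latent_sd=lsd, baseline_log_mean=b0,
            covar_effects={"age": 0.0, "sex": 0.0, "pc1": 0.0, "pc2": 0.0},
        )
        G = simulate_genotypes(cfg)
        panel = simulate_phenotype_panel(G, cfg)
        s = panel.scores(8.0)
        s2 = lsd**2
        m = np.exp(b0 + s2 / 2)
        var = m + m**2 * ((1 + 1 / theta) * np.exp(s2) - 1)
        assert s.mean() == pytest.approx(m, rel=0.05)
        assert s.var() == pytest.approx(var, rel=0.15)

    def test_study_scale_moments(self):
        """A run at study scale with the bounded instrument reproduces the
        target score SDs and adjacent-age rank correlations."""
        cfg = SimConfig(n_individuals=5000, n_snps=600, block_size=10, seed=7,
                        clip_to_range=True)
        G = simulate_genotypes(cfg)
        panel = simulate_phenotype_panel(G, cfg)
        for t in cfg.timepoints:
            s = panel.scores(t)
            assert 3.0 <= s.std() <= 4.5
            assert s.max() <= 24
            assert 0 <= np.median(s) <= 2
        for a, b in [(8.0, 11.0), (11.0, 14.0), (14.0, 17.0)]:
            rho = spearmanr(panel.scores(a), panel.scores(b)).statistic
            assert 0.3 <= rho <= 0.7

    def test_latent_heritability_partition(self):
        cfg = single_trait_config(n=4000, m=500, h2=0.4, seed=8, n_causal=100)
        G = simulate_genotypes(cfg)
        panel = simulate_phenotype_panel(G, cfg)
        g, lat = panel.genetic_values[:, 0], panel.latent[:, 0]
        assert g.var() / lat.var() == pytest.approx(0.4, abs=0.03)

    def test_deterministic_given_seed(self):
        cfg = single_trait_config(n=200, m=100, h2=0.3, seed=9)
        G = simulate_genotypes(cfg)
        p1 = simulate_phenotype_panel(G, cfg)
        p2 = simulate_phenotype_panel(G, cfg)
        assert p1.table.equals(p2.table)


class TestGeneAnnotation:
    def test_candidate_flag_counts(self):
        cfg = SimConfig(seed=10)
        genes = simulate_gene_annotation(cfg, n_genes=400, candidate_fraction=0.02,
                                         mean_len_bp=30_000)
        assert genes.intervals["is_candidate"].sum() == 8
        all_flagged = simulate_gene_annotation(cfg, 50, 1.0, 30_000)
        assert all_flagged.intervals["is_candidate"].all()

    def test_coverage_matches_poisson_approximation(self):
        """Fraction of chromosome covered by the union of uniform genes is
        close to 1 - exp(-n*len/L); the oracle is direct interval-union
        arithmetic on the generated set."""
        cfg = SimConfig(chrom_length_bp=10_000_000, seed=11)
        n_genes, mean_len = 300, 20_000
        genes = simulate_gene_annotation(cfg, n_genes, 0.1, mean_len)
        iv = genes.intervals.sort_values("start")
        covered, cur_s, cur_e = 0, -1, -1
        for s, e in zip(iv["start"], iv["end"]):
            if s > cur_e:
                covered += max(cur_e - cur_s, 0)
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += max(cur_e - cur_s, 0)
        frac = covered / cfg.chrom_length_bp
        expected = 1 - np.exp(-n_genes * mean_len / cfg.chrom_length_bp)
        assert frac == pytest.approx(expected, rel=0.15)

    def test_gene_longer_than_chromosome_rejected(self):
        cfg = SimConfig(chrom_length_bp=10_000, n_snps=100, n_causal=50, seed=12)
        with pytest.raises(ValueError):
            simulate_gene_annotation(cfg, 5, 0.5, 1_000_000)
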