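"""GRM algebra, the rank-based inverse-normal transform, and univariate /
bivariate REML behaviour on simulated truth."""

import numpy as np
import pytest
from scipy.special import ndtri

from countgwas import (
    SimConfig,
    adjust_and_rank_transform,
    compute_grm,
    read_grm,
    reml_bivariate,
    reml_univariate,
    simulate_genotypes,
    simulate_phenotype_panel,
    write_grm,
)
from countgwas.reml import reml_univariate_em
from .conftest import make_genotypes, single_trait_config


class TestGrm:
    def test_single_snp_hand_example(self):
        # one SNP, dosages (2, 0): p = 0.5, A_jk = (1)(-1)/0.5 = -2
        G = make_genotypes(np.array([[2.0], [0.0]]))
        grm = compute_grm(G)
        assert grm.values[0, 1] == pytest.approx(-2.0)
        assert grm.values[0, 0] == pytest.approx(2.0)

    def test_duplicated_individuals_have_equal_entries(self):
        rng = np.random.default_rng(41)
        dos = rng.binomial(2, 0.3, size=(20, 100)).astype(float)
        dos[5] = dos[3]
        grm = compute_grm(make_genotypes(dos))
        assert grm.values[3, 5] == pytest.approx(grm.values[3, 3])
        assert grm.values[3, 3] == pytest.approx(grm.values[5, 5])

    def test_mean_diagonal_near_one_for_unrelateds(self):
        cfg = single_trait_config(n=500, m=2000, h2=0.0, seed=42)
        grm = compute_grm(simulate_genotypes(cfg))
        assert np.diag(grm.values).mean() == pytest.approx(1.0, abs=0.02)

    def test_monomorphic_excluded_with_warning(self):
        rng = np.random.default_rng(43)
        dos = rng.binomial(2, 0.4, size=(30, 5)).astype(float)
        dos[:, 2] = 2.0
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(make_genotypes(dos))
        assert np.all(grm.n_markers == 4)

    def test_binary_round_trip(self, tmp_path):
        cfg = single_trait_config(n=40, m=300, h2=0.0, seed=44)
        grm = compute_grm(simulate_genotypes(cfg))
        write_grm(grm, tmp_path / "g")
        back = read_grm(tmp_path / "g")
        np.testing.assert_allclose(back.values, grm.values, atol=1e-6)
        np.testing.assert_allclose(back.n_markers, grm.n_markers)
        assert back.sample_ids == grm.sample_ids


class TestRankTransform:
    def test_blom_quantiles_on_tied_example(self):
        out = adjust_and_rank_transform(np.array([5.0, 2.0, 2.0]))
        expect = ndtri(np.array([2.625, 1.125, 1.125]) / 3.25)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_zero_mean_and_monotone_without_ties(self):
        rng = np.random.default_rng(45)
        y = rng.gamma(2.0, 1.0, size=501)
        out = adjust_and_rank_transform(y)
        assert abs(out.mean()) < 1e-8
        order = np.argsort(y)
        assert np.all(np.diff(out[order]) > 0)

    def test_large_sample_identity_on_normal_input(self):
        rng = np.random.default_rng(46)
        y = rng.standard_normal(10_000)
        out = adjust_and_rank_transform(y)
        assert np.corrcoef(y, out)[0, 1] > 0.999

    def test_covariate_adjustment_removes_signal(self):
        rng = np.random.default_rng(47)
        x = rng.standard_normal(400)
        y = np.round(3 * x + rng.standard_normal(400), 3)
        out = adjust_and_rank_transform(y, x)
        assert abs(np.corrcoef(out, x)[0, 1]) < 0.1

    def test_missing_values_propagate(self):
        y = np.array([1.0, np.nan, 3.0, 2.0, 5.0])
        out = adjust_and_rank_transform(y)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3, 4]]).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjust_and_rank_transform(np.full(10, 4.0))


class TestUnivariateReml:
    def test_recovers_simulated_heritability(self, heritable_sim):
        cfg, G, panel, grm = heritable_sim
        fit = reml_univariate(grm, panel.latent[:, 0])
        assert fit.converged
        assert abs(fit.h2 - 0.45) < 2 * fit.se_h2

    def test_null_phenotype_estimates_near_zero(self, heritable_sim):
        _, _, _, grm = heritable_sim
        y = np.random.default_rng(48).standard_normal(grm.n)
        fit = reml_univariate(grm, y)
        assert fit.h2 < 2 * fit.se_h2
        assert fit.p_value > 0.01

    def test_scale_invariance(self, heritable_sim):
        _, _, panel, grm = heritable_sim
        y = panel.latent[:, 0]
        f1 = reml_univariate(grm, y)
        f2 = reml_univariate(grm, 7.3 * y)
        assert f2.h2 == pytest.approx(f1.h2, abs=1e-5)
        assert f2.var_g == pytest.approx(7.3**2 * f1.var_g, rel=1e-3)

    def test_identity_grm_is_unidentifiable(self):
        y = np.random.default_rng(49).standard_normal(100)
        with pytest.raises(ValueError, match="identifiable"):
            reml_univariate(np.eye(100), y)

    def test_em_loglik_never_decreases(self, heritable_sim):
        _, _, panel, grm = heritable_sim
        keep = slice(0, 300)
        traj = reml_univariate_em(grm.values[keep, keep], panel.latent[keep, 0],
                                  n_iter=30)
        assert np.all(np.diff(traj) > -1e-8)

    def test_missing_phenotypes_dropped(self, heritable_sim):
        _, _, panel, grm = heritable_sim
        y = panel.latent[:, 0].copy()
        y[:50] = np.nan
        fit = reml_univariate(grm, y)
        assert fit.n == grm.n - 50
        assert abs(fit.h2 - 0.45) < 3 * fit.se_h2

    def test_lrt_mixture_halves_pvalue(self, heritable_sim):
        _, _, panel, grm = heritable_sim
        y = panel.latent[:, 0]
        plain = reml_univariate(grm, y)
        mix = reml_univariate(grm, y, lrt_mixture=True)
        assert mix.p_value == pytest.approx(0.5 * plain.p_value, rel=1e-9)


@pytest.fixture(scope="module")
def bivar_sim():
    cfg = SimConfig(
        n_individuals=1000, n_snps=1500, block_size=1, within_block_rho=0.0,
        timepoints=(8.0, 17.0), h2_by_timepoint=(0.4, 0.4),
        rg_matrix=((1.0, 0.5), (0.5, 1.0)), re_matrix=((1.0, 0.4), (0.4, 1.0)),
        n_causal=250, seed=50,
    )
    G = simulate_genotypes(cfg)
    panel = simulate_phenotype_panel(G, cfg)
    return cfg, panel, compute_grm(G)


class TestBivariateReml:
    def test_recovers_genetic_and_residual_correlation(self, bivar_sim):
        _, panel, grm = bivar_sim
        fit = reml_bivariate(grm, panel.latent[:, 0], panel.latent[:, 1])
        assert fit.converged and fit.rg_defined and fit.re_defined
        assert abs(fit.rg - 0.5) < 2.5 * fit.se_rg
        assert abs(fit.re - 0.4) < 2.5 * fit.se_re

    def test_identical_traits_give_unit_correlations(self, bivar_sim):
        _, panel, grm = bivar_sim
        y = panel.latent[:, 0]
        fit = reml_bivariate(grm, y, y.copy())
        assert fit.rg == pytest.approx(1.0, abs=5e-3)
        assert fit.re == pytest.approx(1.0, abs=5e-3)

    def test_uncorrelated_traits_estimate_near_zero(self):
        cfg = SimConfig(
            n_individuals=1000, n_snps=1500, block_size=1, within_block_rho=0.0,
            timepoints=(8.0, 17.0), h2_by_timepoint=(0.4, 0.4),
            rg_matrix=((1.0, 0.0), (0.0, 1.0)), re_matrix=((1.0, 0.0), (0.0, 1.0)),
            n_causal=250, seed=51,
        )
        G = simulate_genotypes(cfg)
        panel = simulate_phenotype_panel(G, cfg)
        fit = reml_bivariate(compute_grm(G), panel.latent[:, 0], panel.latent[:, 1])
        assert abs(fit.rg) < 2.5 * fit.se_rg
        assert abs(fit.re) < 2.5 * fit.se_re

    def test_zero_heritability_trait_flags_rg_undefined(self, bivar_sim):
        _, panel, grm = bivar_sim
        noise = np.random.default_rng(52).standard_normal(grm.n)
        fit = reml_bivariate(grm, panel.latent[:, 0], noise)
        assert not fit.rg_defined
        assert np.isnan(fit.rg)

    def test_phenotypic_correlation_decomposition(self, bivar_sim):
        """Observed trait correlation matches
        rg*sqrt(h1*h2) + re*sqrt((1-h1)(1-h2)) under the generative model."""
        cfg, panel, _ = bivar_sim
        obs = np.corrcoef(panel.latent[:, 0], panel.latent[:, 1])[0, 1]
        expect = 0.5 * 0.4 + 0.4 * 0.6
        assert obs == pytest.approx(expect, abs=0.06)
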