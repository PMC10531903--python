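import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

import episig as ep
from episig.differential_methylation import ModelError, ProbeFits

from conftest import toy_beta


def _two_group_design(n1, n2):
    cols = [f"s{i}" for i in range(n1 + n2)]
    return pd.DataFrame({"intercept": 1.0,
                         "group": [1.0] * n1 + [0.0] * n2}, index=cols)


class TestFitDmpModel:
    def test_coef_equals_group_mean_difference(self):
        rng = np.random.default_rng(0)
        m = toy_beta(rng.normal(0, 1, size=(50, 10)))
        fits = ep.fit_dmp_model(m, _two_group_design(4, 6))
        expected = (m.iloc[:, :4].mean(axis=1)
                    - m.iloc[:, 4:].mean(axis=1)).to_numpy()
        assert np.allclose(fits.coef, expected, atol=1e-12)

    def test_orthogonal_covariate_leaves_coef_unchanged(self):
        rng = np.random.default_rng(1)
        m = toy_beta(rng.normal(0, 1, size=(30, 8)))
        design = _two_group_design(4, 4)
        base = ep.fit_dmp_model(m, design)
        # covariate orthogonal to both intercept and group indicator
        design2 = design.copy()
        design2["cov"] = [1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0]
        aug = ep.fit_dmp_model(m, design2)
        assert np.allclose(base.coef, aug.coef, atol=1e-10)

    def test_monte_carlo_coefficient_recovery(self):
        rng = np.random.default_rng(2)
        n = 60
        design = _two_group_design(n // 2, n // 2)
        g = design["group"].to_numpy()
        m = toy_beta(0.7 * g + rng.normal(0, 0.1, size=(400, n)))
        fits = ep.fit_dmp_model(m, design)
        assert abs(fits.coef.mean() - 0.7) < 0.05

    def test_missing_values_adjust_df(self):
        rng = np.random.default_rng(3)
        m = toy_beta(rng.normal(0, 1, size=(20, 10)))
        m.iloc[0, 0] = np.nan
        fits = ep.fit_dmp_model(m, _two_group_design(5, 5))
        assert fits.df_resid[0] == 7 and fits.df_resid[1] == 8

    def test_rank_deficient_design_rejected(self):
        m = toy_beta(np.random.default_rng(4).normal(size=(10, 6)))
        design = _two_group_design(3, 3)
        design["dup"] = design["group"]
        with pytest.raises(ModelError):
            ep.fit_dmp_model(m, design)


class TestModerateStatistics:
    def test_equal_variances_collapse_to_ordinary_t(self):
        """When every probe has exactly the same residual variance, the
        prior is degenerate and moderated t == ordinary t."""
        n_probes, df = 50, 10
        coef = np.linspace(-1, 1, n_probes)
        fits = ProbeFits(pd.Index([f"p{i}" for i in range(n_probes)]),
                         coef=coef,
                         sigma2=np.full(n_probes, 0.25),
                         df_resid=np.full(n_probes, float(df)),
                         stdev_unscaled=np.full(n_probes, 0.5))
        stats = ep.moderate_statistics(fits)
        ordinary = coef / (0.5 * 0.5)
        assert np.allclose(stats["t_moderated"], ordinary, atol=1e-8)
        assert np.allclose(stats["s2_posterior"], 0.25, atol=1e-10)

    def test_zero_prior_df_override_gives_ordinary_t(self):
        rng = np.random.default_rng(5)
        m = toy_beta(rng.normal(0, 1, size=(100, 12)))
        fits = ep.fit_dmp_model(m, _two_group_design(6, 6))
        stats = ep.moderate_statistics(fits, prior_df=0)
        ordinary = fits.coef / (np.sqrt(fits.sigma2) * fits.stdev_unscaled)
        assert np.allclose(stats["t_moderated"], ordinary, atol=1e-12)
        assert (stats["df_total"] == fits.df_resid).all()

    def test_shrinkage_bound(self):
        rng = np.random.default_rng(6)
        m = toy_beta(rng.normal(0, rng.uniform(0.5, 2, size=(300, 1)),
                                size=(300, 12)))
        fits = ep.fit_dmp_model(m, _two_group_design(6, 6))
        stats = ep.moderate_statistics(fits)
        s2_prior = stats.attrs["s2_prior"]
        lo = np.minimum(fits.sigma2, s2_prior) - 1e-12
        hi = np.maximum(fits.sigma2, s2_prior) + 1e-12
        post = stats["s2_posterior"].to_numpy()
        assert ((post >= lo) & (post <= hi)).all()

    def test_bh_monotone_after_sorting_by_p(self):
        rng = np.random.default_rng(7)
        m = toy_beta(rng.normal(0, 1, size=(500, 10)))
        fits = ep.fit_dmp_model(m, _two_group_design(5, 5))
        stats = ep.moderate_statistics(fits).sort_values("p_value")
        adj = stats["p_adjusted"].to_numpy()
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= stats["p_value"].to_numpy() - 1e-12).all()

    def test_all_zero_variances_rejected(self):
        fits = ProbeFits(pd.Index([f"p{i}" for i in range(20)]),
                         coef=np.zeros(20), sigma2=np.zeros(20),
                         df_resid=np.full(20, 5.0),
                         stdev_unscaled=np.full(20, 0.5))
        with pytest.raises(ModelError):
            ep.moderate_statistics(fits)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not on PATH")
    def test_matches_limma_reference(self, tmp_path):
        """Independent cross-check of the empirical-Bayes moderation
        against the R/Bioconductor limma implementation."""
        rng = np.random.default_rng(42)
        n_probes, n1, n2 = 120, 5, 7
        y = rng.normal(0, rng.uniform(0.5, 2.0, size=(n_probes, 1)),
                       size=(n_probes, n1 + n2))
        y[:20, :n1] += 1.0
        m = toy_beta(y)
        stats = ep.moderate_statistics(
            ep.fit_dmp_model(m, _two_group_design(n1, n2)))
        m_path = tmp_path / "m.tsv"
        out_path = tmp_path / "limma.csv"
        m.to_csv(m_path, sep="\t")
        script = f'''
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{m_path}", row.names=1))
            design <- cbind(Intercept=1, Group=c(rep(1,{n1}), rep(0,{n2})))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"],
                                 dfp=fit$df.prior, s2p=fit$s2.prior),
                      "{out_path}")
        '''
        res = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, timeout=300)
        if res.returncode != 0:
            pytest.skip(f"limma unavailable: {res.stderr[-200:]}")
        ref = pd.read_csv(out_path, index_col=0)
        assert np.allclose(stats["t_moderated"], ref["t"], atol=1e-8)
        assert np.allclose(stats["p_value"], ref["p"], atol=1e-10)
        assert stats.attrs["df_prior"] == pytest.approx(
            ref["dfp"].iloc[0], rel=1e-5)


class TestGroupMeans:
    def test_identical_groups_zero_delta(self):
        beta = toy_beta(np.full((4, 6), 0.4))
        out = ep.compute_group_means(beta, ["s0", "s1", "s2"],
                                     ["s3", "s4", "s5"])
        assert (out["delta_beta"] == 0).all()

    def test_exact_constant_delta(self):
        beta = toy_beta(np.hstack([np.full((3, 2), 0.3),
                                   np.full((3, 3), 0.4)]))
        out = ep.compute_group_means(beta, ["s0", "s1"], ["s2", "s3", "s4"])
        assert np.allclose(out["delta_beta"], -0.1, atol=1e-12)

    def test_matches_hand_computed_toy(self):
        vals = np.array([[0.1, 0.2, 0.3, 0.4],
                         [0.5, 0.5, 0.1, 0.9],
                         [0.0, 1.0, 0.5, 0.5],
                         [0.2, 0.4, 0.6, 0.8],
                         [0.9, 0.8, 0.7, 0.6]])
        beta = toy_beta(vals)
        out = ep.compute_group_means(beta, ["s0", "s1"], ["s2", "s3"])
        for i in range(5):
            assert out["mean_beta_case"].iloc[i] == pytest.approx(
                vals[i, :2].mean())
            assert out["delta_beta"].iloc[i] == pytest.approx(
                vals[i, :2].mean() - vals[i, 2:].mean())

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ep.compute_group_means(toy_beta([[0.5]]), [], ["s0"])


def test_covariate_adjustment_reduces_confounded_t(small_manifest):
    """Cell-composition confounded probes lose |t| when proportions enter
    the design."""
    manifest, annot = small_manifest
    study = ep.simulate_cohort(manifest, 12, 60,
                               ep.SignatureSpec(0, 0.0),
                               confound_strength=1.0, seed=40,
                               annotation=annot)
    cases = study.case_ids
    sheet = study.samples
    mr = ep.match_controls(sheet[sheet["group"] == "case"],
                           sheet[sheet["group"] == "control_pool"])
    m = ep.beta_to_m(study.beta)
    adj = ep.dmp_statistics(study.beta, m, sheet, cases,
                            mr.matched_control_ids)
    raw = ep.dmp_statistics(study.beta, m, sheet, cases,
                            mr.matched_control_ids,
                            use_cell_covariates=False)
    conf = study.truth_confounded
    assert (adj.loc[conf, "t_moderated"].abs().median()
            < raw.loc[conf, "t_moderated"].abs().median())
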