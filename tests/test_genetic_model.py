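import numpy as np
import pandas as pd
import pytest

from mulard import genetic_model as gm
from mulard import pedigree as pg
from mulard import simdata
from tests.conftest import make_crossbred_frame


class TestNormalityScreen:
    def test_normal_data_mostly_passes(self):
        rng = np.random.default_rng(1)
        passes = 0
        n_rep = 150
        for r in range(n_rep):
            df = pd.DataFrame({"x": rng.standard_normal(1000)})
            passes += gm.check_normality(df, ["x"])["normal"].iloc[0]
        # KS with estimated parameters is conservative: pass rate >= nominal
        assert passes / n_rep >= 0.93

    def test_exponential_data_fails(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.exponential(size=1000)})
        assert not gm.check_normality(df, ["x"])["normal"].iloc[0]

    def test_constant_trait_flagged_degenerate(self):
        df = pd.DataFrame({"x": np.ones(100)})
        report = gm.check_normality(df, ["x"])
        assert "degenerate" in report["note"].iloc[0]

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="fewer than 8"):
            gm.check_normality(pd.DataFrame({"x": np.arange(5.0)}), ["x"])


class TestDerivedQuantities:
    def _summary_with_constant_samples(self, GA, GB, R, n=50):
        t = GA.shape[0]
        mk = lambda M: np.repeat(M[None], n, axis=0)
        return gm.PosteriorSummary(
            traits=tuple(f"t{i}" for i in range(t)),
            samples_G_dam=mk(GA), samples_G_sire=mk(GB), samples_R=mk(R),
            ebv_dam=np.zeros((4, t)), ebv_sire=np.zeros((4, t)),
            ebv_dam_sd=np.zeros((4, t)), ebv_sire_sd=np.zeros((4, t)),
            dam_ids=np.arange(4), sire_ids=np.arange(4),
            config=gm.GibbsConfig(chain_length=10, burn_in=1),
        )

    def test_heritability_arithmetic(self):
        s = self._summary_with_constant_samples(
            np.array([[0.2]]), np.array([[0.1]]), np.array([[0.7]])
        )
        assert s.heritability("dam", "t0") == (pytest.approx(0.2), pytest.approx(0.0))
        assert s.heritability("sire", "t0")[0] == pytest.approx(0.1)

    def test_equal_components_give_one_third(self):
        s = self._summary_with_constant_samples(
            np.array([[1.0]]), np.array([[1.0]]), np.array([[1.0]])
        )
        assert s.heritability("dam", "t0")[0] == pytest.approx(1 / 3)

    def test_diagonal_G_zero_correlation(self):
        s = self._summary_with_constant_samples(
            np.diag([1.0, 2.0]), np.eye(2), np.eye(2)
        )
        assert s.genetic_correlation("dam", "t0", "t1")[0] == pytest.approx(0.0)

    def test_rank_one_G_unit_correlation(self):
        v = np.array([1.0, -0.5])
        s = self._summary_with_constant_samples(np.outer(v, v), np.eye(2), np.eye(2))
        assert s.genetic_correlation("dam", "t0", "t1")[0] == pytest.approx(-1.0)

    @pytest.mark.parametrize(
        "h2,line,expected",
        [(0.20, "dam", 0.40), (0.10, "sire", (0.20, 0.40)), (0.0, "dam", 0.0)],
    )
    def test_rescale_heritability(self, h2, line, expected):
        assert gm.rescale_heritability(h2, line) == pytest.approx(expected)

    def test_rescale_caps_at_one(self):
        assert gm.rescale_heritability(0.8, "dam") == 1.0
        assert gm.rescale_heritability(0.6, "sire") == (1.0, 1.0)

    def test_spearman_identity_and_reversal(self):
        x = np.array([3.0, 1.0, 2.0, 5.0])
        assert gm.ebv_rank_correlation(x, x) == pytest.approx(1.0)
        assert gm.ebv_rank_correlation(x, -x) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="at least 3"):
            gm.ebv_rank_correlation([1.0, 2.0], [1.0, 2.0])


class TestSamplerBasics:
    def test_chain_reproducibility(self, founder_pedigrees):
        ped_d, ped_s = founder_pedigrees
        df = make_crossbred_frame(
            np.random.default_rng(3), ped_d, ped_s, 150, 10.0, 5.0, 30.0
        )
        cfg = gm.GibbsConfig(chain_length=400, burn_in=100, seed=42)
        s1 = gm.gibbs_fit(df, ped_d, ped_s, ["y"], cfg)
        s2 = gm.gibbs_fit(df, ped_d, ped_s, ["y"], cfg)
        assert np.array_equal(s1.samples_G_dam, s2.samples_G_dam)
        assert np.array_equal(s1.ebv_dam, s2.ebv_dam)

    def test_missing_parent_rejected(self, founder_pedigrees):
        ped_d, ped_s = founder_pedigrees
        df = make_crossbred_frame(
            np.random.default_rng(4), ped_d, ped_s, 50, 10.0, 5.0, 30.0
        )
        df.loc[0, "dam"] = 999
        with pytest.raises(ValueError, match="not found"):
            gm.gibbs_fit(df, ped_d, ped_s, ["y"], gm.GibbsConfig(chain_length=10, burn_in=1))

    def test_zero_dam_variance_recovered_as_near_zero(self, founder_pedigrees):
        ped_d, ped_s = founder_pedigrees
        df = make_crossbred_frame(
            np.random.default_rng(5), ped_d, ped_s, 400, 0.0, 5.0, 30.0
        )
        summ = gm.gibbs_fit(
            df, ped_d, ped_s, ["y"],
            gm.GibbsConfig(chain_length=3000, burn_in=800, seed=6),
        )
        assert summ.heritability("dam", "y")[0] < 0.05

    def test_line_role_swap_symmetry(self, founder_pedigrees):
        """Swapping which line is 'dam' and which is 'sire' swaps the
        estimated components (up to Monte-Carlo error)."""
        ped_d, ped_s = founder_pedigrees
        df = make_crossbred_frame(
            np.random.default_rng(7), ped_d, ped_s, 600, 12.0, 8.0, 30.0
        )
        swapped = df.rename(columns={"dam": "sire", "sire": "dam"})
        cfg = gm.GibbsConfig(chain_length=4000, burn_in=1000, seed=8)
        s1 = gm.gibbs_fit(df, ped_d, ped_s, ["y"], cfg)
        s2 = gm.gibbs_fit(swapped, ped_s, ped_d, ["y"], cfg)
        d1 = s1.component_mean("G_dam")[0, 0]
        s2_sire = s2.component_mean("G_sire")[0, 0]
        sd = s1.component_sd("G_dam")[0, 0] + s2.component_sd("G_sire")[0, 0]
        assert abs(d1 - s2_sire) < sd

    def test_anova_oracle_unrelated_parents(self):
        """With unrelated parents and many records the posterior means match
        method-of-moments (ANOVA-style) component estimates."""
        rng = np.random.default_rng(9)
        nd, ns, per = 150, 150, 8
        ped_d = pg.from_frame(
            pd.DataFrame({"animal": np.arange(1, nd + 1), "sire": 0, "dam": 0})
        )
        ped_s = pg.from_frame(
            pd.DataFrame({"animal": np.arange(1, ns + 1), "sire": 0, "dam": 0})
        )
        s2d, s2e = 25.0, 75.0
        ud = rng.normal(0, np.sqrt(s2d), nd)
        # balanced one-way layout in dams; sires carry no variance
        dam = np.repeat(np.arange(nd), per)
        sire = rng.integers(ns, size=nd * per)
        y = 50 + ud[dam] + rng.normal(0, np.sqrt(s2e), nd * per)
        df = pd.DataFrame(
            {"animal": [f"C{i}" for i in range(nd * per)],
             "dam": dam + 1, "sire": sire + 1, "fixed_level": 1, "y": y}
        )
        summ = gm.gibbs_fit(
            df, ped_d, ped_s, ["y"],
            gm.GibbsConfig(chain_length=4000, burn_in=1000, seed=10),
        )
        # one-way ANOVA estimator of the dam component
        groups = df.groupby("dam")["y"]
        msb = groups.mean().var(ddof=1) * per
        msw = groups.var(ddof=1).mean()
        anova_dam = (msb - msw) / per
        est = summ.component_mean("G_dam")[0, 0]
        sd = summ.component_sd("G_dam")[0, 0]
        assert abs(est - anova_dam) < 2.5 * sd
        assert summ.component_mean("R")[0, 0] == pytest.approx(msw, rel=0.15)

    def test_divergence_reported_for_missing_values(self, founder_pedigrees):
        ped_d, ped_s = founder_pedigrees
        df = make_crossbred_frame(
            np.random.default_rng(11), ped_d, ped_s, 50, 10.0, 5.0, 30.0
        )
        df.loc[3, "y"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            gm.gibbs_fit(df, ped_d, ped_s, ["y"], gm.GibbsConfig(chain_length=10, burn_in=1))


class TestDiagnostics:
    def test_ess_of_iid_chain_near_n(self, rng):
        x = rng.standard_normal(2000)
        assert gm.effective_sample_size(x) > 1000

    def test_rhat_near_one_for_stationary_chain(self, rng):
        x = rng.standard_normal(2000)
        assert gm.split_chain_rhat(x) == pytest.approx(1.0, abs=0.05)

    def test_rhat_flags_trending_chain(self):
        x = np.linspace(0, 10, 1000) + np.random.default_rng(0).normal(0, 0.1, 1000)
        assert gm.split_chain_rhat(x) > 1.5
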