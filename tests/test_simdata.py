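import numpy as np
import pandas as pd
import pytest

from mulard import pedigree as pg
from mulard import simdata
from mulard import spectra as sp


class TestPedigreeSimulation:
    def test_single_generation_gives_founders_only(self):
        cfg = simdata.SimulationConfig(
            n_crossbreds=20, n_dams=10, n_sires=5,
            common_pedigree_size=10, muscovy_pedigree_size=5,
            pedigree_generations=1, seed=1,
        )
        peds = simdata.simulate_pedigree(cfg)
        assert len(peds.common) == 10 and peds.common.n_founders == 10
        assert len(peds.muscovy) == 5 and peds.muscovy.n_founders == 5

    def test_default_study_sizes(self):
        peds = simdata.simulate_pedigree(simdata.SimulationConfig(seed=2))
        assert len(peds.common) == 596
        assert len(peds.muscovy) == 201
        assert len(peds.dam_ids) == 382
        assert len(peds.sire_ids) == 56

    def test_impossible_sizes_rejected(self):
        cfg = simdata.SimulationConfig(
            n_crossbreds=10, n_dams=100, n_sires=5,
            common_pedigree_size=50, muscovy_pedigree_size=20,
            pedigree_generations=3, seed=0,
        )
        with pytest.raises(ValueError, match="pedigree"):
            simdata.simulate_pedigree(cfg)

    def test_determinism(self):
        cfg = simdata.SimulationConfig(seed=33)
        p1 = simdata.simulate_pedigree(cfg)
        p2 = simdata.simulate_pedigree(cfg)
        assert np.array_equal(p1.common.sire, p2.common.sire)
        assert np.array_equal(p1.muscovy.dam, p2.muscovy.dam)

    def test_generation_depth_bounded(self):
        cfg = simdata.SimulationConfig(seed=4)
        peds = simdata.simulate_pedigree(cfg)

        def depth(ped):
            d = np.zeros(len(ped), int)
            for i in range(len(ped)):
                parents = [p for p in (ped.sire[i], ped.dam[i]) if p != pg.UNKNOWN]
                d[i] = 1 + max((d[p] for p in parents), default=0)
            return d.max()

        assert depth(peds.common) <= cfg.pedigree_generations
        assert depth(peds.muscovy) <= cfg.pedigree_generations


class TestBreedingValues:
    def test_zero_G_gives_zero_bvs(self):
        cfg = simdata.SimulationConfig(seed=5)
        peds = simdata.simulate_pedigree(cfg)
        u = simdata.simulate_breeding_values(
            peds.common, np.zeros((1, 1)), np.random.default_rng(0)
        )
        assert np.allclose(u, 0)

    def test_founder_variance_law_of_large_numbers(self):
        ped = pg.from_frame(
            pd.DataFrame({"animal": np.arange(1, 10_001), "sire": 0, "dam": 0})
        )
        u = simdata.simulate_breeding_values(
            ped, np.array([[1.0]]), np.random.default_rng(3)
        )
        assert u.var(ddof=1) == pytest.approx(1.0, abs=0.1)

    def test_parent_offspring_covariance_half_G(self):
        # trio replicated many times: cov(parent, offspring) ~ G/2
        n_rep = 40_000
        frame = pd.DataFrame(
            {"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]}
        )
        ped = pg.from_frame(frame)
        rng = np.random.default_rng(8)
        g = 2.0
        sire_bv = np.empty(n_rep)
        child_bv = np.empty(n_rep)
        for r in range(n_rep):
            u = simdata.simulate_breeding_values(ped, np.array([[g]]), rng)
            sire_bv[r], child_bv[r] = u[0, 0], u[2, 0]
        emp = np.cov(sire_bv, child_bv)[0, 1]
        assert emp == pytest.approx(0.5 * g, abs=0.05)

    def test_relative_pair_covariance_matches_A(self, small_config):
        # empirical BV covariance across replicates ~ A entries (oracle)
        peds = simdata.simulate_pedigree(small_config)
        A = pg.build_A(peds.common)
        rng = np.random.default_rng(21)
        pick = [0, 5, 50, 80, 110]
        reps = 3000
        us = np.empty((reps, len(pick)))
        for r in range(reps):
            u = simdata.simulate_breeding_values(peds.common, np.array([[1.0]]), rng)
            us[r] = u[pick, 0]
        emp = np.cov(us, rowvar=False)
        assert np.abs(emp - A[np.ix_(pick, pick)]).max() < 0.12

    def test_non_psd_G_rejected(self, small_config):
        peds = simdata.simulate_pedigree(small_config)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simdata.simulate_breeding_values(peds.common, bad, np.random.default_rng(0))


class TestCrossbreds:
    def test_all_zero_components_give_flat_phenotypes(self):
        cfg = simdata.SimulationConfig(
            n_crossbreds=50, n_dams=25, n_sires=5,
            common_pedigree_size=40, muscovy_pedigree_size=15,
            pedigree_generations=2,
            G_dam=np.zeros((1, 1)), G_sire=np.zeros((1, 1)), R=np.zeros((1, 1)),
            fixed_effect_sd=0.0, seed=6,
        )
        study = simdata.simulate_study(cfg)
        assert np.allclose(study.dataset["mMR"], cfg.trait_means[0])

    def test_melting_rate_mean_and_sd_near_targets(self):
        study = simdata.simulate_study(simdata.SimulationConfig(seed=7))
        mr = study.dataset["mMR"]
        assert mr.mean() == pytest.approx(35.6, abs=5.0)
        assert mr.std() == pytest.approx(14.7, rel=0.12)

    def test_variance_accounting(self):
        # large-n decomposition: total variance ~ sum of components
        cfg = simdata.SimulationConfig(
            n_crossbreds=8000, n_dams=2000, n_sires=400,
            common_pedigree_size=2000, muscovy_pedigree_size=400,
            pedigree_generations=1, seed=8,
        )
        study = simdata.simulate_study(cfg)
        expected = (
            cfg.G_dam[0, 0] + cfg.G_sire[0, 0] + cfg.R[0, 0] + cfg.fixed_effect_sd**2
        )
        assert study.dataset["mMR"].var(ddof=1) == pytest.approx(expected, rel=0.1)

    def test_dam_sharing_covariance_matches_dam_component(self):
        # phenotypic covariance of maternal sibs ~ dam variance (+ shared
        # paternal component when the design nests dams within sires)
        cfg = simdata.SimulationConfig(
            n_crossbreds=4000, n_dams=2000, n_sires=2000,
            common_pedigree_size=2000, muscovy_pedigree_size=2000,
            pedigree_generations=1, fixed_effect_sd=0.0, seed=9,
        )
        study = simdata.simulate_study(cfg)
        df = study.dataset
        # each dam has exactly 2 offspring; sires unique per dam here
        first = df.iloc[:2000].set_index("dam")["mMR"]
        second = df.iloc[2000:].set_index("dam")["mMR"]
        pairs = pd.concat([first, second], axis=1, join="inner")
        cov = np.cov(pairs.iloc[:, 0], pairs.iloc[:, 1])[0, 1]
        # same dam AND same sire -> dam + sire components
        expected = cfg.G_dam[0, 0] + cfg.G_sire[0, 0]
        assert cov == pytest.approx(expected, rel=0.25)

    def test_truth_reconstructs_phenotype_exactly(self, small_study):
        cfg = small_study.config
        t = small_study.truth
        rebuilt = (
            cfg.trait_means[0]
            + t["fixed_mMR"] + t["dam_effect_mMR"]
            + t["sire_effect_mMR"] + t["residual_mMR"]
        )
        assert np.allclose(rebuilt, small_study.dataset["mMR"])

    def test_study_determinism(self, small_config):
        s1 = simdata.simulate_study(small_config)
        s2 = simdata.simulate_study(small_config)
        pd.testing.assert_frame_equal(s1.dataset, s2.dataset)


class TestSpectraSimulation:
    def test_no_artifacts_identical_composition_identical_spectra(self):
        cfg = simdata.SimulationConfig(
            noise_sd=0.0, scatter_mult_sd=0.0, scatter_offset_sd=0.0,
            baseline_sd=0.0, seed=10,
        )
        comp = pd.DataFrame(
            {"DM": [60.0, 60.0], "AC": [0.5, 0.5], "Lip": [55.0, 55.0],
             "Prot": [9.0, 9.0], "MR": [35.0, 35.0]}
        )
        out = simdata.simulate_spectra(comp, cfg, np.random.default_rng(0))
        assert np.allclose(out.values[0], out.values[-1])

    def test_linearity_in_one_constituent(self):
        cfg = simdata.SimulationConfig(
            noise_sd=0.0, scatter_mult_sd=0.0, scatter_offset_sd=0.0,
            baseline_sd=0.0, seed=11,
        )
        base = {"DM": 100.0, "AC": 0.0, "Prot": 0.0, "MR": 0.0}
        comp = pd.DataFrame([{**base, "Lip": 10.0}, {**base, "Lip": 20.0}])
        out = simdata.simulate_spectra(comp, cfg, np.random.default_rng(0))
        one = out.values[out.sample_ids == out.sample_ids[0]][0]
        two = out.values[out.sample_ids != out.sample_ids[0]][0]
        assert np.allclose(two, 2 * one, atol=1e-12)

    def test_negative_composition_rejected(self):
        cfg = simdata.SimulationConfig(seed=12)
        comp = pd.DataFrame(
            {"DM": [60.0], "AC": [-0.1], "Lip": [55.0], "Prot": [9.0], "MR": [35.0]}
        )
        with pytest.raises(ValueError, match="negative"):
            simdata.simulate_spectra(comp, cfg, np.random.default_rng(0))

    def test_replicate_counts_by_mode(self, small_study):
        ground = small_study.spectra_ground
        surface = small_study.spectra_surface
        assert (ground.sample_ids == ground.sample_ids[0]).sum() == 3
        assert (surface.sample_ids == surface.sample_ids[0]).sum() == 6

    def test_noise_free_calibration_recovers_composition(self):
        """With every spectral artifact switched off the forward model is
        exactly linear in composition, so PLS recovers lipid content."""
        from mulard import chemometrics as chem

        cfg = simdata.SimulationConfig(
            n_crossbreds=150, n_dams=50, n_sires=10,
            common_pedigree_size=80, muscovy_pedigree_size=30,
            pedigree_generations=2, noise_sd=0.0, scatter_mult_sd=0.0,
            scatter_offset_sd=0.0, baseline_sd=0.0, seed=13,
        )
        study = simdata.simulate_study(cfg, spectra=True)
        proc = sp.apply_recipe(
            sp.average_replicates(study.spectra_ground),
            sp.PreprocessRecipe(normalization="none"),
        )
        y = study.composition.set_index("animal").loc[proc.sample_ids, "Lip"].to_numpy()
        model = chem.pls_fit(proc.values, y, 4)
        assert model.stats.r2 > 0.99


class TestWeightFilter:
    def test_truncation_filter(self, small_study, rng):
        w = simdata.simulate_liver_weights(small_study.composition, rng)
        filtered, keep = simdata.filter_by_weight(small_study.dataset, w)
        assert len(filtered) == keep.sum()
        assert keep.sum() < len(w)  # some livers fall outside 300-830 g


def test_written_files_roundtrip(tmp_path, small_study):
    small_study.write(tmp_path)
    phen = pd.read_csv(tmp_path / "phenotypes.csv")
    ped = pg.read_pedigree(tmp_path / "pedigree_common.csv")
    assert len(phen) == small_study.config.n_crossbreds
    assert len(ped) == small_study.config.common_pedigree_size
    assert set(phen["dam"]).issubset(set(ped.ids.tolist()))
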