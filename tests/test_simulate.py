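"""Synthetic-population generator: determinism, design, and moment checks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tolgen import simulate as S
from tolgen.models import prepare_tolerance_table


class TestPedigreeGeneration:
    def test_same_seed_identical_output(self):
        cfg = S.SimConfig.reduced(10, 4, 6)
        out1 = S.simulate_population(cfg, seed=5)
        out2 = S.simulate_population(cfg, seed=5)
        assert np.array_equal(out1[0].ids, out2[0].ids)
        pd.testing.assert_frame_equal(out1[1], out2[1])

    def test_different_seed_differs(self):
        cfg = S.SimConfig.reduced(10, 4, 6)
        t1 = S.simulate_population(cfg, seed=5)[1]
        t2 = S.simulate_population(cfg, seed=6)[1]
        assert not t1.equals(t2)

    def test_default_design_counts(self):
        ped, mating = S.simulate_pedigree(S.SimConfig(), seed=1)
        sires = mating.sire_id.unique()
        assert len(sires) == 83
        assert len(mating) == 7722
        # every offspring has both parents known
        off = set(mating.animal_id)
        for a in off:
            i = ped.index_of(a)
            assert ped.sire[i] >= 0 and ped.dam[i] >= 0

    def test_mean_dams_per_sire_near_config(self):
        counts = []
        for seed in range(12):
            _, mating = S.simulate_pedigree(
                S.SimConfig(n_offspring=2000, n_sires=40), seed=seed
            )
            counts.append(mating.groupby("sire_id")["dam_id"].nunique().mean())
        assert np.mean(counts) == pytest.approx(15.7, rel=0.08)

    def test_zero_sires_rejected(self):
        with pytest.raises(ValueError):
            S.simulate_pedigree(S.SimConfig(n_sires=0), seed=1)


class TestGeneticValues:
    def test_zero_variance_gives_zero_values(self):
        cfg = S.SimConfig.reduced(5, 2, 3)
        cfg = S.SimConfig.reduced(
            5, 2, 3, genetic_vars=(0.0, 0.0, 0.0, 0.0), maternal_vars=(0, 0, 0, 0)
        )
        ped, mating = S.simulate_pedigree(cfg, seed=1)
        bv, mat = S.simulate_genetic_values(ped, cfg, seed=2)
        assert np.allclose(bv.to_numpy(), 0.0)
        assert np.allclose(mat.to_numpy(), 0.0)

    def test_founder_covariance_matches_target(self):
        cfg = S.SimConfig()
        trips = [(f"f{i}", None, None) for i in range(20000)]
        from tolgen.pedigree import make_pedigree

        ped = make_pedigree(trips)
        bv, _ = S.simulate_genetic_values(ped, cfg, seed=3)
        emp = np.cov(bv.to_numpy().T)
        target = cfg.genetic_cov()
        sd = np.sqrt(np.diag(target))
        assert np.abs((np.diag(emp) - np.diag(target)) / np.diag(target)).max() < 0.05
        # correlations within 0.05 absolute
        empc = emp / np.outer(np.sqrt(np.diag(emp)), np.sqrt(np.diag(emp)))
        tgtc = target / np.outer(sd, sd)
        assert np.abs(empc - tgtc).max() < 0.05

    def test_parent_offspring_slope_covariance(self):
        # cov(parent BV, offspring BV) = sigma^2/2 for non-inbred parents
        cfg = S.SimConfig.reduced(60, 10, 4)
        ped, mating = S.simulate_pedigree(cfg, seed=4)
        acc = []
        for seed in range(8):
            bv, _ = S.simulate_genetic_values(ped, cfg, seed=seed)
            sl = bv["slope"]
            sires = mating.sire_id.to_numpy()
            acc.append(np.cov(sl.loc[sires], sl.loc[mating.animal_id])[0, 1])
        assert np.mean(acc) == pytest.approx(57.8 / 2, rel=0.15)

    def test_nearest_psd_repair(self):
        c = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.9], [-0.99, 0.9, 1.0]])
        fixed = S.nearest_psd(c)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)


class TestPhenotypes:
    def test_affected_fraction_matches_normal_tail(self):
        cfg = S.SimConfig.reduced(40, 8, 10)
        fracs = []
        for seed in range(6):
            _, tab, _ = S.simulate_population(cfg, seed=seed)
            fracs.append((tab.ratio.dropna() > cfg.threshold).mean())
        sd = np.sqrt(15.1 + 1.17 + cfg.residual_ratio)
        expected = 1 - stats.norm.cdf((cfg.threshold - cfg.mean_ratio) / sd)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.03)

    def test_mortality_removes_bw7_and_ratio(self):
        cfg = S.SimConfig.reduced(40, 8, 10)
        _, tab, _ = S.simulate_population(cfg, seed=2)
        missing = tab.bw7.isna().mean()
        assert missing == pytest.approx(cfg.mortality, abs=0.02)
        assert (tab.loc[tab.bw7.isna(), "ratio"].isna()).all()

    def test_slope_free_generator_decouples_bw7_from_severity(self):
        cfg = S.SimConfig.reduced(
            20, 5, 6,
            genetic_vars=(309.0, 15.1, 10640.0, 0.0),
            maternal_vars=(59.3, 1.17, 2771.0, 0.0),
            population_slope=0.0,
            batch_stable_slope_sd=0.0,
            cutter_slope_sd=0.0,
        )
        _, tab, _ = S.simulate_population(cfg, seed=3)
        t2 = prepare_tolerance_table(tab).dropna(subset=["bw7", "ratio"])
        r = np.corrcoef(t2.bw7, t2.ratioplat)[0, 1]
        assert abs(r) < 0.1

    def test_class_cv_sequence_increases(self):
        cfg = S.SimConfig.reduced(40, 10, 10)
        _, tab, _ = S.simulate_population(cfg, seed=5)
        t2 = prepare_tolerance_table(tab).dropna(subset=["bw7", "ratio"])
        cvs = t2.groupby("rclass")["bw7"].apply(
            lambda v: 100 * v.std(ddof=1) / v.mean()
        )
        # calibrated to an increasing CV profile along the severity classes
        assert cvs.iloc[-1] > cvs.iloc[1] > 0
        assert cvs.is_monotonic_increasing or (np.diff(cvs) > -1.0).all()

    def test_residual_class_calibration_reproduces_target_cvs(self):
        cfg = S.SimConfig()
        ve = cfg.bw7_class_variances()
        mids = S.class_midpoints(cfg)
        G = cfg.genetic_cov()[2:, 2:]
        M = cfg.maternal_cov()[2:, 2:]
        for c, t in enumerate(mids):
            x = np.array([1.0, t])
            vp = ve[c] + x @ G @ x + x @ M @ x
            mean = cfg.mean_intercept + cfg.population_slope * t
            assert 100 * np.sqrt(vp) / mean == pytest.approx(
                S.TARGET_CLASS_CV[c], rel=0.02
            )
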