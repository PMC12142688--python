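"""VOI construction, index extraction, coactivation, statistics ladder."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import musclestrain4d as m
from musclestrain4d import voi_stats as vs


class TestBuildVoi:
    def test_nominal_box_in_voxels(self):
        voi = vs.build_voi("VM", (30.0, 30.0, 30.0))
        assert voi.extent_voxels == (5, 15)  # 9.38 and 28.13 mm at 1.875 mm

    def test_slice_replication(self):
        voi = vs.build_voi("VL", (30.0, 30.0, 30.0), n_slices=5)
        sl = voi.slices()[2]
        assert list(range(sl.start, sl.stop)) == [4, 5, 6, 7, 8]

    def test_minimum_extent_one_voxel(self):
        voi = vs.build_voi("RF", (30.0, 30.0, 30.0), box_mm=(1.0, 1.0))
        assert voi.extent_voxels == (1, 1)

    def test_even_slice_count_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            vs.build_voi("VI", (30.0, 30.0, 30.0), n_slices=4)

    def test_out_of_bounds_box_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            vs.build_voi("VM", (2.0, 30.0, 30.0), grid_shape=(32, 64, 12))


class TestPeakForceFrame:
    def test_phantom_default_peak_frame(self):
        assert vs.peak_force_frame(m.make_force_trace()) == 20

    def test_strictly_increasing_gives_last(self):
        force = m.ForceTrace(values=np.linspace(0, 0.3, 10), pct_mvc=0.3,
                             peak_frame=9)
        assert vs.peak_force_frame(force) == 9

    def test_plateau_tie_gives_earliest(self):
        values = np.zeros(32)
        values[18:23] = 0.3
        force = m.ForceTrace(values=values, pct_mvc=0.3, peak_frame=18)
        assert vs.peak_force_frame(force) == 18


class TestExtractVoiIndices:
    def test_constant_region_recovered_exactly(self, noiseless_run):
        """The phantom's VOIs sit in regions of constant prescribed tensor."""
        table = noiseless_run["table"]
        ag = table[table.muscle == "agonist"].iloc[0]
        assert ag.lambda1 == pytest.approx(0.20, abs=1e-3)
        assert ag.lambda2 == pytest.approx(0.01, abs=1e-3)
        assert ag.lambda3 == pytest.approx(0.19, abs=1e-3)

    def test_invalid_voi_flagged_no_row(self, noiseless_run):
        run = noiseless_run
        # border VOI: valid_mask is False on the volume border
        voi = vs.Voi("bad", "quadriceps", (2, 2), 0, (4, 4), 1)
        with pytest.warns(UserWarning, match="flagged"):
            row = vs.extract_voi_indices(run["fields"], voi,
                                         run["force"].peak_frame)
        assert row is None


class TestCoactivationRatio:
    @staticmethod
    def toy_table(ham, quad):
        return pd.DataFrame(
            [
                {"subject": "s0", "muscle": "LBF", "group": "hamstrings",
                 "pct_mvc": 0.3, "lambda1": ham},
                {"subject": "s0", "muscle": "VM", "group": "quadriceps",
                 "pct_mvc": 0.3, "lambda1": quad},
            ]
        )

    def test_simple_division(self):
        assert vs.coactivation_ratio(self.toy_table(0.10, 0.20)).ratio[0] == \
            pytest.approx(0.5)

    def test_identical_groups_unity(self):
        assert vs.coactivation_ratio(self.toy_table(0.15, 0.15)).ratio[0] == \
            pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        with pytest.warns(UserWarning, match="zero agonist"):
            out = vs.coactivation_ratio(self.toy_table(0.1, 0.0))
        assert np.isnan(out.ratio[0])


class TestFriedman:
    def test_statistic_matches_scipy(self, rng):
        """scipy.stats.friedmanchisquare is the independent oracle."""
        for _ in range(20):
            data = rng.normal(0, 1, (8, 4))
            ours = vs.friedman_statistic(data)
            ref = stats.friedmanchisquare(*data.T).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_values_statistic_zero(self):
        data = np.full((6, 3), 0.2)
        assert vs.friedman_statistic(data) == 0.0
        stat, p = vs.friedman_test(data)
        assert stat == 0.0 and p == 1.0

    def test_exact_p_matches_independent_enumeration(self, rng):
        """Brute-force enumeration over all (k!)^n within-subject orderings,
        written independently of the implementation."""
        data = rng.normal(0, 1, (4, 3))
        stat, p = vs.friedman_test(data, method="exact")
        count = total = 0
        perms = list(itertools.permutations(range(3)))
        for combo in itertools.product(perms, repeat=4):
            permuted = np.array([data[i, list(pi)] for i, pi in enumerate(combo)])
            total += 1
            if vs.friedman_statistic(permuted) >= stat - 1e-12:
                count += 1
        assert p == pytest.approx(count / total, abs=1e-15)

    def test_mc_close_to_exact(self, rng):
        data = rng.normal(0, 1, (5, 3))
        _, p_exact = vs.friedman_test(data, method="exact")
        _, p_mc = vs.friedman_test(data, method="mc", n_perm=4000, seed=3)
        assert p_mc == pytest.approx(p_exact, abs=0.03)

    def test_asymptotic_matches_scipy_p(self, rng):
        data = rng.normal(0, 1, (12, 4))
        stat, p = vs.friedman_test(data, method="asymptotic")
        ref = stats.friedmanchisquare(*data.T)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)


class TestWilcoxonAndBonferroni:
    def test_antisymmetric_differences_p_one(self):
        """Positive ranks summing to n(n+1)/4 sit at the null center, so the
        two-sided exact p is 1; verified against full sign enumeration."""
        y = np.zeros(4)
        x = np.array([1.0, -2.0, -3.0, 4.0])  # ranks {1, 4} positive -> W+ = 5
        p = vs._wilcoxon_p(x, y)
        # independent oracle: enumerate all 2^n sign assignments
        ranks = np.array([1, 2, 3, 4])
        w_obs = 5.0
        dist = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=4)
        ]
        lo = np.mean([w <= w_obs for w in dist])
        hi = np.mean([w >= w_obs for w in dist])
        expected = min(1.0, 2 * min(lo, hi))
        assert p == pytest.approx(expected)
        assert p == 1.0

    def test_all_zero_differences_p_one(self):
        assert vs._wilcoxon_p(np.ones(6), np.ones(6)) == 1.0

    def test_bonferroni_monotone_and_capped(self, rng):
        p = rng.random(8)
        adj = vs.bonferroni(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert np.allclose(adj, np.minimum(8 * p, 1.0))


class TestRunStatistics:
    def test_unbalanced_table_names_missing_cells(self):
        table = vs.simulate_voi_table(n_subjects=4)
        table = table.drop(table.index[0])
        with pytest.raises(ValueError, match="missing cells"):
            vs.run_statistics(table)

    def test_normal_data_routes_to_rm_anova(self):
        rng = np.random.default_rng(5)
        table = vs.simulate_voi_table(n_subjects=12, sigma=0.02, rng=rng)
        report = vs.run_statistics(table, indices=("lambda1",))
        rep = report.indices["lambda1"]
        if rep.all_normal:
            assert rep.test == "rm_anova"
            assert rep.sphericity  # Mauchly ran
        else:
            assert rep.test == "friedman"
            assert set(rep.muscle_p_by_level) == {0.30, 0.45}

    def test_skewed_data_routes_to_friedman(self):
        rng = np.random.default_rng(6)
        table = vs.simulate_voi_table(n_subjects=12, sigma=1e-12, rng=rng)
        # heavy-tailed noise forces the nonparametric branch
        table["lambda1"] = 0.2 + rng.exponential(0.05, len(table)) ** 3
        report = vs.run_statistics(table, indices=("lambda1",))
        rep = report.indices["lambda1"]
        assert rep.test == "friedman"
        desc = next(iter(rep.descriptives.values()))
        assert desc["kind"] == "median+-iqr"

    def test_descriptives_match_normality_gate(self):
        rng = np.random.default_rng(7)
        table = vs.simulate_voi_table(n_subjects=12, sigma=0.02, rng=rng)
        report = vs.run_statistics(table, indices=("lambda1", "l_max"))
        for rep in report.indices.values():
            kinds = {d["kind"] for d in rep.descriptives.values()}
            expected = "mean+-sd" if rep.all_normal else "median+-iqr"
            assert kinds == {expected}

    def test_strong_mvc_effect_detected(self):
        rng = np.random.default_rng(8)
        table = vs.simulate_voi_table(
            n_subjects=12, mvc_effect=0.05, sigma=0.01, rng=rng
        )
        report = vs.run_statistics(table, indices=("lambda1",))
        assert report.indices["lambda1"].mvc_p < 0.05

    def test_report_serializes_to_json(self):
        import json

        rng = np.random.default_rng(9)
        table = vs.simulate_voi_table(n_subjects=8, sigma=0.02, rng=rng)
        report = vs.run_statistics(table, indices=("lambda1",))
        blob = json.dumps(report.to_dict())
        assert "lambda1" in blob
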