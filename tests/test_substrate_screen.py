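import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_diff_table
from deconcord import (
    Candidates,
    ConfigurationError,
    DegenerateInputError,
    GeneSetCollection,
    ScreenConfig,
    Stage4Criteria,
    ValidationError,
    fit_fc_regression,
    pair_by_identity,
    run_screen,
    simulate_gene_sets,
    simulate_paired_transcriptomes,
    simulate_proteome,
    stage1_select,
    stage2_intersect,
    stage3_go_filter,
    stage4_final_filter,
    standardized_residuals,
)
from deconcord.synthetic_data import SimConfig


def _pairs(x, y, p_adj_x=None, p_adj_y=None):
    ids = [f"g{i:03d}" for i in range(len(x))]
    tx = make_diff_table(ids, x, p_adj=p_adj_x, label="mrna_t", layer="mrna")
    ty = make_diff_table(ids, y, p_adj=p_adj_y, label="prot_t", layer="protein")
    return pair_by_identity(tx, ty)


class TestFitRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        fit = fit_fc_regression(_pairs(x, 2 * x + 1))
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-12)

    def test_four_point_normal_equations(self):
        # hand-solved: Sxx = 5, Sxy = 3 -> slope 0.6, intercept 0.1
        fit = fit_fc_regression(_pairs([0, 1, 2, 3], [0, 1, 1, 2]))
        assert fit.slope == pytest.approx(0.6, abs=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.n == 4

    def test_constant_x_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_fc_regression(_pairs([1, 1, 1, 1], [0, 1, 2, 3]))

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            fit_fc_regression(_pairs([1, 2, 3], [1, 2, 3]))


class TestStandardizedResiduals:
    def test_collinear_data_rejected(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        pairs = _pairs(x, 3 * x)
        fit = fit_fc_regression(pairs)
        with pytest.raises(DegenerateInputError):
            standardized_residuals(pairs, fit)

    def test_ols_identities(self, rng):
        x = rng.normal(size=40)
        y = 0.7 * x + rng.normal(size=40)
        pairs = _pairs(x, y)
        fit = fit_fc_regression(pairs)
        res = standardized_residuals(pairs, fit)
        raw = res.to_numpy() * fit.residual_sd
        assert abs(raw.sum()) < 1e-9 * np.abs(raw).sum()
        assert np.sum(res.to_numpy() ** 2) == pytest.approx(len(x) - 2, rel=1e-9)

    def test_six_point_direct_recomputation(self, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        pairs = _pairs(x, y)
        fit = fit_fc_regression(pairs)
        got = standardized_residuals(pairs, fit)
        # independent oracle via numpy polyfit
        slope, intercept = np.polyfit(pairs.x, pairs.y, 1)
        raw = pairs.y - (intercept + slope * pairs.x)
        sd = math.sqrt(np.sum(raw**2) / (6 - 2))
        np.testing.assert_allclose(got.to_numpy(), raw / sd, atol=1e-10)

    def test_keyed_by_feature_id(self):
        pairs = _pairs([0, 1, 2, 3, 4], [0, 1, 1, 2, 5])
        res = standardized_residuals(pairs, fit_fc_regression(pairs))
        assert list(res.index) == list(pairs.rows["id_x"])


class TestStage1:
    def test_down_in_both_kept(self):
        res_a = pd.Series({"a": -1.5, "b": 0.0})
        res_b = pd.Series({"a": -2.0, "b": 0.0})
        cand = stage1_select(res_a, res_b)
        assert cand.down == frozenset({"a"})
        assert cand.up == frozenset()

    def test_mixed_sign_excluded(self):
        res_a = pd.Series({"a": -1.5})
        res_b = pd.Series({"a": 1.5})
        cand = stage1_select(res_a, res_b)
        assert len(cand) == 0

    def test_boundary_not_kept(self):
        res = pd.Series({"a": 1.0})
        assert len(stage1_select(res, res, cut=1.0)) == 0  # strict inequality

    def test_no_shared_keys_error(self):
        with pytest.raises(ValidationError):
            stage1_select(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))

    def test_null_binomial_expectation(self):
        # 200 iid standard-normal residual pairs; expected down count
        # 200 * Phi(-1)^2 ~= 5.0; check within the central 99% binomial range
        p_down = stats.norm.cdf(-1.0) ** 2
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, p_down)
        counts = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            res_a = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
            res_b = pd.Series(rng.normal(size=200), index=[f"g{i}" for i in range(200)])
            counts.append(len(stage1_select(res_a, res_b).down))
        inside = sum(lo <= c <= hi for c in counts)
        assert inside >= 9


class TestStage2:
    def test_identical_sets(self):
        c = Candidates(up=frozenset("ab"), down=frozenset("cd"))
        assert stage2_intersect(c, c) == c

    def test_disjoint_empty(self):
        c1 = Candidates(up=frozenset("a"), down=frozenset())
        c2 = Candidates(up=frozenset("b"), down=frozenset())
        assert len(stage2_intersect(c1, c2)) == 0

    def test_random_sets_match_brute_force(self, rng):
        ids = [f"g{i}" for i in range(50)]
        u1 = frozenset(rng.choice(ids, 20, replace=False))
        u2 = frozenset(rng.choice(ids, 20, replace=False))
        d1 = frozenset(rng.choice(ids, 15, replace=False))
        d2 = frozenset(rng.choice(ids, 15, replace=False))
        got = stage2_intersect(Candidates(up=u1, down=d1), Candidates(up=u2, down=d2))
        assert got.up == frozenset(i for i in ids if i in u1 and i in u2)
        assert got.down == frozenset(i for i in ids if i in d1 and i in d2)


class TestStage3:
    def test_no_significant_term_retains_nothing(self):
        coll = GeneSetCollection(sets={"T": ("t", frozenset({"a"}))})
        background = {f"g{i}" for i in range(30)} | {"a", "b"}
        cand = Candidates(up=frozenset({"a"}), down=frozenset({"b"}))
        retained, _ = stage3_go_filter(cand, background, [coll], alpha=1e-6)
        assert len(retained) == 0

    def test_significant_term_retains_exact_members(self):
        down = frozenset({"d1", "d2", "d3", "d4", "d5"})
        term = frozenset({"d1", "d2", "d3"})
        coll = GeneSetCollection(sets={"T": ("t", term)})
        background = {f"g{i}" for i in range(200)} | down
        cand = Candidates(up=frozenset(), down=down)
        retained, enr = stage3_go_filter(cand, background, [coll], mode="fisher", alpha=0.05)
        assert retained.down == frozenset({"d1", "d2", "d3"})
        assert retained.up == frozenset()
        assert any(r.significant for r in enr["down"])

    def test_other_direction_term_does_not_rescue(self):
        # term significant among down candidates only; an up candidate inside
        # the same term must not be retained
        term = frozenset({"d1", "d2", "d3", "u1"})
        coll = GeneSetCollection(sets={"T": ("t", term)})
        background = {f"g{i}" for i in range(200)} | term | {"u2"}
        cand = Candidates(up=frozenset({"u1", "u2"}), down=frozenset({"d1", "d2", "d3"}))
        retained, enr = stage3_go_filter(cand, background, [coll], mode="fisher", alpha=1e-3)
        assert not any(r.significant for r in enr["up"])
        assert "u1" not in retained.up

    def test_candidates_outside_background_rejected(self):
        coll = GeneSetCollection(sets={"T": ("t", frozenset({"a"}))})
        with pytest.raises(ValidationError):
            stage3_go_filter(
                Candidates(up=frozenset({"zz"}), down=frozenset()), {"a"}, [coll]
            )


class TestStage4:
    def _rows(self, lfc, padj, prot_padj=None):
        frame = pd.DataFrame({"mrna_lfc": lfc, "mrna_padj": padj})
        if prot_padj is not None:
            frame["prot_padj"] = prot_padj
        return frame

    def test_default_drops_nonsignificant_mrna(self):
        rows = self._rows([2.0], [0.2])
        assert not stage4_final_filter(rows, Stage4Criteria()).iloc[0]

    def test_default_keeps_qualifying_row(self):
        rows = self._rows([2.0], [0.01])
        assert stage4_final_filter(rows, Stage4Criteria()).iloc[0]

    def test_ten_rows_hand_enumeration(self):
        lfc = [2.0, -2.0, 0.5, 1.0, 1.5, -1.5, 3.0, -0.2, 2.5, -4.0]
        padj = [0.01, 0.04, 0.01, 0.01, 0.2, 0.001, 0.05, 0.01, 0.049, 0.3]
        # hand evaluation with strict cuts |lfc| > 1 and padj < 0.05:
        expected = [True, True, False, False, False, True, False, False, True, False]
        got = stage4_final_filter(self._rows(lfc, padj), Stage4Criteria())
        assert list(got) == expected

    def test_protein_filter_enabled(self):
        rows = self._rows([2.0, 2.0], [0.01, 0.01], prot_padj=[0.001, 0.5])
        got = stage4_final_filter(rows, Stage4Criteria(prot_padj_max=0.05))
        assert list(got) == [True, False]

    def test_missing_statistic_is_configuration_error(self):
        rows = pd.DataFrame({"mrna_lfc": [1.0]})
        with pytest.raises(ConfigurationError):
            stage4_final_filter(rows, Stage4Criteria())
        rows2 = self._rows([2.0], [0.01])
        with pytest.raises(ConfigurationError):
            stage4_final_filter(rows2, Stage4Criteria(prot_padj_max=0.05))


def _simulate_screen(seed, delta, n_genes=2000):
    cfg = SimConfig(n_genes=n_genes, delta_shift=delta, seed=seed)
    tables, omap, truth = simulate_paired_transcriptomes(cfg, 2)
    pairs = {
        t.dataset_label: (t, simulate_proteome(t, cfg, truth)) for t in tables
    }
    sets = simulate_gene_sets(cfg, truth)
    return run_screen(pairs, omap, sets), truth


class TestRunScreen:
    def test_planted_substrates_recovered(self):
        result, truth = _simulate_screen(seed=7, delta=3.0)
        final = set(result.final_candidates["id_x"])
        substrates = set(truth.substrate_genes)
        recall = len(final & substrates) / len(substrates)
        precision = len(final & substrates) / max(len(final), 1)
        assert recall >= 0.8
        assert precision >= 0.5

    def test_funnel_monotone(self):
        result, _ = _simulate_screen(seed=8, delta=3.0)
        s1, s2, s3, s4 = result.stage_sizes()
        assert s1 >= s2 >= s3 >= s4
        rows = result.rows
        assert not (rows["pass_stage2"] & ~rows["pass_stage1"]).any()
        assert not (rows["pass_stage3"] & ~rows["pass_stage2"]).any()
        assert not (rows["pass_stage4"] & ~rows["pass_stage3"]).any()

    def test_null_delta_final_count_small(self):
        result, truth = _simulate_screen(seed=9, delta=0.0)
        # without a planted shift the designated term is not enriched among
        # residual outliers, so stage 3 should cut the funnel to near zero
        assert result.stage_sizes()[3] <= 5

    def test_deterministic_rerun(self):
        r1, _ = _simulate_screen(seed=10, delta=3.0)
        r2, _ = _simulate_screen(seed=10, delta=3.0)
        pd.testing.assert_frame_equal(r1.rows, r2.rows)
        assert r1.config_echo == r2.config_echo

    def test_single_dataset_rejected(self):
        cfg = SimConfig(n_genes=500, seed=1, n_substrates=5)
        tables, omap, truth = simulate_paired_transcriptomes(cfg, 1)
        prot = simulate_proteome(tables[0], cfg, truth)
        sets = simulate_gene_sets(cfg, truth)
        with pytest.raises(ValidationError):
            run_screen({"mouse": (tables[0], prot)}, None, sets)

    def test_config_echoed(self):
        result, _ = _simulate_screen(seed=11, delta=3.0)
        echo = result.config_echo
        assert echo["residual_cut"] == 1.0
        assert echo["stage4_mrna_padj_max"] == 0.05
        assert echo["stage4_mrna_lfc_min_abs"] == 1.0
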