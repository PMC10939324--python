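import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reachmetrics.stats import (
    RmDataset,
    mauchly,
    posthoc_bonferroni,
    rm_anova2,
    rm_dataset_from_summaries,
)

from ._oracles import rm_anova_oracle

A_LEVELS = ["big", "small"]
B_LEVELS = ["baseline", "TV", "TH", "TM"]


def _dataset(y):
    """Wrap Y[s, a, b] into the long-format dataset."""
    rows = []
    for s in range(y.shape[0]):
        for i, a in enumerate(A_LEVELS[: y.shape[1]]):
            for j, b in enumerate(B_LEVELS[: y.shape[2]]):
                rows.append((f"P{s:02d}", a, b, y[s, i, j]))
    return RmDataset(pd.DataFrame(rows, columns=["participant", "ball_mode", "cell", "value"]))


def _random_y(rng, n=10, na=2, nb=4):
    return rng.normal(size=(n, na, nb))


class TestRmDataset:
    def test_missing_cell_rejected(self, rng):
        data = _dataset(_random_y(rng)).data.iloc[:-1]
        with pytest.raises(ValueError, match="complete"):
            RmDataset(data)

    def test_duplicate_cell_rejected(self, rng):
        df = _dataset(_random_y(rng)).data
        with pytest.raises(ValueError, match="balanced"):
            RmDataset(pd.concat([df, df.iloc[:1]], ignore_index=True))

    def test_cell_array_layout(self, rng):
        y = _random_y(rng, n=3)
        assert np.allclose(_dataset(y).cell_array(), y)


class TestMauchly:
    def test_two_level_factor_trivially_spherical(self, rng):
        w, p, eps = mauchly(_dataset(_random_y(rng)), "A")
        assert (w, p, eps) == (1.0, 1.0, 1.0)

    def test_compound_symmetry_rarely_rejected(self):
        # under H0 with an exchangeable covariance, rejection ~ alpha
        rng = np.random.default_rng(7)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            subj = rng.normal(size=(40, 1))
            y = subj[:, :, None] + rng.normal(size=(40, 2, 4))
            _, p, _ = mauchly(_dataset(y), "B")
            rejections += p < 0.05
        assert rejections / n_rep <= 0.10  # i.e. p > .05 in >= 90%

    def test_heterogeneous_covariance_deflates_epsilon(self):
        rng = np.random.default_rng(8)
        scales = np.array([0.05, 0.3, 1.0, 3.0])
        y = rng.normal(size=(60, 2, 4)) * scales
        w, p, eps = mauchly(_dataset(y), "B")
        assert eps < 0.8
        assert p < 0.05

    def test_interaction_contrasts_accepted(self, rng):
        w, p, eps = mauchly(_dataset(_random_y(rng)), "A*B")
        assert 0 < w <= 1 and 0 <= p <= 1 and 1 / 3 - 1e-9 <= eps <= 1


class TestRmAnova:
    def test_matches_loop_oracle_to_1e8(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            y = _random_y(rng)
            table = rm_anova2(_dataset(y), sphericity_policy="never")
            oracle = rm_anova_oracle(y)
            for eff in ("A", "B", "A*B"):
                assert table[eff].f == pytest.approx(oracle[eff]["F"], abs=1e-8)
                assert table[eff].p == pytest.approx(oracle[eff]["p"], abs=1e-8)
                assert table[eff].ss == pytest.approx(oracle["ss"][eff], abs=1e-8)

    def test_ss_conservation(self, rng):
        table = rm_anova2(_dataset(_random_y(rng)))
        parts = ("A", "B", "subject", "A*B", "A*subject", "B*subject", "A*B*subject")
        assert sum(table.ss[k] for k in parts) == pytest.approx(
            table.ss["total"], rel=1e-8
        )

    def test_null_factor_gives_zero_f(self, rng):
        y = np.repeat(rng.normal(size=(10, 2, 1)), 4, axis=2)  # constant across B
        table = rm_anova2(_dataset(y))
        assert table["B"].f == pytest.approx(0.0, abs=1e-12)
        assert table["B"].p == pytest.approx(1.0)

    def test_additive_design_zero_interaction(self):
        # P1:(1,2,3,4), P2:(2,3,4,5), P3:(3,4,5,6) over (A1B1,A1B2,A2B1,A2B2)
        y = np.array([[[1, 2], [3, 4]], [[2, 3], [4, 5]], [[3, 4], [5, 6]]], float)
        table = rm_anova2(_dataset(y))
        assert table.ss["A*B"] == pytest.approx(0.0, abs=1e-12)
        assert table["A*B"].f == pytest.approx(0.0, abs=1e-12)

    def test_two_level_f_equals_squared_paired_t(self, rng):
        y = _random_y(rng)
        table = rm_anova2(_dataset(y))
        diff = y.mean(axis=2)[:, 0] - y.mean(axis=2)[:, 1]
        t = sps.ttest_rel(y.mean(axis=2)[:, 0], y.mean(axis=2)[:, 1]).statistic
        assert table["A"].f == pytest.approx(t**2, abs=1e-8)

    def test_participant_permutation_invariance(self, rng):
        y = _random_y(rng)
        t1 = rm_anova2(_dataset(y))
        t2 = rm_anova2(_dataset(y[::-1]))
        for eff in ("A", "B", "A*B"):
            assert t1[eff].f == pytest.approx(t2[eff].f, rel=1e-12)
            assert t1[eff].p == pytest.approx(t2[eff].p, rel=1e-12)

    def test_gg_correction_applied_when_sphericity_fails(self):
        rng = np.random.default_rng(9)
        scales = np.array([0.02, 0.2, 1.0, 5.0])
        y = rng.normal(size=(30, 2, 4)) * scales
        auto = rm_anova2(_dataset(y), sphericity_policy="auto")
        never = rm_anova2(_dataset(y), sphericity_policy="never")
        assert auto["B"].mauchly_p < 0.05
        assert auto["B"].epsilon < 1.0
        assert never["B"].epsilon == 1.0
        assert auto["B"].f == never["B"].f  # correction changes dfs/p only
        assert auto["B"].p >= never["B"].p  # GG is conservative

    def test_cross_check_against_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = _random_y(rng)
        data = _dataset(y)
        mine = rm_anova2(data, sphericity_policy="never")
        theirs = pg.rm_anova(
            data=data.data, dv="value", within=["ball_mode", "cell"],
            subject="participant", detailed=True,
        ).set_index("Source")
        assert mine["A"].f == pytest.approx(theirs.loc["ball_mode", "F"], rel=1e-9)
        assert mine["B"].f == pytest.approx(theirs.loc["cell", "F"], rel=1e-9)
        assert mine["A*B"].f == pytest.approx(
            theirs.loc["ball_mode * cell", "F"], rel=1e-9
        )
        assert mine["B"].p == pytest.approx(theirs.loc["cell", "p_unc"], rel=1e-9)
        # Mauchly W and GG epsilon against pingouin on the collapsed layout
        collapsed = (
            data.data.groupby(["participant", "cell"], sort=False)["value"]
            .mean()
            .reset_index()
        )
        w_mine, _, eps_mine = mauchly(data, "B")
        spher = pg.sphericity(collapsed, dv="value", within="cell", subject="participant")
        assert w_mine == pytest.approx(spher.W, rel=1e-9)
        assert eps_mine == pytest.approx(
            pg.epsilon(collapsed, dv="value", within="cell", subject="participant"),
            rel=1e-9,
        )


class TestPosthoc:
    def test_identical_values_null_result(self):
        y = np.ones((6, 2, 4)) * np.arange(6)[:, None, None]
        res = posthoc_bonferroni(_dataset(y))
        for r in res:
            assert np.isnan(r.t) or r.t == 0.0
            assert r.p_adjusted == 1.0 or np.isnan(r.p_raw)

    def test_bonferroni_definition(self, rng):
        res = posthoc_bonferroni(_dataset(_random_y(rng)))
        for r in res:
            assert r.m == 3
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_default_family_baseline_vs_each_retention_per_mode(self, rng):
        res = posthoc_bonferroni(_dataset(_random_y(rng)))
        assert len(res) == 6  # 3 comparisons x 2 ball modes
        assert {r.comparison for r in res} == {
            ("baseline", "TV"), ("baseline", "TH"), ("baseline", "TM")
        }
        assert {r.split for r in res} == {"big", "small"}

    def test_closed_form_paired_t(self, rng):
        y = _random_y(rng)
        res = posthoc_bonferroni(_dataset(y), comparisons=[("baseline", "TH")])
        r = next(x for x in res if x.split == "big")
        d = y[:, 0, 0] - y[:, 0, 2]
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert r.t == pytest.approx(t_expected, abs=1e-10)

    def test_too_few_participants_rejected(self):
        y = np.zeros((1, 2, 4))
        with pytest.raises(ValueError, match="participants"):
            posthoc_bonferroni(_dataset(y))


def test_rm_dataset_from_summaries_orders_cells():
    rows = []
    for p in range(3):
        for mode in A_LEVELS:
            for cell in ["TM", "baseline", "TH", "TV"]:  # scrambled input
                rows.append((f"P{p}", mode, cell, 4, 1.0, 0.1, 0.2, 0.5, 3.0))
    df = pd.DataFrame(rows, columns=[
        "participant", "ball_mode", "cell", "n_segments", "movement_time",
        "v_avg", "v_peak", "time_to_peak", "n_peak",
    ])
    data = rm_dataset_from_summaries(df, "movement_time")
    assert data.b_levels == ["baseline", "TV", "TH", "TM"]
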