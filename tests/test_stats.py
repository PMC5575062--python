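import numpy as np
import pytest

import gcflow as g
from gcflow.stats import two_way_anova_tukey


class TestZScore:
    def test_simple_example(self):
        z = g.zscore_pair([1, 2, 3], [4, 5, 6])
        assert np.allclose(z.x_z, [-1, 0, 1])
        assert np.allclose(z.y_z, [-1, 0, 1])

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        z = g.zscore_pair(rng.uniform(0, 50, 40), rng.normal(3, 7, 40))
        for v in (z.x_z, z.y_z):
            assert abs(v.mean()) < 1e-9
            assert abs(v.std(ddof=1) - 1) < 1e-9

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        z1 = g.zscore_pair(x, y)
        z2 = g.zscore_pair(2.5 * x + 7, 0.3 * y - 2)
        assert np.allclose(z1.x_z, z2.x_z)
        assert np.allclose(z1.y_z, z2.y_z)

    def test_zero_variance_names_variable(self):
        with pytest.raises(ValueError, match="'y'"):
            g.zscore_pair([1, 2, 3], [5, 5, 5])


class TestPearsonFit:
    def test_exact_line(self):
        x = np.arange(10.0)
        fit = g.pearson_fit(x, 2 * x + 1)
        assert fit.r == pytest.approx(1.0)
        assert fit.p_value < 1e-12
        assert fit.slope == pytest.approx(2.0)

    def test_slope_equals_r_on_zscored_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3, 50)
        y = 0.7 * x + rng.normal(0, 2, 50)
        fit = g.pearson_fit(g.zscore_pair(x, y))
        assert fit.slope == pytest.approx(fit.r, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0, 1, 40)
        assert g.pearson_fit(x, -y).r == pytest.approx(-g.pearson_fit(x, y).r)

    def test_recovers_population_r(self):
        df = g.simulate_paired_table(10000, 0.67, rng_seed=4)
        fit = g.pearson_fit(df.x.to_numpy(), df.y.to_numpy())
        # Fisher-z 99% interval around 0.67 at n=10000 is ~±0.014
        assert abs(fit.r - 0.67) < 0.02


class TestLinearityGate:
    def test_linear_data_takes_linear_branch(self):
        rng = np.random.default_rng(15)
        x = np.linspace(-3, 3, 60)
        y = 1.5 * x + rng.normal(0, 0.05, 60)
        out = g.fit_with_linearity_gate(x, y)
        assert isinstance(out, g.CorrelationResult)

    def test_curved_data_takes_quadratic_branch(self):
        rng = np.random.default_rng(6)
        x = np.linspace(-2, 2, 60)
        y = x ** 2 + rng.normal(0, 0.05, 60)
        out = g.fit_with_linearity_gate(x, y)
        assert isinstance(out, g.PolyFitResult)
        assert out.lack_of_linearity_p < 0.05
        assert 0 <= out.r_squared <= 1
        # quadratic beats linear on its own data
        lin = g.pearson_fit(x, y)
        assert out.r_squared >= lin.r ** 2
        # no remaining deviation from the quadratic model
        assert out.deviation_from_model_p > 0.05

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            g.fit_with_linearity_gate([1, 2, 3], [1, 2, 3])


class TestCompareGroups:
    def test_identical_groups_t_is_zero(self):
        res = g.compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.test == "t_test"

    def test_sem_definition(self):
        res = g.compare_groups({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0, 6.0]})
        a = res.groups["a"]
        assert a["sem"] == pytest.approx(np.std([1, 2, 3, 4], ddof=1) / 2)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(7)
        samples = {k: rng.normal(i * 0.5, 1, 12)
                   for i, k in enumerate(["ctl", "g1", "g2", "g3"])}
        for design, kw in [("one_way_anova_dunnett", {"control": "ctl"}),
                           ("one_way_anova_tukey", {})]:
            res = g.compare_groups(samples, design=design, **kw)
            for c in res.comparisons:
                assert c["p_adj"] >= c["p_raw"] - 1e-12

    def test_posthoc_reduces_to_t_test_for_two_groups(self):
        rng = np.random.default_rng(8)
        samples = {"a": rng.normal(0, 1, 10), "b": rng.normal(1, 1, 10)}
        t_res = g.compare_groups(samples, design="t_test")
        for design in ("one_way_anova_dunnett", "one_way_anova_tukey"):
            res = g.compare_groups(samples, design=design, control="a")
            assert res.comparisons[0]["p_adj"] == pytest.approx(t_res.p_value,
                                                                rel=1e-6)

    def test_dunnett_requires_control(self):
        rng = np.random.default_rng(9)
        samples = {k: rng.normal(0, 1, 5) for k in "abc"}
        with pytest.raises(ValueError, match="control"):
            g.compare_groups(samples, design="one_way_anova_dunnett")

    def test_treadmilling_drug_effect_detected(self):
        # control vs microtubule-depolymerized speeds: a 3 um/min drop with
        # SEM ~0.2 at n=10 is overwhelming; detection should be near-certain
        rng = np.random.default_rng(10)
        detected = 0
        n_rep = 100
        for _ in range(n_rep):
            ctl = rng.normal(4.7258, 0.1918 * np.sqrt(10), 10)
            noc = rng.normal(1.6522, 0.1183 * np.sqrt(10), 10)
            res = g.compare_groups({"control": ctl, "nocodazole": noc})
            detected += res.p_value < 0.05
        assert detected / n_rep > 0.95

    def test_two_way_layout_runs(self):
        import pandas as pd
        rng = np.random.default_rng(11)
        rows = []
        for fa in ("wt", "mut"):
            for fb in ("veh", "drug"):
                for v in rng.normal(1.0 + (fa == "mut"), 0.3, 6):
                    rows.append({"value": v, "geno": fa, "treat": fb})
        res = two_way_anova_tukey(pd.DataFrame(rows), "value", "geno", "treat")
        assert res.test == "two_way_anova_tukey"
        assert res.p_value < 0.05
        assert len(res.comparisons) == 6
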