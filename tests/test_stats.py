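import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from atpuncta.stats import (
    fit_group_model,
    normality_check,
    transform,
)


def _nested_data(rng, effect=0.0, n_cases=6, n_stacks=3, sb=1.0, se=1.0):
    rows = []
    for g, mu in (("ctrl", 0.0), ("ad", effect)):
        for c in range(n_cases):
            ce = rng.normal(0, sb)
            for _ in range(n_stacks):
                rows.append(dict(case=f"{g}{c}", group=g,
                                 response=mu + ce + rng.normal(0, se)))
    return pd.DataFrame(rows)


class TestTransform:
    def test_lambda_one_is_affine(self, rng):
        x = rng.uniform(1.0, 5.0, 50)
        from scipy.special import boxcox
        t = boxcox(x, 1.0)
        assert t == pytest.approx(x - 1.0)

    def test_lognormal_selects_lambda_near_zero(self, rng):
        x = rng.lognormal(1.0, 0.6, 200)
        res = transform(x, method="box-cox", lambda_selection="log-likelihood")
        assert abs(res.lam) < 0.2

    def test_tukey_normalizes_lognormal(self, rng):
        x = rng.lognormal(1.0, 0.6, 150)
        res = transform(x, method="tukey")
        assert abs(res.lam) < 0.3
        w_raw = sps.shapiro(x).statistic
        w_t = sps.shapiro(res.values).statistic
        assert w_t > w_raw

    def test_guerrero_runs_and_reports_lambda(self, rng):
        x = rng.lognormal(0.0, 0.4, 100)
        res = transform(x, method="box-cox", lambda_selection="guerrero")
        assert res.lambda_selection == "guerrero"
        assert np.isfinite(res.lam)

    def test_nonpositive_without_shift_rejected(self, rng):
        x = np.r_[rng.uniform(1, 2, 20), -0.5]
        with pytest.raises(ValueError, match="positive"):
            transform(x, method="box-cox")
        res = transform(x, method="box-cox", shift=1.0)
        assert res.shift == 1.0

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError, match="all-equal"):
            transform(np.ones(10), method="tukey")


class TestNormalityCheck:
    def test_type_one_error_is_calibrated(self, rng):
        rejections = sum(
            normality_check(rng.normal(0, 1, 50))[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 < rejections / 400 < 0.09

    def test_heavy_tails_are_rejected_often(self, rng):
        rejections = sum(
            normality_check(rng.standard_t(2, 200))[1] < 0.05
            for _ in range(100)
        )
        assert rejections / 100 > 0.5

    def test_small_and_constant_samples_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_check(np.ones(10))


class TestMixedModel:
    def test_agrees_with_lmerTest_oracle(self, rng, tmp_path):
        """t, Satterthwaite df and p match lme4/lmerTest on one dataset."""
        df = _nested_data(rng, effect=1.0, n_cases=5, n_stacks=3)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages({{library(lmerTest)}})
            d <- read.csv("{csv}")
            d$group <- relevel(factor(d$group), ref="ctrl")
            m <- lmerTest::lmer(response ~ group + (1|case), data=d)
            co <- summary(m)$coefficients["groupad", ]
            cat(sprintf("%.6f %.6f %.6f\\n", co["t value"], co["df"],
                        co["Pr(>|t|)"]))
        """)
        out = subprocess.run(["Rscript", "-e", script],
                             capture_output=True, text=True, check=True)
        t_ref, df_ref, p_ref = map(float, out.stdout.split())
        fit = fit_group_model(df, reference="ctrl")
        c = fit.contrast("group[ad]")
        assert c.t == pytest.approx(t_ref, abs=1e-3)
        assert c.df == pytest.approx(df_ref, rel=0.02)
        assert c.p == pytest.approx(p_ref, rel=0.02, abs=1e-4)

    def test_one_observation_per_case_matches_t_test(self, rng):
        a = rng.normal(0, 1, 8)
        b = rng.normal(0.8, 1, 8)
        df = pd.DataFrame(dict(
            case=[f"c{i}" for i in range(16)],
            group=["a"] * 8 + ["b"] * 8,
            response=np.r_[a, b],
        ))
        fit = fit_group_model(df, reference="a")
        t_ref = sps.ttest_ind(b, a).statistic
        assert fit.contrast("group[b]").t == pytest.approx(t_ref, abs=1e-3)

    def test_affine_shift_changes_only_intercept(self, rng):
        df = _nested_data(rng, effect=0.7)
        f1 = fit_group_model(df, reference="ctrl")
        df2 = df.assign(response=df["response"] + 100.0)
        f2 = fit_group_model(df2, reference="ctrl")
        assert f1.contrast("group[ad]").t == pytest.approx(
            f2.contrast("group[ad]").t, rel=1e-6
        )

    def test_identical_responses_flagged_singular(self):
        df = pd.DataFrame(dict(
            case=["a", "a", "b", "b"], group=["g1", "g1", "g2", "g2"],
            response=[3.0] * 4,
        ))
        fit = fit_group_model(df)
        assert fit.singular

    def test_median_aggregation_reduces_to_one_row_per_case(self, rng):
        df = _nested_data(rng, effect=0.5, n_cases=4, n_stacks=5)
        fit = fit_group_model(df, aggregate="median")
        assert fit.n_obs == 8

    def test_requires_two_cases(self):
        df = pd.DataFrame(dict(case=["a"] * 4, group=["g1", "g1", "g2", "g2"],
                               response=[1.0, 2.0, 3.0, 4.0]))
        with pytest.raises(ValueError, match="2 cases"):
            fit_group_model(df)

    def test_null_p_values_are_roughly_uniform(self, rng):
        """Sampled null p-values pass a KS test against Uniform(0,1)."""
        ps = [
            fit_group_model(_nested_data(rng, n_cases=6, n_stacks=2))
            .contrasts[0].p
            for _ in range(150)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01
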