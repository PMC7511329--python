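"""Lesion preprocessing, correlation checks, trait pruning, mixed models
with Satterthwaite df, stepwise selection and the likelihood-ratio test."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from playnet.netbuild import Animal, InteractionEvent
from playnet.outcomes import (
    ModelResult,
    ModelSpec,
    compute_outcomes,
    fit_lmm,
    lrt,
    play_lesion_correlation,
    prune_correlated,
    stepwise_network_traits,
    stepwise_systematic,
)


def make_animal(i, lesions, latency=50.0, treatment="control", pen="p1", litter=None, **extra):
    return Animal(
        id=f"a{i}",
        pen_id=pen,
        litter_id=litter or ("LX" if treatment == "control" else "LA"),
        sex="male" if i % 2 else "female",
        treatment=treatment,
        batch=1,
        attack_latency_s=latency,
        lesion_counts=lesions,
        extra=extra,
    )


class TestComputeOutcomes:
    def test_contest_delta_by_subtraction(self):
        a = make_animal(1, dict(pre_contest=5, post_contest=45, pre_mix=2, mix_24h=30, mix_3wk=7))
        (o,) = compute_outcomes([a])
        assert o.contest_delta == 40
        assert o.mix24_delta == 28

    def test_zero_three_week_count_log1p(self):
        a = make_animal(1, dict(pre_contest=0, post_contest=1, pre_mix=0, mix_24h=1, mix_3wk=0))
        (o,) = compute_outcomes([a], transform="log1p")
        assert o.mix3wk_log == 0.0

    def test_natural_log_flag(self):
        a = make_animal(1, dict(pre_contest=0, post_contest=1, pre_mix=0, mix_24h=1, mix_3wk=20))
        (o,) = compute_outcomes([a], transform="log")
        assert o.mix3wk_log == pytest.approx(np.log(20))

    def test_vector_matches_hand_computation(self):
        rng = np.random.default_rng(1)
        animals = []
        expected = []
        for i in range(12):
            pre_c, post_c = int(rng.integers(0, 10)), int(rng.integers(10, 60))
            pre_m, m24, m3 = int(rng.integers(0, 10)), int(rng.integers(10, 90)), int(rng.integers(0, 40))
            animals.append(make_animal(i, dict(pre_contest=pre_c, post_contest=post_c,
                                               pre_mix=pre_m, mix_24h=m24, mix_3wk=m3)))
            expected.append((post_c - pre_c, m24 - pre_m, np.log1p(m3)))
        got = [(o.contest_delta, o.mix24_delta, o.mix3wk_log) for o in compute_outcomes(animals)]
        assert np.allclose(got, expected)

    def test_missing_time_point_excluded_with_warning(self):
        good = make_animal(1, dict(pre_contest=1, post_contest=2, pre_mix=1, mix_24h=2, mix_3wk=3))
        bad = make_animal(2, dict(pre_contest=1, post_contest=2))
        with pytest.warns(UserWarning, match="missing lesion"):
            out = compute_outcomes([good, bad])
        assert [o.animal_id for o in out] == ["a1"]


class TestPlayLesionCorrelation:
    def _setup(self, rng, n=64, linear=False):
        animals, events = [], []
        for treatment, pen, litters in (("socialised", "pS", ("LA", "LB")), ("control", "pC", ("LX",))):
            for i in range(n):
                idx = len(animals)
                k = int(rng.integers(0, 12))
                lesions = dict(pre_contest=0, post_contest=1, pre_mix=0, mix_24h=1, mix_3wk=1)
                lesions["soc_24h"] = int(4 * k) if linear else int(rng.integers(0, 30))
                animals.append(
                    Animal(f"x{idx}", pen, litters[idx % len(litters)],
                           "female", treatment, 1, lesion_counts=lesions)
                )
                for _ in range(k):
                    events.append(InteractionEvent(pen, 1, f"x{idx}", f"x{(idx + 1)}", True))
        # partner ids referenced above must exist; pad one extra per pen
        return events, animals

    def test_independent_vectors_p_matches_t_formula(self):
        rng = np.random.default_rng(12)
        events, animals = self._setup(rng, n=128)
        r_s, p_s, r_c, p_c = play_lesion_correlation(events, animals)
        for r, p, n in ((r_s, p_s, 128), (r_c, p_c, 128)):
            assert abs(r) < 0.25
            t = r * np.sqrt((n - 2) / (1 - r**2))
            assert p == pytest.approx(2 * stats.t.sf(abs(t), n - 2), rel=1e-6)

    def test_small_group_errors(self):
        rng = np.random.default_rng(1)
        events, animals = self._setup(rng, n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            play_lesion_correlation(events, animals)


class TestPruneCorrelated:
    def test_duplicate_column_dropped_once(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        reduced, dropped = prune_correlated(df)
        assert dropped == ["b"]
        assert list(reduced.columns) == ["a", "c"]

    def test_independent_noise_untouched(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        reduced, dropped = prune_correlated(df)
        assert dropped == []
        assert reduced.shape == df.shape

    def test_constant_dropped_with_warning(self):
        df = pd.DataFrame({"a": np.arange(10.0), "flat": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            reduced, dropped = prune_correlated(df)
        assert dropped == ["flat"]

    def test_postcondition_no_pair_above_threshold(self):
        rng = np.random.default_rng(9)
        latent = rng.normal(size=150)
        df = pd.DataFrame(
            {
                "w": latent + 0.1 * rng.normal(size=150),
                "x": latent + 0.1 * rng.normal(size=150),
                "y": latent + 0.2 * rng.normal(size=150),
                "z": rng.normal(size=150),
            }
        )
        reduced, _ = prune_correlated(df, threshold=0.8)
        corr = reduced.corr().abs().values
        np.fill_diagonal(corr, 0)
        assert corr.max() <= 0.8


def simulate_lmm(rng, n_groups=12, per_group=18, beta=(2.0, -1.0), group_sd=1.0, resid_sd=1.0):
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for _ in range(per_group):
            x1, x2 = rng.normal(), rng.normal()
            y = beta[0] * x1 + beta[1] * x2 + u + rng.normal(0, resid_sd)
            rows.append({"y": y, "x1": x1, "x2": x2, "g": f"g{g}"})
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_zero_variance_grouping_matches_ols(self):
        rng = np.random.default_rng(21)
        # residuals centred within groups: between-group variance is
        # exactly zero, so the variance component pins at the boundary
        df = pd.DataFrame({"x": rng.normal(size=120), "g": [f"g{i % 6}" for i in range(120)]})
        e = rng.normal(size=120)
        df["y"] = 1.5 * df.x + (e - pd.Series(e).groupby(df.g).transform("mean"))
        with pytest.warns(UserWarning, match="singular"):
            res = fit_lmm(ModelSpec("y", ("x",), ("g",)), df)
        import statsmodels.formula.api as smf

        ols = smf.ols("y ~ x", df).fit()
        assert res.coefficients["x"].estimate == pytest.approx(ols.params["x"], abs=1e-3)
        assert res.singular

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(100)
        df = simulate_lmm(rng)
        res = fit_lmm(ModelSpec("y", ("x1", "x2"), ("g",)), df)
        for term, true in (("x1", 2.0), ("x2", -1.0)):
            c = res.coefficients[term]
            assert abs(c.estimate - true) < 3 * c.se

    def test_reml_and_ml_loglik_ordering(self):
        rng = np.random.default_rng(5)
        df = simulate_lmm(rng, n_groups=8, per_group=10)
        ml = fit_lmm(ModelSpec("y", ("x1",), ("g",), "ML"), df)
        ml_red = fit_lmm(ModelSpec("y", (), ("g",), "ML"), df)
        assert ml.loglik >= ml_red.loglik  # extra parameter cannot hurt ML fit

    def test_satterthwaite_df_matches_lmerTest(self, tmp_path):
        """Independent oracle: lmerTest's Satterthwaite df/t/p in R."""
        rng = np.random.default_rng(42)
        df = simulate_lmm(rng, n_groups=10, per_group=8)
        res = fit_lmm(ModelSpec("y", ("x1", "x2"), ("g",)), df)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            f"""
suppressMessages(library(lmerTest))
d <- read.csv("{csv}")
m <- lmer(y ~ x1 + x2 + (1|g), d)
s <- coef(summary(m))
write.csv(s, "{tmp_path}/out.csv")
"""
        )
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/lmerTest unavailable: {proc.stderr[-200:]}")
        r = pd.read_csv(tmp_path / "out.csv", index_col=0)
        for term, rname in (("Intercept", "(Intercept)"), ("x1", "x1"), ("x2", "x2")):
            c = res.coefficients[term]
            assert c.estimate == pytest.approx(r.loc[rname, "Estimate"], abs=2e-3)
            assert c.se == pytest.approx(r.loc[rname, "Std. Error"], rel=1e-2)
            assert c.df == pytest.approx(r.loc[rname, "df"], rel=0.05)
            assert c.p == pytest.approx(r.loc[rname, "Pr(>|t|)"], rel=0.1, abs=1e-6)


class TestStepwise:
    def test_all_noise_covariates_removed(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame(rng.normal(size=(150, 4)), columns=["y", "n1", "n2", "n3"])
        df["g"] = [f"g{i % 5}" for i in range(150)]
        spec = stepwise_systematic(ModelSpec("y", ("n1", "n2", "n3"), ("g",)), df)
        assert spec.fixed == ()

    def test_strong_covariate_always_retained(self):
        rng = np.random.default_rng(7)
        for rep in range(10):
            df = pd.DataFrame({"x": rng.normal(size=80), "n1": rng.normal(size=80)})
            df["y"] = 5.0 * df.x + rng.normal(size=80)
            df["g"] = [f"g{i % 4}" for i in range(80)]
            spec = stepwise_systematic(ModelSpec("y", ("x", "n1"), ("g",)), df)
            assert "x" in spec.fixed

    def test_empty_candidates_unchanged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.normal(size=30), "g": ["g1"] * 15 + ["g2"] * 15})
        spec = ModelSpec("y", (), ("g",))
        assert stepwise_systematic(spec, df) == spec

    def test_interaction_terms_protect_main_effects(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=100), "z": rng.normal(size=100)})
        df["y"] = rng.normal(size=100)
        df["g"] = [f"g{i % 4}" for i in range(100)]
        spec = stepwise_systematic(ModelSpec("y", ("x", "z", "x:z"), ("g",)), df,
                                   protected={"x:z"})
        assert {"x", "z", "x:z"} <= set(spec.fixed)


class TestStepwiseNetworkTraits:
    def _data(self, rng, effect=4.0, n=160):
        df = pd.DataFrame(rng.normal(size=(n, 9)), columns=[f"t{i}" for i in range(9)])
        df["y"] = effect * df.t0 + rng.normal(size=n)
        return df

    def test_informative_trait_selected(self):
        rng = np.random.default_rng(77)
        df = self._data(rng)
        spec, vif = stepwise_network_traits(
            ModelSpec("y", (), ()), [f"t{i}" for i in range(9)], df
        )
        assert "t0" in spec.fixed
        assert all(v < 10 for v in vif.values())

    def test_all_noise_selection_close_to_null(self):
        rng = np.random.default_rng(13)
        df = self._data(rng, effect=0.0)
        spec, _ = stepwise_network_traits(ModelSpec("y", (), ()), [f"t{i}" for i in range(9)], df)
        null_aic = fit_lmm(ModelSpec("y", (), (), "ML"), df).aic
        sel_aic = fit_lmm(ModelSpec("y", spec.fixed, (), "ML"), df).aic
        assert sel_aic <= null_aic + 2

    def test_duplicated_trait_excluded_before_search(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"t0": rng.normal(size=60)})
        df["t1"] = df["t0"]
        df["y"] = df.t0 + rng.normal(size=60)
        with pytest.warns(UserWarning, match="collinear"):
            spec, _ = stepwise_network_traits(ModelSpec("y", (), ()), ["t0", "t1"], df)
        assert "t1" not in spec.fixed


class TestLrt:
    def _ml(self, fixed, loglik, n=100):
        coefs = {f"b{i}": None for i in range(len(fixed) + 1)}
        return ModelResult(ModelSpec("y", tuple(fixed), (), "ML"), coefs, 0.0, loglik, n)

    def test_identical_models(self):
        full = self._ml(["x"], -100.0)
        red = self._ml(["x"], -100.0)
        chi2, df, p = lrt(full, red)
        assert (chi2, df, p) == (0.0, 0, 1.0)

    def test_chi2_quantile_identity(self):
        full = self._ml(["x"], -100.0)
        red = self._ml([], -100.0 - 3.841459 / 2)
        chi2, df, p = lrt(full, red)
        assert df == 1
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_reml_fits_rejected(self):
        bad = ModelResult(ModelSpec("y", ("x",), (), "REML"), {}, 0.0, -1.0, 10)
        with pytest.raises(ValueError, match="ML"):
            lrt(bad, bad)

    def test_simulated_effect_consistent_with_wald(self):
        rng = np.random.default_rng(3)
        df = simulate_lmm(rng, n_groups=10, per_group=12, beta=(0.3, 0.0))
        full = fit_lmm(ModelSpec("y", ("x1",), ("g",), "ML"), df)
        red = fit_lmm(ModelSpec("y", (), ("g",), "ML"), df)
        chi2, dfree, p_lrt = lrt(full, red)
        z = full.coefficients["x1"].estimate / full.coefficients["x1"].se
        p_wald = 2 * stats.norm.sf(abs(z))
        assert dfree == 1
        # agreement to order of magnitude on the log scale
        assert abs(np.log10(max(p_lrt, 1e-300)) - np.log10(max(p_wald, 1e-300))) < 1.0
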