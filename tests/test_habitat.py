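import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import eaglestates as es
from eaglestates.habitat import (GelmanScale, ModelFit, aicc, average_models,
                                 build_frames, dredge_aicc,
                                 fit_mixed_logistic, ranking_table,
                                 rescale_gelman)
from eaglestates.synthetic import REFERENCE_LOWHIGH_COEFS


# ---------------------------------------------------------------------------
# rescaling
# ---------------------------------------------------------------------------

class TestRescaleGelman:
    def test_mean_zero_half_sd(self):
        x = np.random.default_rng(0).gamma(2, 3, 1000)
        xr, _ = rescale_gelman(x)
        assert abs(xr.mean()) < 1e-12
        assert abs(xr.std(ddof=1) - 0.5) < 1e-12

    def test_balanced_binary_values(self):
        n = 200
        x = np.repeat([0.0, 1.0], n // 2)
        xr, _ = rescale_gelman(x)
        # (1 - 0.5) / (2 * sd1) with sample sd of a balanced 0/1 column
        expected = 0.5 * math.sqrt((n - 1) / n)
        np.testing.assert_allclose(sorted(set(np.round(xr, 12))),
                                   [-expected, expected], atol=1e-9)

    def test_stored_transform_reusable(self):
        x = np.random.default_rng(1).normal(10, 2, 500)
        xr, scale = rescale_gelman(x)
        again, _ = rescale_gelman(x, scale=scale)
        np.testing.assert_allclose(again, xr)
        assert isinstance(scale, GelmanScale)

    def test_constant_column_error_names_column(self):
        with pytest.raises(ValueError, match="elevation"):
            rescale_gelman(np.ones(10), name="elevation")


# ---------------------------------------------------------------------------
# modeling frames
# ---------------------------------------------------------------------------

def _points_table(states, year=2015, month=6, bird="b1"):
    n = len(states)
    rng = np.random.default_rng(0)
    return pd.DataFrame({
        "bird_id": bird,
        "t": pd.Timestamp(f"{year}-{month:02d}-01 18:00"),
        "state": states,
        "elevation": rng.normal(900, 100, n),
        "northness": rng.uniform(-1, 1, n),
        "eastness": rng.uniform(-1, 1, n),
        "slope": rng.uniform(0, 25, n),
        "landcover": rng.integers(1, 5, n),
        "tpi_class": rng.integers(1, 5, n),
    })


class TestBuildFrames:
    def test_frame_sizes_match_state_counts(self):
        states = [1] * 60 + [2] * 30 + [3] * 7 + [4] * 3
        frames = build_frames(_points_table(states))
        assert len(frames["lowhigh"]) == 100
        assert frames["lowhigh"]["response"].sum() == 90
        assert len(frames["s1v2"]) == 90
        assert frames["s1v2"]["response"].sum() == 60
        assert len(frames["s3v4"]) == 10
        assert frames["s3v4"]["response"].sum() == 7

    def test_age_increments_each_january(self):
        pts_dec = _points_table([1] * 50 + [3] * 50, year=2016, month=12)
        pts_jan = _points_table([1] * 50 + [3] * 50, year=2017, month=1)
        meta = pd.DataFrame({"bird_id": ["b1"], "hatch_year": [2012]})
        dec = build_frames(pts_dec, bird_meta=meta)["lowhigh"]
        jan = build_frames(pts_jan, bird_meta=meta)["lowhigh"]
        assert (dec["age_preadult"] == 1.0).all()   # age 4 in December
        assert (jan["age_preadult"] == 0.0).all()   # adult from January

    def test_single_class_frame_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="s3v4"):
            frames = build_frames(_points_table([1] * 50 + [2] * 50 + [3] * 5))
        assert "s3v4" not in frames

    def test_reference_levels_absent_from_dummies(self):
        frames = build_frames(_points_table([1] * 80 + [3] * 20))
        cols = frames["lowhigh"].columns
        # canyon, forest, and adult are reference levels, not columns
        assert "tpi_canyon" not in cols and "landcover_forest" not in cols
        assert {"tpi_steep", "tpi_gentle", "tpi_ridge",
                "landcover_semidesert"} <= set(cols)


# ---------------------------------------------------------------------------
# mixed logistic regression
# ---------------------------------------------------------------------------

class TestFitMixedLogistic:
    def test_degenerate_variances_match_plain_logit(self):
        fr = es.simulate_logistic_frame(n_obs=4000, n_birds=10,
                                        re_sd_bird=0.0, re_sd_month=0.0, seed=1)
        fit = fit_mixed_logistic(fr, ("elevation", "northness", "eastness",
                                      "slope"))
        X = sm.add_constant(fr[["elevation", "northness", "eastness", "slope"]])
        plain = sm.Logit(fr["response"], X).fit(disp=0)
        np.testing.assert_allclose(fit.coef.to_numpy(), plain.params.to_numpy(),
                                   atol=1e-3)
        assert fit.re_sd["bird"] < 0.1

    def test_intercept_only_matches_logit_of_rate(self):
        fr = es.simulate_logistic_frame(n_obs=3000, n_birds=8, intercept=0.8,
                                        re_sd_bird=0.0, re_sd_month=0.0, seed=2)
        fit = fit_mixed_logistic(fr, ())
        rate = fr["response"].mean()
        assert abs(fit.coef["(Intercept)"] - math.log(rate / (1 - rate))) < 0.02

    def test_recovery_within_3se(self):
        fr = es.simulate_logistic_frame(n_obs=20_000, n_birds=40, seed=3)
        fit = fit_mixed_logistic(fr, ("elevation", "northness", "eastness",
                                      "slope"))
        for name, truth in REFERENCE_LOWHIGH_COEFS.items():
            assert abs(fit.coef[name] - truth) <= 3 * fit.se[name]
        # generating random-intercept SDs were 0.5
        assert 0.3 < fit.re_sd["bird"] < 0.8
        assert 0.3 < fit.re_sd["month"] < 0.8

    def test_rescaling_invariance_to_raw_units(self):
        rng = np.random.default_rng(4)
        raw = rng.normal(1000, 150, 3000)
        fr = es.simulate_logistic_frame(n_obs=3000, n_birds=10, seed=5)
        a = fr.copy()
        a["elevation"], _ = rescale_gelman(raw)
        b = fr.copy()
        b["elevation"], _ = rescale_gelman(2.0 * raw)   # doubled raw units
        fa = fit_mixed_logistic(a, ("elevation",))
        fb = fit_mixed_logistic(b, ("elevation",))
        np.testing.assert_allclose(fa.coef["elevation"], fb.coef["elevation"],
                                   atol=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_cross_check_against_lme4(self, tmp_path):
        fr = es.simulate_logistic_frame(n_obs=1500, n_birds=12, seed=9)
        csv = tmp_path / "frame.csv"
        fr.to_csv(csv, index=False)
        fit = fit_mixed_logistic(fr, ("elevation", "northness", "eastness",
                                      "slope"))
        script = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        m <- glmer(response ~ elevation + northness + eastness + slope
                   + (1|bird_id) + (1|month), data=d, family=binomial)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep='\\n')
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True, timeout=300)
        vals = [float(v) for v in out.stdout.strip().splitlines()]
        fixef, re_sds, loglik = vals[:5], vals[5:7], vals[7]
        np.testing.assert_allclose(fit.coef.to_numpy(), fixef, atol=0.02)
        np.testing.assert_allclose(sorted(fit.re_sd.values()), sorted(re_sds),
                                   atol=0.01)
        assert abs(fit.loglik - loglik) < 0.05


# ---------------------------------------------------------------------------
# AICc
# ---------------------------------------------------------------------------

class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(-100.0, 5, 100) == pytest.approx(210 + 60 / 94, abs=1e-9)

    def test_k_zero_equals_aic(self):
        assert aicc(-50.0, 0, 30) == pytest.approx(100.0)

    def test_large_n_limit_is_aic(self):
        assert aicc(-100.0, 5, 10 ** 9) == pytest.approx(210.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


# ---------------------------------------------------------------------------
# dredge and averaging
# ---------------------------------------------------------------------------

def _mk_fit(terms, coef, se, weight, n=1000):
    names = ["(Intercept)"] + list(coef)
    return ModelFit(terms=tuple(terms),
                    coef=pd.Series([0.0] + list(coef.values()), index=names),
                    se=pd.Series([0.1] + list(se.values()), index=names),
                    re_sd={"bird": 0.5, "month": 0.5}, loglik=-100.0,
                    k=len(coef) + 3, n=n, aicc=0.0, delta_aicc=0.0,
                    weight=weight)


@pytest.fixture(scope="module")
def small_frame():
    return es.simulate_logistic_frame(
        n_obs=2500, n_birds=8,
        coefs={"elevation": 1.0, "slope": 0.8, "northness": 0.0,
               "eastness": 0.0},
        re_sd_bird=0.3, re_sd_month=0.3, seed=11)


@pytest.fixture(scope="module")
def fits(small_frame):
    return dredge_aicc(small_frame,
                       ("elevation", "slope", "northness", "eastness"))


class TestDredge:
    def test_all_subsets_ranked(self, fits):
        assert len(fits) == 16
        aiccs = [f.aicc for f in fits]
        assert aiccs == sorted(aiccs)

    def test_weights_sum_to_one(self, fits):
        assert abs(sum(f.weight for f in fits) - 1.0) < 1e-9

    def test_true_terms_dominate_top_model(self):
        # signal terms always make the top model; pure-noise terms are
        # excluded in most replicates (they sneak in by chance occasionally)
        exact = 0
        for seed in range(10):
            fr = es.simulate_logistic_frame(
                n_obs=2000, n_birds=8,
                coefs={"elevation": 1.0, "slope": 0.8, "northness": 0.0,
                       "eastness": 0.0},
                re_sd_bird=0.3, re_sd_month=0.3, seed=100 + seed)
            top = dredge_aicc(fr, ("elevation", "slope", "northness",
                                   "eastness"))[0]
            assert {"elevation", "slope"} <= set(top.terms)
            exact += not ({"northness", "eastness"} & set(top.terms))
        assert exact >= 7

    def test_duplicate_term_sets_deduplicated(self, small_frame):
        fits = dredge_aicc(small_frame, ("elevation", "elevation", "slope"))
        assert len(fits) == 4

    def test_ranking_table_shape(self, fits):
        t = ranking_table(fits)
        assert list(t.columns) == ["terms", "AICc", "dAICc", "weight",
                                   "logLik", "k"]
        assert t["dAICc"].iloc[0] == 0.0


class TestAverageModels:
    def test_single_model_degenerate(self):
        f = _mk_fit(("elevation",), {"elevation": 0.4}, {"elevation": 0.05},
                    weight=1.0)
        avg = average_models([f])
        row = avg.set_index("term").loc["elevation"]
        assert row["estimate"] == pytest.approx(0.4)
        assert row["adj_se"] == pytest.approx(0.05)

    def test_zero_substitution_half_weight(self):
        a = _mk_fit(("elevation",), {"elevation": 1.0}, {"elevation": 0.0},
                    weight=0.5)
        b = _mk_fit((), {}, {}, weight=0.5)
        avg = average_models([a, b]).set_index("term")
        assert avg.loc["elevation", "estimate"] == pytest.approx(0.5)
        # between-model variance only: w*(1-0.5)^2 + w*(0-0.5)^2 = 0.25
        assert avg.loc["elevation", "adj_se"] == pytest.approx(0.5)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            fits = []
            weights = rng.dirichlet(np.ones(4))
            term_sets = [("elevation", "slope"), ("elevation",), ("slope",), ()]
            for terms, w in zip(term_sets, weights):
                coef = {t: rng.normal() for t in terms}
                se = {t: abs(rng.normal()) + 0.01 for t in terms}
                fits.append(_mk_fit(terms, coef, se, weight=float(w)))
            avg = average_models(fits, weight_floor=0.0).set_index("term")
            for term in ("elevation", "slope"):
                b = np.array([f.coef.get(term, 0.0) for f in fits])
                s = np.array([f.se.get(term, 0.0) for f in fits])
                bbar = weights @ b
                adj = math.sqrt(weights @ (s ** 2 + (b - bbar) ** 2))
                assert abs(avg.loc[term, "estimate"] - bbar) < 1e-10
                assert abs(avg.loc[term, "adj_se"] - adj) < 1e-10

    def test_weight_floor_monotonicity(self):
        fits = [_mk_fit(("elevation",), {"elevation": 1.0},
                        {"elevation": 0.1}, weight=w)
                for w in (0.7, 0.25, 0.04, 0.008)]
        hi = average_models(fits, weight_floor=0.01)
        lo = average_models(fits, weight_floor=0.001)
        # lowering the floor only widens the retained set
        assert len(hi) == len(lo)
        assert not hi.equals(lo)   # estimates shift, ordering logic unchanged

    def test_empty_retained_set_rejected(self):
        f = _mk_fit((), {}, {}, weight=0.001)
        with pytest.raises(ValueError):
            average_models([f], weight_floor=0.01)
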