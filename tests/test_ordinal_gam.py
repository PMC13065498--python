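"""Cumulative-logit additive model: likelihood, fitting, prediction."""

import numpy as np
import pandas as pd
import pytest

from windforay import ordinal_gam as og
from windforay import synthetic as syn

STUDY_COUNTS = np.array([157770.0, 7408.0, 3024.0])


def _counts_frame():
    return pd.DataFrame({"label": ["SRM", "MRM", "LRM"]})


@pytest.fixture(scope="module")
def label_draws():
    cfg = syn.SimConfig(seed=3, start_date="2021-01-01", end_date="2021-03-31")
    return syn.simulate_ordinal_labels(cfg, n_per_individual=250)


def _reduced_spec():
    return og.OrdinalGamSpec(terms=[
        og.Term("tensor", ("wind_dir_deg", "wind_kmh"), k=(8, 5), period=360.0,
                name="te(dir,wind)"),
        og.Term("spline", ("radiation_wm2",), k=6, name="f(rad)"),
        og.Term("random", ("individual_id",), name="b(individual)"),
    ])


class TestLikelihood:
    def test_derivatives_match_finite_differences(self, rng):
        y = rng.integers(1, 4, 60)
        eta = rng.normal(0, 1.5, 60)
        th2 = 0.8
        eps = 1e-6
        ll, de, dt, hee, het, htt = og._cumlogit_derivs(y, eta, th2)
        np.testing.assert_allclose(
            (og._cumlogit_derivs(y, eta + eps, th2)[0] - ll) / eps, de, atol=1e-5)
        np.testing.assert_allclose(
            (og._cumlogit_derivs(y, eta, th2 + eps)[0] - ll) / eps, dt, atol=1e-5)
        np.testing.assert_allclose(
            (og._cumlogit_derivs(y, eta + eps, th2)[1] - de) / eps, hee, atol=1e-4)
        np.testing.assert_allclose(
            (og._cumlogit_derivs(y, eta + eps, th2)[2] - dt) / eps, het, atol=1e-4)
        np.testing.assert_allclose(
            (og._cumlogit_derivs(y, eta, th2 + eps)[2] - dt) / eps, htt, atol=1e-4)

    def test_symmetric_thresholds_closed_form(self):
        probs = og.category_probs(np.array([0.0]), theta2=1.0)[0]
        np.testing.assert_allclose(probs, [0.26894142, 0.46211716, 0.26894142],
                                   atol=1e-8)

    def test_probabilities_sum_to_one_and_monotone_in_eta(self):
        eta = np.linspace(-5, 5, 101)
        probs = og.category_probs(eta, theta2=0.7)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (np.diff(probs[:, 0]) < 0).all()   # P(SRM) falls as eta rises
        assert (np.diff(probs[:, 2]) > 0).all()   # P(LRM) rises


class TestNullModel:
    def test_intercept_only_recovers_empirical_proportions(self):
        fit = og.fit_ordinal_gam(og.OrdinalGamSpec(terms=[]), _counts_frame(),
                                 weights=STUDY_COUNTS, lambdas=np.zeros(0))
        probs = og.category_probs(np.array([fit.beta[0]]), fit.theta2)[0]
        np.testing.assert_allclose(probs, STUDY_COUNTS / STUDY_COUNTS.sum(),
                                   atol=1e-4)

    def test_gradient_vanishes_at_optimum(self, rng):
        # small penalised fit: score must vanish at the returned optimum
        n = 200
        d = pd.DataFrame({
            "wind_dir_deg": rng.uniform(0, 360, n),
            "radiation_wm2": rng.uniform(0, 800, n),
            "label": rng.choice(["SRM", "MRM", "LRM"], n, p=[0.6, 0.25, 0.15]),
        })
        spec = og.OrdinalGamSpec(terms=[
            og.Term("cyclic", ("wind_dir_deg",), k=6, period=360.0, name="f(dir)"),
            og.Term("spline", ("radiation_wm2",), k=5, name="f(rad)"),
        ])
        lam = np.array([1.0, 1.0])
        fit = og.fit_ordinal_gam(spec, d, lambdas=lam)
        X, blocks, _ = og._build_blocks(spec, d)
        y = og._encode_response(d["label"])
        P = og._penalty_matrix(blocks, lam, X.shape[1])
        _, d_eta, d_th, *_ = og._cumlogit_derivs(y, X @ fit.beta, fit.theta2)
        grad = np.concatenate([X.T @ d_eta - P @ fit.beta, [d_th.sum()]])
        assert np.abs(grad).max() < 1e-6


class TestPenaltyBehaviour:
    def _toy(self, rng, n=400):
        x = rng.uniform(0, 10, n)
        eta = np.sin(x)
        probs = og.category_probs(eta, 1.0)
        u = rng.random(n)
        y = 1 + (u > probs[:, 0]) + (u > probs[:, 0] + probs[:, 1])
        return pd.DataFrame({"x": x, "label": y})

    def test_infinite_lambda_reduces_to_null_space(self, rng):
        d = self._toy(rng)
        spec = og.OrdinalGamSpec(terms=[og.Term("spline", ("x",), k=6, name="f(x)")])
        fit = og.fit_ordinal_gam(spec, d, lambdas=np.array([1e10]))
        # curvature penalty null space after centring: the linear trend (1 df)
        assert fit.edf_by_term["f(x)"] == pytest.approx(1.0, abs=0.05)
        loose = og.fit_ordinal_gam(spec, d, lambdas=np.array([1e-8]))
        assert loose.edf_by_term["f(x)"] > 3.0

    def test_penalized_loglik_non_decreasing_over_lambda_refit(self, rng):
        d = self._toy(rng)
        spec = og.OrdinalGamSpec(terms=[og.Term("spline", ("x",), k=6, name="f(x)")])
        lls = [og.fit_ordinal_gam(spec, d, lambdas=np.array([lam])).loglik
               for lam in (1e-6, 1.0, 1e6)]
        assert lls[0] >= lls[1] >= lls[2]  # likelihood falls as smoothing rises


class TestRecovery:
    def test_radiation_partial_effect_recovered(self, label_draws):
        fit = og.fit_ordinal_gam(_reduced_spec(), label_draws,
                                 lambda_grid=np.logspace(-2, 3, 6), refine=False)
        blk = [b for b in fit.blocks if b.term.name == "f(rad)"][0]
        grid = og.reference_frame(fit, 60, {"radiation_wm2": np.linspace(0, 800, 60)})
        partial = og.design_for(fit, grid)[:, blk.sl] @ fit.beta[blk.sl]
        truth = np.linspace(0, 1, 60)  # generating effect is a3 * R_norm
        assert np.corrcoef(partial, truth)[0, 1] >= 0.8

    def test_surface_periodic_and_normalised(self, label_draws):
        fit = og.fit_ordinal_gam(_reduced_spec(), label_draws,
                                 lambda_grid=np.logspace(-2, 3, 6), refine=False)
        surf = og.predict_surface(fit, dir_grid=np.arange(0, 361, 10.0),
                                  wind_grid=np.linspace(0, 60, 13))
        total = sum(surf["prob"][c] for c in og.CATEGORIES)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        for c in og.CATEGORIES:
            np.testing.assert_allclose(surf["prob"][c][:, 0], surf["prob"][c][:, -1],
                                       atol=1e-9)
            assert (surf["se"][c] >= 0).all()

    def test_no_spurious_interaction_when_data_additive(self, rng):
        # generate from an additive surface; the fitted eta surface must
        # stay (ANOVA-)additive: its interaction component is negligible
        n = 5000
        d = pd.DataFrame({
            "wind_dir_deg": rng.uniform(0, 360, n),
            "wind_kmh": rng.uniform(0, 50, n),
        })
        eta = (np.cos(np.radians(d["wind_dir_deg"])) + 0.04 * d["wind_kmh"]).to_numpy()
        probs = og.category_probs(eta, 1.0)
        u = rng.random(n)
        d["label"] = 1 + (u > probs[:, 0]) + (u > probs[:, 0] + probs[:, 1])
        spec = og.OrdinalGamSpec(terms=[
            og.Term("tensor", ("wind_dir_deg", "wind_kmh"), k=(6, 4), period=360.0,
                    name="te(dir,wind)"),
        ])
        fit = og.fit_ordinal_gam(spec, d, lambda_grid=np.logspace(-1, 4, 6),
                                 refine=False)
        dirs = np.arange(0.0, 360.0, 15.0)
        winds = np.linspace(2.0, 48.0, 12)
        D, W = np.meshgrid(dirs, winds)
        frame = pd.DataFrame({"wind_dir_deg": D.ravel(), "wind_kmh": W.ravel()})
        surf = og.predict_eta(fit, frame).reshape(D.shape)
        centred = surf - surf.mean()
        additive = (centred.mean(axis=0, keepdims=True)
                    + centred.mean(axis=1, keepdims=True))
        interaction = centred - additive
        assert interaction.var() < 0.05 * max(centred.var(), 1e-12)


class TestModelSelection:
    def test_duplicate_candidates_identical_aic(self, label_draws):
        spec = og.OrdinalGamSpec(terms=[
            og.Term("spline", ("radiation_wm2",), k=5, name="f(rad)")])
        table = og.select_model([("a", spec), ("b", spec)], label_draws,
                                lambdas=np.array([1.0]))
        assert table["aic"][0] == pytest.approx(table["aic"][1])

    def test_non_nested_lrt_refused(self, label_draws):
        s1 = og.OrdinalGamSpec(terms=[
            og.Term("spline", ("radiation_wm2",), k=5, name="f(rad)")])
        s2 = og.OrdinalGamSpec(terms=[
            og.Term("spline", ("wind_kmh",), k=5, name="f(wind)")])
        with pytest.raises(ValueError):
            og.select_model([("a", s1), ("b", s2)], label_draws,
                            lambdas=np.array([1.0]), nested=[("a", "b")])

    def test_lrt_null_calibration(self, rng):
        # adding an unpenalised pure-noise linear term: LRT ~ chi2_1 under null
        from scipy.stats import kstest, chi2

        pvals = []
        for s in range(60):
            r = np.random.default_rng(1000 + s)
            n = 300
            d = pd.DataFrame({
                "noise": r.normal(0, 1, n),
                "label": r.choice([1, 2, 3], n, p=[0.6, 0.25, 0.15]),
            })
            null_spec = og.OrdinalGamSpec(terms=[])
            alt_spec = og.OrdinalGamSpec(terms=[
                og.Term("linear", ("noise",), name="noise")])
            f0 = og.fit_ordinal_gam(null_spec, d, lambdas=np.zeros(0))
            f1 = og.fit_ordinal_gam(alt_spec, d, lambdas=np.zeros(0))
            stat = max(2.0 * (f1.loglik - f0.loglik), 0.0)
            pvals.append(chi2.sf(stat, 1))
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_aic_plateau_with_growing_basis(self, rng):
        n = 2000
        x = rng.uniform(0, 10, n)
        eta = np.sin(x)  # one-cycle smooth: small basis suffices
        probs = og.category_probs(eta, 1.0)
        u = rng.random(n)
        d = pd.DataFrame({"x": x,
                          "label": 1 + (u > probs[:, 0])
                          + (u > probs[:, 0] + probs[:, 1])})
        aics = []
        for k in (5, 8, 12):
            spec = og.OrdinalGamSpec(terms=[og.Term("spline", ("x",), k=k,
                                                    name="f(x)")])
            aics.append(og.fit_ordinal_gam(
                spec, d, lambda_grid=np.logspace(-2, 3, 6), refine=False).aic)
        assert abs(aics[2] - aics[1]) < 2.0


class TestConfusionMatrix:
    def test_row_sums_match_observed_counts(self, label_draws):
        fit = og.fit_ordinal_gam(_reduced_spec(), label_draws,
                                 lambda_grid=np.logspace(-2, 3, 6), refine=False)
        cm = og.confusion_matrix(fit, label_draws)
        obs = label_draws["label"].value_counts()
        for c in og.CATEGORIES:
            assert cm.loc[f"{c} (observed)"].sum() == obs.get(c, 0)

    def test_dominant_class_collapses_predictions(self, label_draws):
        # heavy imbalance with weak covariates: modal prediction ~ all SRM
        fit = og.fit_ordinal_gam(_reduced_spec(), label_draws,
                                 lambda_grid=np.logspace(-2, 3, 6), refine=False)
        cm = og.confusion_matrix(fit, label_draws)
        srm_pred = cm["SRM (predicted)"].sum()
        assert srm_pred / len(label_draws) > 0.99

    def test_separable_classes_diagonal(self, rng):
        n = 600
        x = np.r_[rng.normal(-6, 0.3, n // 3), rng.normal(0, 0.3, n // 3),
                  rng.normal(6, 0.3, n // 3)]
        d = pd.DataFrame({"x": x, "label": np.repeat([1, 2, 3], n // 3)})
        spec = og.OrdinalGamSpec(terms=[og.Term("linear", ("x",), name="x")])
        fit = og.fit_ordinal_gam(spec, d, lambdas=np.zeros(0))
        cm = og.confusion_matrix(fit, d).to_numpy()
        assert np.trace(cm) >= 0.97 * n
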