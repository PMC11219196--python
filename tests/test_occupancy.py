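import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import occudesign as od
from occudesign.occupancy import (
    FitError,
    FitResult,
    _aicc,
    candidate_set,
    get_spec,
    psi_estimate,
)


def make_history(y_by_site, methods=None, temps=None):
    """Build a small DetectionHistory from per-site outcome tuples."""
    rows = []
    for s, ys in enumerate(y_by_site):
        for j, y in enumerate(ys):
            rows.append(
                {
                    "site": f"S{s}",
                    "method": methods[s][j] if methods else "acoustic",
                    "date": dt.date(2021, 1, 1) + dt.timedelta(days=j),
                    "y": int(y),
                    "temp_max_z": temps[s][j] if temps else 0.0,
                }
            )
    return od.DetectionHistory(frame=pd.DataFrame(rows))


def enumeration_nll(psi, p_by_site, y_by_site):
    """Independent oracle: sum over the latent occupancy state per site."""
    total = 0.0
    for ys, ps in zip(y_by_site, p_by_site):
        lik = 0.0
        for z in (0, 1):
            term = psi if z == 1 else 1.0 - psi
            for y, p in zip(ys, ps):
                pe = p * z
                term *= pe if y == 1 else (1.0 - pe)
            lik += term
        total += -math.log(lik)
    return total


class TestCandidateSet:
    def test_fifteen_specs_with_stable_names(self):
        specs = candidate_set()
        assert len(specs) == 15
        assert [s.name for s in specs] == [f"M{i}" for i in range(1, 16)]

    def test_named_models_match_their_formulas(self):
        assert get_spec("M2").blocks == ()
        assert get_spec("M2").method_effect
        assert get_spec("M7").blocks == ("temp2",)
        assert get_spec("M4").blocks == ("rh",)
        assert get_spec("M11").blocks == ("rain", "temp2")
        assert get_spec("M15").blocks == ("rh2", "temp2")

    def test_every_spec_uses_at_most_two_covariates(self):
        for spec in candidate_set():
            assert len(spec.required_covariates()) <= 2

    def test_duplicate_covariate_blocks_rejected(self):
        with pytest.raises(ValueError):
            od.ModelSpec("bad", blocks=("temp", "temp2"))


class TestNegLogLikelihood:
    def test_hand_computed_two_site_value(self):
        history = make_history([(1, 0), (0, 0)])
        spec = od.ModelSpec("null", method_effect=False)
        nll = od.neg_log_likelihood([0.0, 0.0], spec, history)  # psi=p=0.5
        expected = -(math.log(0.125) + math.log(0.625))
        assert nll == pytest.approx(expected, abs=1e-12)

    def test_certain_model_certain_data(self):
        history = make_history([(1, 1), (1, 1)])
        spec = od.ModelSpec("null", method_effect=False)
        nll = od.neg_log_likelihood([30.0, 30.0], spec, history)
        assert nll == pytest.approx(0.0, abs=1e-6)

    def test_wrong_parameter_count_raises(self):
        history = make_history([(1, 0)])
        with pytest.raises(FitError, match="parameters"):
            od.neg_log_likelihood([0.0, 0.0, 0.0], od.ModelSpec("null", method_effect=False), history)

    def test_empty_history_rejected(self):
        frame = pd.DataFrame(columns=["site", "method", "date", "y"])
        history = od.DetectionHistory(frame=frame)
        with pytest.raises(FitError, match="empty"):
            od.neg_log_likelihood([0.0, 0.0], od.ModelSpec("null", method_effect=False), history)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n_sites=st.integers(1, 4),
        n_occ=st.integers(1, 3),
        data=st.data(),
    )
    def test_matches_latent_state_enumeration(self, n_sites, n_occ, data):
        """Likelihood equals brute-force enumeration over occupancy states
        for arbitrary small histories with method and temperature terms."""
        y = [
            tuple(data.draw(st.integers(0, 1)) for _ in range(n_occ))
            for _ in range(n_sites)
        ]
        meths = [
            tuple(data.draw(st.sampled_from(od.METHODS)) for _ in range(n_occ))
            for _ in range(n_sites)
        ]
        temps = [
            tuple(data.draw(st.floats(-2, 2)) for _ in range(n_occ))
            for _ in range(n_sites)
        ]
        history = make_history(y, methods=meths, temps=temps)
        spec = od.ModelSpec("toy", blocks=("temp",))
        from occudesign.occupancy import design_matrix

        X, names, _ = design_matrix(spec, history)
        k = X.shape[1]
        params = np.array(
            [data.draw(st.floats(-2, 2)) for _ in range(1 + k)]
        )
        nll = od.neg_log_likelihood(params, spec, history)

        # oracle: recompute p per occasion longhand from the named columns
        present = [m for m in od.METHODS if any(m in row for row in meths)]
        beta = dict(zip(names, params[1:]))
        p_by_site = []
        for s in range(n_sites):
            ps = []
            for j in range(n_occ):
                m = meths[s][j]
                eta = beta["p:(intercept)"]
                eta += beta.get(f"p:method[{m}]", 0.0)
                key = f"p:temp_max[{m}]"
                if key in beta:
                    eta += beta[key] * temps[s][j]
                ps.append(expit(eta))
            p_by_site.append(ps)
        expected = enumeration_nll(expit(params[0]), p_by_site, y)
        assert nll == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_all_detected_flags_boundary(self):
        history = make_history([(1, 1, 1)] * 4)
        result = od.fit(od.ModelSpec("null", method_effect=False), history)
        assert result.boundary
        assert result.psi > 0.999

    def test_single_occasion_sites_rejected(self):
        history = make_history([(1,), (0,)])
        with pytest.raises(FitError, match=">= 2 occasions"):
            od.fit("M2", history)

    def test_nesting_never_decreases_loglik(self, paper_history):
        history, _ = paper_history
        lls = [od.fit(name, history, seed=0).loglik for name in ("M2", "M6", "M7")]
        assert lls[0] <= lls[1] + 1e-6
        assert lls[1] <= lls[2] + 1e-6

    def test_aicc_penalises_null_noise_covariate(self):
        """On data with no weather signal the covariate model should lose
        on AICc on average (here: a single seeded realisation is enough
        to check the penalty direction for a clearly null covariate)."""
        config = od.recovery_scenario(n_sites=100, k=8)
        history, _ = od.simulate_binned(config, seed=21)
        simple = od.fit("M2", history, seed=0)
        bigger = od.fit("M6", history, seed=0)
        assert bigger.aicc > simple.aicc

    def test_estimator_api(self, paper_history):
        history, _ = paper_history
        model = od.OccupancyModel(spec="M2", seed=0)
        assert model.get_params()["spec"] == "M2"
        model.fit(history)
        assert model.converged_
        assert model.coef_.shape == (4,)
        assert model.aicc_ == model.result_.aicc
        est = model.predict_detection("acoustic")
        assert 0 < est.estimate < 1

    def test_scaling_invariance_of_predictions(self):
        """Fitting on z-scores and predicting at z gives the same
        detection probability as fitting on raw covariates and
        predicting at the equivalent raw point."""
        config = od.recovery_scenario(n_sites=120, k=8)
        history, _ = od.simulate_binned(config, seed=9, standardize=False)
        scaled, scaler = od.zscore(history)

        fit_raw = od.fit("M6", history, seed=0)
        fit_z = od.fit("M6", scaled, seed=0)
        mu, sd = scaler.means["temp_max"], scaler.sds["temp_max"]
        for m in od.METHODS:
            for z in (-1.0, 0.0, 1.0):
                p_z = od.predict_detection(fit_z, m, {"temp_max": z}).estimate
                p_raw = od.predict_detection(
                    fit_raw, m, {"temp_max": mu + sd * z}
                ).estimate
                assert p_z == pytest.approx(p_raw, abs=1e-3)


class TestRankModels:
    @staticmethod
    def _result(name, loglik, n_params, data_hash=1):
        return FitResult(
            spec=od.ModelSpec(name, method_effect=False),
            coef=np.zeros(n_params),
            coef_names=["x"] * n_params,
            cov=None,
            loglik=loglik,
            n_params=n_params,
            n_sites=46,
            n_occasions_used=100,
            aicc=_aicc(loglik, n_params, 46),
            converged=True,
            boundary=False,
            data_hash=data_hash,
        )

    def test_equal_aicc_splits_weight(self):
        table = od.rank_models([self._result("A", -100, 3), self._result("B", -100, 3)])
        assert np.allclose(table["weight"], [0.5, 0.5])
        assert np.allclose(table["cum_weight"], [0.5, 1.0])

    def test_delta_two_point_four_one(self):
        # contrive AICc gap of exactly 2.41 via the log-likelihoods
        a = self._result("A", -100.0, 3)
        b = self._result("B", -100.0 - 2.41 / 2.0, 3)
        table = od.rank_models([a, b])
        assert table["dAICc"].iloc[1] == pytest.approx(2.41, abs=1e-12)
        assert table["weight"].iloc[0] == pytest.approx(0.769, abs=1e-3)
        assert table["weight"].iloc[1] == pytest.approx(0.231, abs=1e-3)

    def test_best_row_has_zero_delta_and_sorted(self):
        results = [self._result(f"M{i}", -100 - i * 1.7, 3) for i in range(5)]
        table = od.rank_models(results[::-1])
        assert table["dAICc"].iloc[0] == 0.0
        assert table["AICc"].is_monotonic_increasing
        assert table["cum_weight"].iloc[-1] == pytest.approx(1.0)

    def test_mixed_datasets_rejected(self):
        with pytest.raises(ValueError, match="different datasets"):
            od.rank_models(
                [self._result("A", -100, 3, data_hash=1),
                 self._result("B", -90, 3, data_hash=2)]
            )


class TestPredictDetection:
    def test_zero_coefficients_give_half(self):
        history = make_history([(1, 0), (0, 0), (1, 1)])
        result = od.fit("M2", history, seed=0)
        forced = FitResult(
            spec=result.spec,
            coef=np.zeros_like(result.coef),
            coef_names=result.coef_names,
            cov=np.eye(len(result.coef)) * 0.04,
            loglik=result.loglik,
            n_params=result.n_params,
            n_sites=result.n_sites,
            n_occasions_used=result.n_occasions_used,
            aicc=result.aicc,
            converged=True,
            boundary=False,
            data_hash=result.data_hash,
            methods=result.methods,
        )
        est = od.predict_detection(forced, "acoustic")
        assert est.estimate == pytest.approx(0.5)
        # symmetric on the link scale -> symmetric around 0.5 after expit
        assert est.upper - 0.5 == pytest.approx(0.5 - est.lower, abs=1e-12)

    def test_method_only_recovers_generating_probabilities(self):
        config = od.recovery_scenario(n_sites=300, k=14)
        history, _ = od.simulate_binned(config, seed=2, standardize=False)
        result = od.fit("M2", history, seed=0)
        truth = {"acoustic": 0.32, "drone": 0.28, "camera": 0.019}
        for method, p_true in truth.items():
            est = od.predict_detection(result, method)
            assert est.lower <= p_true <= est.upper

    def test_concave_down_quadratic_predicts_interior_peak(self, paper_history):
        history, _ = paper_history
        result = od.fit("M7", history, seed=0)
        p0 = od.predict_detection(result, "acoustic", {"temp_max": 0.0}).estimate
        p_lo = od.predict_detection(result, "acoustic", {"temp_max": -2.0}).estimate
        p_hi = od.predict_detection(result, "acoustic", {"temp_max": 2.0}).estimate
        quad = [c for n, c in zip(result.coef_names, result.coef)
                if n == "p:temp_max^2[acoustic]"][0]
        assert quad < 0
        assert p0 > p_lo
        assert p0 > p_hi

    def test_out_of_support_prediction_warns(self, m2_fit, paper_history):
        history, _ = paper_history
        result = od.fit("M6", history, seed=0)
        with pytest.warns(UserWarning, match="outside fitted support"):
            od.predict_detection(result, "acoustic", {"temp_max": 50.0})

    def test_psi_estimate_ci_nests_point(self, m2_fit):
        est, lo, hi = psi_estimate(m2_fit)
        assert 0 < lo <= est <= hi < 1
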