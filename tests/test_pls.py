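"""NIPALS PLS1, the 1% component rule, VIP scores and hold-out validation."""
import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from redflesh.pls import PREDICTORS, fit_pls1, prepare_design, validate, vip_scores
from redflesh.synthetic import generate_panel

# Frozen manual NIPALS trace of the 6×3 system below (z-score ddof=1, then
# w = Xᵀy/‖Xᵀy‖, t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflation), evaluated
# independently step by step with scalar arithmetic before the build.
X6 = np.array(
    [
        [1.0, 4.0, 2.0],
        [2.0, 1.0, 0.0],
        [3.0, 3.0, 1.0],
        [4.0, 2.0, 5.0],
        [5.0, 5.0, 4.0],
        [6.0, 0.0, 3.0],
    ]
)
Y6 = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
TRACE = {
    "w1": [0.80962642, 0.25126337, 0.53044489],
    "t1": [-1.02221729, -1.55944097, -0.57453088, 0.85806561, 1.41021217, 0.88791137],
    "p1": [0.72626307, 0.10188387, 0.7284424],
    "q1": 0.69902139,
    "r2_1": 0.71537828,
    "w2": [0.31859244, 0.57088854, -0.75669355],
    "q2": 0.77813572,
    "r2_2": 0.20837246,
    "yhat2": [2.1147952, 1.30044672, 3.51118545, 3.37879947, 6.48059485, 4.21417831],
    "vip2": [1.26158157, 0.60599316, 1.02038436],
}


class TestNipalsTrace:
    def test_matches_manual_six_by_three_trace(self):
        m = fit_pls1(X6, Y6, max_components=2, threshold=-1.0)
        assert m.n_components == 2
        assert m.weights[:, 0] == pytest.approx(TRACE["w1"], abs=1e-6)
        assert m.x_scores[:, 0] == pytest.approx(TRACE["t1"], abs=1e-6)
        assert m.x_loadings[:, 0] == pytest.approx(TRACE["p1"], abs=1e-6)
        assert m.y_loadings[0] == pytest.approx(TRACE["q1"], abs=1e-6)
        assert m.r2y_per_component == pytest.approx(
            [TRACE["r2_1"], TRACE["r2_2"]], abs=1e-6
        )
        assert m.weights[:, 1] == pytest.approx(TRACE["w2"], abs=1e-6)
        assert m.predict(X6) == pytest.approx(TRACE["yhat2"], abs=1e-6)
        assert m.vip == pytest.approx(TRACE["vip2"], abs=1e-6)

    def test_cross_check_against_sklearn(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20)
        ours = fit_pls1(X, y, max_components=3, threshold=-1.0)
        ref = PLSRegression(n_components=3, scale=True).fit(X, y)
        assert ours.predict(X) == pytest.approx(
            ref.predict(X).ravel(), abs=1e-8
        )


class TestComponentRule:
    def test_collinear_single_signal_gives_one_component(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(100, 4))
        y = 2.5 * X[:, 0]
        m = fit_pls1(X, y)
        assert m.n_components == 1
        assert m.r2y_cum > 0.99

    def test_at_least_one_component_retained(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)  # pure noise response
        assert fit_pls1(X, y).n_components >= 1

    def test_r2_increments_exceed_threshold(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ np.array([1.0, -0.5, 0.3, 0, 0, 0]) + 0.3 * rng.normal(size=40)
        m = fit_pls1(X, y, threshold=0.01)
        assert np.all(m.r2y_per_component[: m.n_components] > 0.01) or m.n_components == 1

    def test_scores_orthogonal_and_r2_cumulative(self, rng):
        X = rng.normal(size=(25, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=25)
        m = fit_pls1(X, y, max_components=4, threshold=-1.0)
        G = m.x_scores.T @ m.x_scores
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        assert np.all(m.r2y_per_component >= 0)
        assert m.r2y_cum <= 1 + 1e-9

    def test_single_predictor_equals_least_squares(self, rng):
        x = rng.normal(size=50)
        y = 3 * x + rng.normal(size=50)
        m = fit_pls1(x[:, None], y, max_components=1)
        slope, intercept = np.polyfit(x, y, 1)
        assert m.predict(x[:, None]) == pytest.approx(slope * x + intercept, abs=1e-8)

    def test_degenerate_inputs_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 4.2
        with pytest.raises(ValueError, match="1"):
            fit_pls1(X, rng.normal(size=20))
        with pytest.raises(ValueError, match="constant"):
            fit_pls1(rng.normal(size=(20, 3)), np.full(20, 1.0))


class TestVip:
    def test_single_predictor_vip_is_one(self, rng):
        x = rng.normal(size=30)
        m = fit_pls1(x[:, None], 2 * x + rng.normal(size=30), max_components=1)
        assert m.vip == pytest.approx([1.0])

    def test_sum_of_squares_equals_p(self, rng):
        for _ in range(10):
            n, p = int(rng.integers(15, 40)), int(rng.integers(2, 8))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            m = fit_pls1(X, y)
            assert (m.vip**2).sum() == pytest.approx(p, abs=1e-8)

    def test_lone_weighted_predictor_closed_form(self):
        # one component, all weight on predictor 1 of 4 → VIP = √(p·1) = 2
        class M:
            weights = np.array([[1.0], [0.0], [0.0], [0.0]])
            r2y_per_component = np.array([0.9])

        v = vip_scores(M())
        assert v == pytest.approx([2.0, 0.0, 0.0, 0.0])

    def test_equal_weights_give_unit_vip(self):
        class M:
            weights = np.full((4, 1), 0.5)
            r2y_per_component = np.array([0.6])

        assert vip_scores(M()) == pytest.approx([1.0] * 4)

    def test_unfitted_model_rejected(self):
        class Empty:
            weights = np.empty((0, 0))

        with pytest.raises(ValueError):
            vip_scores(Empty())

    def test_coefficient_signs_recover_generative_signs(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 4))
            beta = np.array([1.2, -0.8, 0.0, 0.0])
            y = X @ beta + 0.5 * rng.normal(size=100)
            m = fit_pls1(X, y)
            if m.coefficients[0] > 0 and m.coefficients[1] < 0:
                hits += 1
        assert hits == 100


class TestValidation:
    def test_noiseless_linear_response(self, rng):
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, 2.0, -1.0])
        rep = validate(X, y, seed=5, max_components=3, threshold=-1.0)
        assert rep.rmse_test < 1e-8
        assert rep.n_test == 12 and rep.n_train == 48

    def test_known_noise_level_recovered(self):
        rmses = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(300, 4))
            y = X @ np.array([2.0, -1.0, 0.5, 0.0]) + rng.normal(0, 2.0, 300)
            rmses.append(validate(X, y, seed=seed).rmse_test)
        assert np.mean(rmses) == pytest.approx(2.0, abs=0.1)

    def test_same_seed_is_deterministic(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ np.array([1.0, -1.0, 0.5]) + rng.normal(size=40)
        assert validate(X, y, seed=9) == validate(X, y, seed=9)

    def test_tiny_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            validate(rng.normal(size=(8, 2)), rng.normal(size=8))


class TestPrepareDesign:
    def test_aligned_panel_gives_91_by_7(self, panel):
        profiles, desc, _ = panel
        X, y = prepare_design(profiles, desc, response="a_mean")
        assert X.shape == (91, 7)
        assert tuple(X.columns) == PREDICTORS
        assert len(y) == 91

    def test_missing_value_drops_row(self, panel, caplog):
        profiles, desc, _ = panel
        profiles = profiles.copy()
        profiles.loc[profiles.index[3], "pH"] = np.nan
        X, y = prepare_design(profiles, desc, response="a_mean")
        assert X.shape == (90, 7)

    def test_row_order_invariance(self, panel):
        profiles, desc, _ = panel
        shuffled = profiles.sample(frac=1.0, random_state=0)
        X1, y1 = prepare_design(profiles, desc, response="hue_deg")
        X2, y2 = prepare_design(shuffled, desc, response="hue_deg")
        pd.testing.assert_frame_equal(X1.sort_index(), X2.sort_index())
        pd.testing.assert_series_equal(y1.sort_index(), y2.sort_index())

    def test_disjoint_genotypes_rejected(self, panel):
        profiles, desc, _ = panel
        bad = profiles.copy()
        bad["genotype_id"] = "X" + bad["genotype_id"]
        with pytest.raises(ValueError):
            prepare_design(bad, desc)

    def test_anthocyanins_enter_on_log_scale(self, panel):
        profiles, desc, _ = panel
        X, _ = prepare_design(profiles, desc)
        assert X["log_anthocyanins"].to_numpy() == pytest.approx(
            np.log(profiles.set_index("genotype_id").loc[X.index, "anthocyanins"])
        )
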