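"""Unit tests for pseudo-absence generation, SDM fitting, and skill metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree
from scipy.special import expit

from ricascade.grid import EnvGrid, OccurrenceSet
from ricascade.sdm import (
    EvaluationError,
    FitError,
    SamplingError,
    evaluate_auc,
    evaluate_tss,
    fit_sdm,
    generate_pseudo_absences,
    predict_surface,
    relative_intensity,
    SDMFit,
)
from ricascade.synth import make_environment, simulate_occurrences


@pytest.fixture(scope="module")
def presences(scenario_module=None):
    from ricascade.config import default_scenario
    sc = default_scenario(rng_seed=5)
    env = make_environment(sc)
    return sc, env, simulate_occurrences(sc, env, "species_3")


class TestPseudoAbsences:
    def test_ratio_controls_count(self, presences):
        _, env, pres = presences
        absences = generate_pseudo_absences(pres, env, ratio=4, rng_seed=0)
        assert len(absences) == 4 * len(pres)

    def test_every_absence_outside_buffer(self, presences):
        _, env, pres = presences
        buffer = 0.05
        absences = generate_pseudo_absences(pres, env, buffer_deg=buffer, rng_seed=1)
        dist, _ = cKDTree(pres.points).query(absences.points, k=1)
        assert dist.min() > buffer

    def test_zero_buffer_excludes_only_presence_cells(self, presences):
        _, env, pres = presences
        absences = generate_pseudo_absences(pres, env, buffer_deg=0.0, rng_seed=2)
        presence_cells = {env.cell_of(*p) for p in pres.points}
        absence_cells = {env.cell_of(*p) for p in absences.points}
        assert not (absence_cells & presence_cells)
        dist, _ = cKDTree(pres.points).query(absences.points, k=1)
        assert dist.min() > 0

    def test_shortfall_reported(self, presences):
        _, env, pres = presences
        with pytest.raises(SamplingError, match="short"):
            generate_pseudo_absences(pres, env, buffer_deg=10.0, rng_seed=0)


class TestAUC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((0.9, 0.8), (1, 0), 1.0),
            ((0.5, 0.5), (1, 0), 0.5),
            # 4 presence-absence pairs: 3 concordant, 1 discordant -> 0.75
            ((0.2, 0.4, 0.6, 0.8), (0, 1, 0, 1), 0.75),
        ],
    )
    def test_known_rankings(self, scores, labels, expected):
        assert evaluate_auc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            evaluate_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=30))
    def test_invariant_under_monotone_transform(self, raw):
        rng = np.random.default_rng(0)
        scores = np.asarray(raw)
        labels = rng.integers(0, 2, size=len(scores))
        if len(np.unique(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        before = evaluate_auc(scores, labels)
        # strictly increasing transform that cannot collapse distinct floats
        after = evaluate_auc(4.0 * scores, labels)
        assert after == pytest.approx(before)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(42)
        scores = rng.uniform(size=200)
        labels = np.array([0] * 100 + [1] * 100)
        aucs = []
        for _ in range(200):
            aucs.append(evaluate_auc(scores, rng.permutation(labels)))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


class TestTSS:
    def test_perfect_separation_gives_one(self):
        tss, thr = evaluate_tss(np.array([0.1, 0.4, 0.6, 0.9]), np.array([0, 0, 1, 1]))
        assert tss == pytest.approx(1.0)
        assert thr == pytest.approx(0.5)

    def test_identical_scores_give_zero(self):
        tss, _ = evaluate_tss(np.array([0.3, 0.3, 0.3]), np.array([0, 1, 1]))
        assert tss == pytest.approx(0.0)

    def test_bounded_and_one_iff_separable(self):
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[0], labels[1] = 0, 1
        tss, _ = evaluate_tss(scores, labels)
        assert -1.0 <= tss <= 1.0


class TestFitSDM:
    def test_separable_predictor_yields_perfect_test_auc(self):
        env = _toy_env()
        pres = OccurrenceSet("sp", _points_in_rows(env, rows=range(0, 4), n=40), "presence")
        abse = OccurrenceSet("sp", _points_in_rows(env, rows=range(8, 12), n=40), "pseudo_absence")
        fit = fit_sdm(pres, abse, env, rng_seed=0)
        assert fit.auc == pytest.approx(1.0)
        assert fit.tss == pytest.approx(1.0)

    def test_coefficient_sign_matches_monotone_likelihood(self):
        # presences strictly higher on the gradient than absences -> positive slope
        env = _toy_env()
        pres = OccurrenceSet("sp", _points_in_rows(env, rows=range(0, 4), n=40), "presence")
        abse = OccurrenceSet("sp", _points_in_rows(env, rows=range(8, 12), n=40), "pseudo_absence")
        fit = fit_sdm(pres, abse, env, predictors=["grad"], rng_seed=0)
        assert fit.coefficients["grad"] > 0  # grad is higher in northern rows

    def test_zero_variance_predictor_rejected(self):
        env = _toy_env()
        env.layers["flat"] = np.ones(env.shape)
        pres = OccurrenceSet("sp", _points_in_rows(env, rows=range(0, 6), n=30), "presence")
        abse = OccurrenceSet("sp", _points_in_rows(env, rows=range(6, 12), n=30), "pseudo_absence")
        with pytest.raises(FitError, match="zero variance"):
            fit_sdm(pres, abse, env, predictors=["flat"], rng_seed=0)


class TestPredictSurface:
    def test_zero_coefficients_give_half_everywhere(self):
        env = _toy_env()
        fit = SDMFit("sp", intercept=0.0, coefficients={"grad": 0.0},
                     predictor_names=["grad"])
        surf = predict_surface(fit, env)
        np.testing.assert_allclose(surf.values[env.mask], 0.5)

    def test_saturating_intercept(self):
        env = _toy_env()
        fit = SDMFit("sp", intercept=50.0, coefficients={"grad": 0.0},
                     predictor_names=["grad"])
        surf = predict_surface(fit, env)
        np.testing.assert_allclose(surf.values[env.mask], 1.0, atol=1e-9)

    def test_cells_match_manual_inverse_logit(self):
        env = _toy_env()
        fit = SDMFit("sp", intercept=-1.0, coefficients={"grad": 0.3},
                     predictor_names=["grad"])
        surf = predict_surface(fit, env)
        for r, c in [(0, 0), (5, 3), (11, 7)]:
            expected = expit(-1.0 + 0.3 * env.layers["grad"][r, c])
            assert surf.values[r, c] == pytest.approx(expected)

    def test_missing_layer_rejected(self):
        env = _toy_env()
        fit = SDMFit("sp", 0.0, {"ghost": 1.0}, predictor_names=["ghost"])
        with pytest.raises(KeyError):
            predict_surface(fit, env)

    def test_intensity_is_monotone_in_linear_predictor(self):
        env = _toy_env()
        fit = SDMFit("sp", intercept=-1.0, coefficients={"grad": 0.3},
                     predictor_names=["grad"])
        prob = predict_surface(fit, env).values[env.mask]
        inten = relative_intensity(fit, env).values[env.mask]
        assert np.nanmax(inten) == pytest.approx(1.0)
        # same ranking on both scales
        assert np.array_equal(np.argsort(prob), np.argsort(inten))


def _toy_env() -> EnvGrid:
    """12 x 8 grid with one north-south gradient layer."""
    n_rows, n_cols = 12, 8
    extent = (0.0, n_cols * 0.1, 0.0, n_rows * 0.1)
    mask = np.ones((n_rows, n_cols), dtype=bool)
    grad = np.repeat(np.linspace(100, 0, n_rows)[:, None], n_cols, axis=1)
    return EnvGrid(extent, 0.1, {"grad": grad}, mask)


def _points_in_rows(env: EnvGrid, rows, n: int) -> np.ndarray:
    rng = np.random.default_rng(0)
    lons, lats = env.cell_centers()
    rows = list(rows)
    pts = []
    for i in range(n):
        r = rows[i % len(rows)]
        c = rng.integers(0, env.n_cols)
        pts.append((lons[r, c], lats[r, c]))
    return np.array(pts)
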