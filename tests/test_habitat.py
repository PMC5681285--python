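"""Habitat GLM, threshold selection, confusion statistics, areas."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from sedigrass import (
    SeagrassHabitatModel,
    confusion_stats,
    fit_sdm,
    habitat_area,
    predict_probability,
    reference,
    select_threshold,
)
from sedigrass.habitat import THRESHOLD_CRITERIA, THRESHOLD_GRID

REF = reference.HABITAT_REFERENCE


def brute_force_threshold(obs, prob, criterion):
    """Exhaustive oracle over the same grid, written independently."""
    best_thr, best_score = None, None
    for thr in THRESHOLD_GRID:
        pred = (np.asarray(prob) >= thr).astype(int)
        tp = int(((obs == 1) & (pred == 1)).sum())
        fp = int(((obs == 0) & (pred == 1)).sum())
        tn = int(((obs == 0) & (pred == 0)).sum())
        fn = int(((obs == 1) & (pred == 0)).sum())
        n = len(obs)
        if criterion == "kappa":
            po = (tp + tn) / n
            pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
            score = 0.0 if pe == 1 else (po - pe) / (1 - pe)
        elif criterion == "maxPC":
            score = (tp + tn) / n
        elif criterion == "sens_spec":
            sens = tp / (tp + fn) if tp + fn else np.nan
            spec = tn / (tn + fp) if tn + fp else np.nan
            score = -abs(sens - spec)
        if best_score is None or score > best_score + 1e-12:
            best_thr, best_score = thr, score
    return float(best_thr)


class TestPrediction:
    def test_logistic_midpoint(self):
        model = SeagrassHabitatModel.from_coefficients(
            {"intercept": 0.0, "light": 0.0, "waves": 0.0, "waves_x_light": 0.0}
        )
        assert model.predict_proba([[3.0, 0.5]])[0, 1] == pytest.approx(0.5)

    def test_reference_intercept_probability(self):
        model = SeagrassHabitatModel.from_coefficients(REF)
        p = model.predict_proba([[0.0, 0.0]])[0, 1]
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-2.28)), abs=1e-6)

    def test_monotone_in_light_when_calm(self):
        model = SeagrassHabitatModel.from_coefficients(REF)
        L = np.linspace(-5, 4.6, 40)
        p = model.predict_proba(np.column_stack([L, np.zeros_like(L)]))[:, 1]
        assert (np.diff(p) > 0).all()

    def test_interaction_reverses_light_effect_in_heavy_waves(self):
        # conditional monotonicity: light helps below Hs = b_L/|b_HL| (~0.904 m)
        # and hurts above it
        model = SeagrassHabitatModel.from_coefficients(REF)
        pivot = REF["light"] / abs(REF["waves_x_light"])
        L = np.linspace(-5, 4.6, 40)
        for hs, increasing in [(pivot - 0.2, True), (pivot + 0.2, False)]:
            p = model.predict_proba(np.column_stack([L, np.full_like(L, hs)]))[:, 1]
            assert (np.diff(p) > 0).all() == increasing

    def test_raster_prediction_masks_land(self):
        model = SeagrassHabitatModel.from_coefficients(REF)
        L = np.array([[1.0, np.nan], [2.0, 3.0]])
        hs = np.zeros((2, 2))
        p = predict_probability(model, L, hs)
        assert np.isnan(p[0, 1])
        assert np.isfinite(p[1]).all()
        with pytest.raises(ValueError, match="shape"):
            predict_probability(model, L, np.zeros((3, 2)))


class TestFit:
    def test_single_class_rejected(self):
        L = np.random.default_rng(0).normal(size=(5, 5))
        with pytest.raises(ValueError, match="presence and absence"):
            fit_sdm(np.ones((5, 5)), L, np.zeros((5, 5)))

    def test_recovery_on_sampled_map(self):
        rng = np.random.default_rng(21)
        n = 5000
        L = rng.uniform(-6, 4.6, n)
        hs = rng.uniform(0, 0.9, n)
        g = (REF["intercept"] + REF["light"] * L + REF["waves"] * hs
             + REF["waves_x_light"] * hs * L)
        y = (rng.random(n) < 1 / (1 + np.exp(-g))).astype(float)
        model = SeagrassHabitatModel().fit(np.column_stack([L, hs]), y)
        got = model.coefficients()
        # every coefficient within 3 standard errors of its truth
        truth = [REF["intercept"], REF["light"], REF["waves"], REF["waves_x_light"]]
        est = [got["intercept"], got["light"], got["waves"], got["waves_x_light"]]
        for t, e, se in zip(truth, est, model.bse_):
            assert abs(e - t) < 3 * se


class TestThresholdSelection:
    def test_separable_case_tie_breaks_small(self):
        obs = np.array([0, 0, 0, 1, 1, 1])
        prob = np.array([0.1, 0.15, 0.2, 0.8, 0.9, 0.95])
        # any threshold in (0.2, 0.8] classifies perfectly; smallest grid value wins
        assert select_threshold(obs, prob, "kappa") == pytest.approx(0.21)

    def test_default_ignores_data(self):
        obs = np.array([0, 1, 1, 1])
        prob = np.array([0.9, 0.1, 0.2, 0.3])
        assert select_threshold(obs, prob, "default") == 0.5

    def test_unknown_criterion(self):
        with pytest.raises(ValueError, match="criterion"):
            select_threshold(np.array([0, 1]), np.array([0.2, 0.8]), "youden")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            select_threshold(np.ones(4), np.linspace(0, 1, 4), "kappa")

    def test_spec_example_vector(self):
        obs = np.array([0, 0, 1, 1])
        prob = np.array([0.1, 0.4, 0.6, 0.9])
        for criterion in THRESHOLD_CRITERIA:
            got = select_threshold(obs, prob, criterion)
            if criterion == "default":
                assert got == 0.5
            else:
                assert got == pytest.approx(brute_force_threshold(obs, prob, criterion))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_exhaustive_oracle(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = rng.integers(10, 200)
        obs = (rng.random(n) < 0.5).astype(int)
        if obs.min() == obs.max():
            obs[0] = 1 - obs[0]
        prob = np.round(rng.random(n), 3)
        for criterion in ("kappa", "maxPC", "sens_spec"):
            assert select_threshold(obs, prob, criterion) == pytest.approx(
                brute_force_threshold(obs, prob, criterion)
            )


class TestConfusion:
    def test_perfect_agreement(self):
        obs = np.array([1, 0, 1, 1, 0])
        s = confusion_stats(obs, obs)
        assert s.pcc == 1.0 and s.kappa == 1.0

    def test_hand_computed_example(self):
        s = confusion_stats([1, 1, 0, 0], [1, 0, 0, 0])
        assert s.pcc == pytest.approx(0.75)
        assert s.sensitivity == pytest.approx(0.5)
        assert s.specificity == pytest.approx(1.0)
        # p_o = 0.75, p_e = 0.5 -> kappa = 0.5
        assert s.kappa == pytest.approx(0.5)

    def test_constant_prediction_scores_zero_kappa(self):
        s = confusion_stats([1, 0, 1, 0], [1, 1, 1, 1])
        assert s.kappa == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion_stats([0, 1], [0, 1, 1])

    @pytest.mark.parametrize("trial", range(10))
    def test_kappa_matches_sklearn(self, trial):
        rng = np.random.default_rng(2000 + trial)
        obs = (rng.random(100) < 0.4).astype(int)
        pred = (rng.random(100) < 0.6).astype(int)
        s = confusion_stats(obs, pred)
        assert s.kappa == pytest.approx(cohen_kappa_score(obs, pred))
        assert -1.0 <= s.kappa <= 1.0


class TestArea:
    def test_counting(self):
        prob = np.full((2, 5), 0.3)
        assert habitat_area(prob, 0.22, cell_area_ha=1.0) == 10.0
        assert habitat_area(np.zeros((3, 3)), 0.22) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(5)
        prob = rng.random((20, 20))
        areas = [habitat_area(prob, t) for t in (0.11, 0.22, 0.44, 0.5)]
        assert areas == sorted(areas, reverse=True)

    def test_threshold_domain(self):
        with pytest.raises(ValueError):
            habitat_area(np.zeros((2, 2)), 0.0)
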