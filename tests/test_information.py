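import numpy as np
import pytest

from grmkit import (
    ItemBank,
    ItemParameters,
    ThetaGrid,
    ValidationError,
    category_prob,
    eap_scores,
    information_summary,
    item_information,
    max_information,
    occ_table,
)
from grmkit.information import (
    test_information as bank_information,
    test_information_table as bank_information_table,
)
from grmkit.simulate import SimulationConfig, simulate_responses

# EDANX53's information curve has two near-equal peaks (at its first and
# second thresholds); which one wins flips under two-decimal rounding of the
# stored parameters, so its reported theta location is excluded from the
# location regression while both magnitudes are still checked.
NEAR_TIE_ITEMS = {"EDANX53"}


class TestItemInformation:
    def test_reproduces_published_information_table(self, default_bank, published_information):
        """46-cell regression: the packaged parameters reproduce the published
        per-item information summary to parameter-rounding accuracy."""
        for it in default_bank:
            row = published_information.loc[it.item_id]
            mi, th = max_information(it)
            assert mi == pytest.approx(row["max_info"], abs=0.05), it.item_id
            assert item_information(it, 0.0) == pytest.approx(row["info_at_zero"], abs=0.05), it.item_id
            if it.item_id not in NEAR_TIE_ITEMS:
                assert th == pytest.approx(row["theta_at_max"], abs=0.1 + 1e-9), it.item_id

    def test_dichotomous_item_peaks_at_a_squared_over_four(self):
        it = ItemParameters("x", a=1.7, b=(0.3,))
        assert item_information(it, 0.3) == pytest.approx(1.7**2 / 4, rel=1e-12)

    def test_matches_finite_difference_fisher_definition(self, default_bank, rng):
        """Oracle: Fisher information as the negative expected second
        derivative of the log category likelihood, by central differences."""
        h = 1e-5
        for _ in range(20):
            it = default_bank[int(rng.integers(0, 23))]
            theta = float(rng.uniform(-3.5, 3.5))
            p0 = category_prob(it, theta)
            lp = lambda t: np.log(category_prob(it, t))
            d2 = (lp(theta + h) - 2 * lp(theta) + lp(theta - h)) / h**2
            expected = -(p0 * d2).sum()
            assert item_information(it, theta) == pytest.approx(expected, abs=1e-4)

    def test_information_nonnegative_on_grid(self, default_bank):
        grid = np.linspace(-6, 6, 241)
        for it in default_bank:
            assert np.all(item_information(it, grid) >= 0)

    def test_symmetric_item_has_even_information_curve(self):
        it = ItemParameters("sym", a=2.0, b=(-1.0, 0.0, 1.0))
        grid = np.linspace(-4, 4, 81)
        info = item_information(it, grid)
        assert np.allclose(info, info[::-1], atol=1e-12)


class TestMaxInformation:
    def test_anchor_items(self, default_bank):
        mi5, th5 = max_information(default_bank["EDANX05"])
        assert mi5 == pytest.approx(7.49, abs=0.05)
        assert th5 == pytest.approx(-2.3, abs=0.1 + 1e-9)
        mi47, _ = max_information(default_bank["EDANX47"])
        assert mi47 == pytest.approx(1.38, abs=0.05)

    def test_grid_convention_one_decimal(self, default_bank):
        for it in default_bank:
            _, th = max_information(it)
            assert round(th, 1) == pytest.approx(th, abs=1e-9)


class TestTestInformation:
    def test_study_bank_total_at_zero(self, default_bank):
        assert bank_information(default_bank, 0.0) == pytest.approx(63.427, abs=0.5)

    def test_single_item_bank_additivity(self, default_bank):
        it = default_bank[0]
        solo = ItemBank(items=(it,), K=5)
        grid = np.linspace(-3, 3, 13)
        assert np.allclose(bank_information(solo, grid), item_information(it, grid))

    def test_dominates_every_item(self, default_bank):
        grid = np.linspace(-4, 4, 81)
        total = bank_information(default_bank, grid)
        for it in default_bank:
            assert np.all(total >= item_information(it, grid) - 1e-12)

    def test_table_reports_conditional_se(self, default_bank):
        tab = bank_information_table(default_bank)
        t = tab.columns["information"]
        assert np.allclose(tab.columns["se"], 1 / np.sqrt(t))


class TestOCC:
    def test_rows_sum_to_one(self, default_bank):
        tab = occ_table(default_bank["EDANX27"])
        probs = np.column_stack([tab.columns[f"P{k}"] for k in range(1, 6)])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert probs.min() >= 0

    def test_middle_category_modal_at_center_for_steep_item(self, default_bank):
        it = default_bank["EDANX05"]
        p = category_prob(it, 0.0)
        assert np.argmax(p) == 2  # category 3
        assert p[2] == pytest.approx(0.566, abs=0.01)
        tab = occ_table(it)
        at_zero = np.argmin(np.abs(tab.theta))
        assert tab.columns["modal_category"][at_zero] == 3

    def test_steeper_discrimination_steeper_curves(self):
        lo = ItemParameters("lo", a=1.0, b=(0.0,))
        hi = ItemParameters("hi", a=4.0, b=(0.0,))
        grid = np.linspace(-2, 2, 401)
        slope = lambda it: np.max(np.abs(np.diff(category_prob(it, grid)[:, 1])))
        assert slope(hi) > slope(lo)


class TestEAPScores:
    def test_extreme_patterns_order(self, default_bank):
        lo = np.full((2, 23), 1.0)
        hi = np.full((2, 23), 5.0)
        assert eap_scores(default_bank, lo)["eap_theta"].iloc[0] < 0
        assert eap_scores(default_bank, hi)["eap_theta"].iloc[0] > 0

    def test_posterior_sd_below_prior_sd(self, study_sim, default_bank):
        responses, _ = study_sim
        scores = eap_scores(default_bank, responses.values[:200])
        assert (scores["posterior_sd"] < 1.0).all()

    def test_shrinkage_is_mild_for_informative_bank(self, default_bank):
        config = SimulationConfig(n=400, seed=77, bank=default_bank,
                                  theta_mean=1.0, theta_sd=0.0, covariate_spec={})
        rm, _ = simulate_responses(config)
        mean_eap = eap_scores(default_bank, rm)["eap_theta"].mean()
        assert 0.8 < mean_eap < 1.0

    def test_unanswered_person_reported_missing(self, default_bank):
        vals = np.full((2, 23), np.nan)
        vals[1] = 3.0
        scores = eap_scores(default_bank, vals)
        assert np.isnan(scores["eap_theta"].iloc[0])
        assert np.isfinite(scores["eap_theta"].iloc[1])

    def test_posterior_sd_tracks_information_near_center(self, study_sim, default_bank):
        """1/sqrt(T(theta_hat)) approximates the posterior SD for persons
        near the bank's center."""
        responses, _ = study_sim
        scores = eap_scores(default_bank, responses.values)
        central = scores[np.abs(scores["eap_theta"]) < 1.0]
        approx = 1 / np.sqrt(bank_information(default_bank, central["eap_theta"].to_numpy()))
        rel = np.abs(central["posterior_sd"].to_numpy() - approx) / approx
        assert np.median(rel) < 0.15


class TestInformationSummary:
    def test_high_information_count_and_window(self, default_bank):
        s = information_summary(default_bank)
        assert s["n_high_information"] == 10
        lo, hi = s["high_theta_window"]
        assert -2.5 <= lo <= hi <= 2.5

    def test_extreme_item_values(self, default_bank):
        s = information_summary(default_bank)
        assert 7.44 <= s["table"]["max_info"].max() <= 7.54
        assert 1.33 <= s["table"]["max_info"].min() <= 1.43
        assert (s["table"]["max_info"] >= s["table"]["info_at_zero"] - 1e-12).all()

    def test_empty_bank_is_an_error(self):
        bank = ItemBank(items=(), K=5)
        with pytest.raises(ValidationError, match="empty"):
            information_summary(bank)
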