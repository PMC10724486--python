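import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grmkit import (
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    ThetaGrid,
    boundary_prob,
    category_prob,
    fit_grm,
    log_likelihood,
    screen_items,
)
from grmkit.fitstats import fit_indices
from grmkit.grm import GradedResponseModel
from grmkit.simulate import SimulationConfig, simulate_responses

item_strategy = st.builds(
    lambda a, b0, gaps: ItemParameters(
        "x", a=a, b=tuple(np.cumsum([b0] + gaps))),
    a=st.floats(0.2, 8.0),
    b0=st.floats(-3.5, 0.0),
    gaps=st.lists(st.floats(0.2, 2.0), min_size=1, max_size=4),
)


class TestProbabilities:
    def test_boundary_prob_is_half_at_threshold(self, default_bank):
        for it in default_bank:
            for k, b in enumerate(it.b):
                assert boundary_prob(it, b)[k] == pytest.approx(0.5, abs=1e-12)

    def test_high_discrimination_anchor_value(self, default_bank):
        """Direct evaluation of the logistic boundary for the steepest item:
        P*_3(0) = 1 / (1 + exp(5.47 * 0.05))."""
        it = default_bank["EDANX05"]
        assert boundary_prob(it, 0.0)[2] == pytest.approx(1 / (1 + np.exp(0.2735)), abs=1e-12)

    def test_large_a_approaches_step_function(self):
        it = ItemParameters("x", a=200.0, b=(0.0,))
        assert boundary_prob(it, -0.1)[0] < 1e-8
        assert boundary_prob(it, 0.1)[0] > 1 - 1e-8

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(item=item_strategy, theta=st.floats(-6, 6))
    def test_category_probs_form_a_distribution(self, item, theta):
        pstar = boundary_prob(item, theta)
        assert np.all(np.diff(pstar) <= 1e-12)  # boundary curves are ordered
        p = category_prob(item, theta)
        assert np.all(p >= -1e-15)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_extremes(self, default_bank):
        it = default_bank[0]
        assert category_prob(it, -30.0)[0] == pytest.approx(1.0, abs=1e-10)
        assert category_prob(it, 30.0)[-1] == pytest.approx(1.0, abs=1e-10)

    def test_every_category_is_modal_somewhere(self, default_bank):
        grid = np.arange(-4, 4.01, 0.05)
        for it in default_bank:
            modal = np.argmax(category_prob(it, grid), axis=1)
            assert set(modal) == set(range(5)), it.item_id


class TestLogLikelihood:
    def test_single_person_hand_computed(self):
        """One person, one item, flat two-node prior: the marginal likelihood
        is a plain weighted sum computable by hand."""
        it = ItemParameters("x", a=1.5, b=(-0.5, 0.8))
        bank = ItemBank(items=(it,), K=3)
        prior = ThetaGrid(nodes=np.array([-1.0, 1.0]), weights=np.array([0.5, 0.5]))
        values = np.array([[2.0], [2.0]])  # container requires n >= 2
        p_at = lambda t: category_prob(it, t)[1]
        expected = 2 * np.log(0.5 * p_at(-1.0) + 0.5 * p_at(1.0))
        assert log_likelihood(bank, values, prior) == pytest.approx(expected, rel=1e-12)

    def test_missing_item_leaves_loglik_unchanged(self, default_bank, rng):
        config = SimulationConfig(n=100, seed=5, bank=default_bank, covariate_spec={})
        rm, _ = simulate_responses(config)
        base = log_likelihood(default_bank, rm)
        extra = ItemParameters("new", a=2.0, b=(-1.0, 0.0, 0.5, 1.0))
        bank2 = ItemBank(items=default_bank.items + (extra,), K=5)
        vals2 = np.column_stack([rm.values, np.full(100, np.nan)])
        assert log_likelihood(bank2, vals2) == pytest.approx(base, rel=1e-12)

    def test_true_parameters_beat_perturbed_on_average(self, default_bank):
        diffs = []
        for seed in range(5):
            config = SimulationConfig(n=300, seed=seed, bank=default_bank, covariate_spec={})
            rm, _ = simulate_responses(config)
            items = tuple(ItemParameters(it.item_id, it.a * 1.5, it.b, it.wording)
                          for it in default_bank)
            perturbed = ItemBank(items=items, K=5)
            diffs.append(log_likelihood(default_bank, rm) - log_likelihood(perturbed, rm))
        assert np.mean(diffs) > 0


class TestCalibration:
    def test_em_trace_is_monotone(self, study_calibration):
        assert np.all(np.diff(study_calibration.trace_) > -1e-8)

    def test_parameter_recovery_study_scale(self, study_calibration, default_bank):
        """Most items' discriminations land within 15% and central thresholds
        within 0.15 of the generating values at the study sample size."""
        est = study_calibration.bank_
        n_ok = 0
        for it_true, it_est in zip(default_bank, est):
            rel_a = abs(it_est.a - it_true.a) / it_true.a
            central = [abs(be - bt) for be, bt in zip(it_est.b, it_true.b) if abs(bt) < 2]
            n_ok += rel_a < 0.15 and all(d < 0.15 for d in central)
        assert n_ok >= 20

    def test_bias_shrinks_with_sample_size(self, default_bank):
        """Consistency: errors at n = 8000 are smaller than at n = 800 for a
        five-item sub-bank."""
        sub = default_bank.subset(["EDANX27", "EDANX47", "EDANX30", "EDANX08", "EDANX51"])
        err = {}
        for n in (800, 8000):
            rm, _ = simulate_responses(SimulationConfig(n=n, seed=42, bank=sub, covariate_spec={}))
            calib = fit_grm(rm)
            err[n] = np.sqrt(np.mean((calib.bank.discriminations() - sub.discriminations()) ** 2
                                     / sub.discriminations() ** 2))
        assert err[8000] < err[800]

    def test_below_minimum_sample_refused(self, default_bank):
        rm, _ = simulate_responses(SimulationConfig(n=10, seed=1, bank=default_bank,
                                                    covariate_spec={}))
        with pytest.raises(Exception, match="minimum"):
            GradedResponseModel(min_persons=100).fit(rm)

    def test_empty_category_collapsed_with_logged_remap(self, rng):
        it = ItemParameters("x", a=2.0, b=(-1.0, 0.0, 1.0, 2.0))
        bank = ItemBank(items=(it, ItemParameters("y", a=2.0, b=(-1.5, -0.5, 0.5, 1.5))), K=5)
        rm, _ = simulate_responses(SimulationConfig(n=400, seed=3, bank=bank, covariate_spec={}))
        vals = rm.values.copy()
        vals[vals[:, 0] == 5, 0] = 4  # category 5 never observed for item x
        with pytest.warns(UserWarning, match="did not converge"):
            model = GradedResponseModel(min_persons=100, max_cycles=50).fit(vals)
        assert "item1" in model.result_.category_maps
        assert model.result_.category_maps["item1"][5] == 4

    def test_transform_returns_eap_scores(self, study_calibration, study_sim):
        responses, theta = study_sim
        scores = study_calibration.transform(responses.values[:50])
        assert scores.shape == (50, 2)
        assert np.all(scores[:, 1] > 0)

    def test_sklearn_param_interface(self):
        model = GradedResponseModel(tol=1e-3)
        assert model.get_params()["tol"] == 1e-3
        model.set_params(max_cycles=7)
        assert model.max_cycles == 7


class TestScreening:
    def test_default_bank_passes_discrimination_and_location_rules(self, default_bank):
        rep = screen_items(default_bank)
        assert rep.table["a_ok"].all()
        assert rep.table["b_ok"].all()

    def test_exactly_one_narrow_interval(self, default_bank):
        """Only the first interval of EDANX09 falls below 0.81 (it is 0.74
        exactly, by subtraction of the stored thresholds)."""
        rep = screen_items(default_bank)
        flagged = rep.flagged_intervals
        assert len(flagged) == 1
        item_id, which, value = flagged[0]
        assert (item_id, which) == ("EDANX09", "b2_b1")
        assert value == pytest.approx(0.74, abs=1e-9)

    def test_weak_item_flagged(self):
        it = ItemParameters("weak", a=0.3, b=(-1.0, 0.0, 1.0, 2.0))
        rep = screen_items(ItemBank(items=(it,), K=5))
        assert not rep.table.loc["weak", "a_ok"]

    def test_intervals_are_exact_differences(self, default_bank):
        rep = screen_items(default_bank)
        for it in default_bank:
            for k, iv in enumerate(it.intervals):
                assert rep.table.loc[it.item_id, f"interval_b{k + 2}_b{k + 1}"] == iv


class TestFitIndices:
    SUB = ["EDANX27", "EDANX47", "EDANX30", "EDANX08", "EDANX51"]

    def test_correctly_specified_model_fits_well(self, default_bank):
        """Data simulated from the calibrated model itself: RMSEA stays at or
        below 0.05 in nearly all replicates."""
        sub = default_bank.subset(self.SUB)
        good = 0
        for seed in range(6):
            rm, _ = simulate_responses(SimulationConfig(n=800, seed=seed, bank=sub,
                                                        covariate_spec={}))
            calib = fit_grm(rm)
            fi = fit_indices(rm, calib.bank)
            good += fi.rmsea <= 0.05
        assert good >= 5

    def test_misspecification_increases_rmsea(self, default_bank, rng):
        from grmkit.grm import boundary_prob

        sub = default_bank.subset(self.SUB)
        rm_good, _ = simulate_responses(SimulationConfig(n=800, seed=11, bank=sub,
                                                         covariate_spec={}))
        fi_good = fit_indices(rm_good, fit_grm(rm_good).bank)
        n = 800
        th = rng.normal(size=(n, 2))
        vals = np.empty((n, 5))
        for j, it in enumerate(sub):
            t = th[:, 0] if j < 3 else th[:, 1]
            u = rng.random(n)
            vals[:, j] = 1 + (u[:, None] < boundary_prob(it, t)).sum(axis=1)
        rm_bad = ResponseMatrix(values=vals, item_ids=sub.item_ids, K=5)
        fi_bad = fit_indices(rm_bad, fit_grm(rm_bad).bank)
        assert fi_bad.rmsea > fi_good.rmsea
        assert fi_bad.cfi < fi_good.cfi

    def test_degrees_of_freedom_bookkeeping(self, default_bank):
        sub = default_bank.subset(self.SUB)
        rm, _ = simulate_responses(SimulationConfig(n=900, seed=2, bank=sub, covariate_spec={}))
        fi = fit_indices(rm, sub)
        # 5 items: 20 univariate + 160 bivariate moments, 25 free parameters
        assert fi.df == 180 - 25
        assert fi.df_baseline == 180 - 20
        assert fi.rmsea >= 0 and fi.cfi <= 1
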