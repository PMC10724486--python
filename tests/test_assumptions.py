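import numpy as np
import pytest

from grmkit import (
    ResponseMatrix,
    ValidationError,
    assumption_report,
    bartlett_sphericity,
    eigenvalue_ratio,
    kmo_statistic,
    load_default_bank,
    monotonicity_curves,
    residual_correlations,
)
from grmkit.simulate import SimulationConfig, simulate_responses


def _rm(values, K=5):
    values = np.asarray(values, dtype=float)
    return ResponseMatrix(values=values, item_ids=[f"i{j}" for j in range(values.shape[1])], K=K)


class TestKMO:
    def test_matches_textbook_formula_on_random_case(self, rng):
        """Independent oracle: evaluate the KMO definition directly from the
        correlation matrix and its inverse on a random 4-variable dataset."""
        x = rng.normal(size=(300, 4)) @ rng.normal(size=(4, 4))
        vals = np.clip(np.round(3 + x / np.abs(x).max() * 2), 1, 5)
        rm = _rm(vals)
        r = np.corrcoef(vals, rowvar=False)
        rinv = np.linalg.inv(r)
        q = -rinv / np.sqrt(np.outer(np.diag(rinv), np.diag(rinv)))
        off = ~np.eye(4, dtype=bool)
        expected = (r[off] ** 2).sum() / ((r[off] ** 2).sum() + (q[off] ** 2).sum())
        assert kmo_statistic(rm) == pytest.approx(expected, abs=1e-12)

    def test_uncorrelated_items_sit_near_half(self, rng):
        rm = _rm(rng.integers(1, 6, size=(4000, 2)))
        assert kmo_statistic(rm) == pytest.approx(0.5, abs=0.02)

    def test_one_factor_data_is_meritorious(self, study_sim):
        responses, _ = study_sim
        assert kmo_statistic(responses) > 0.9


class TestBartlett:
    def test_independent_items_are_not_spherical_violating(self, rng):
        rm = _rm(rng.integers(1, 6, size=(500, 5)))
        chi2, df, p = bartlett_sphericity(rm)
        assert df == 10
        assert p > 0.01  # no evidence against the identity correlation

    def test_df_bookkeeping_for_study_shape(self, study_sim):
        responses, _ = study_sim
        chi2, df, p = bartlett_sphericity(responses)
        assert df == 253
        assert p < 0.001


class TestEigenvalueRatio:
    def test_eigenvalues_sum_to_item_count(self, study_sim):
        responses, _ = study_sim
        eig, ratio, ok = eigenvalue_ratio(responses)
        assert eig.sum() == pytest.approx(responses.n_items, abs=1e-8)
        assert np.all(np.diff(eig) <= 1e-12)

    def test_one_factor_simulation_passes(self, study_sim):
        responses, _ = study_sim
        _, ratio, ok = eigenvalue_ratio(responses)
        assert ratio > 3 and ok

    def test_two_orthogonal_factors_fail(self, default_bank, rng):
        """Two independent traits driving half the bank each: the first-to-
        second root ratio falls under the unidimensionality cut-off."""
        from grmkit.grm import boundary_prob

        n = 1000
        th = rng.normal(size=(n, 2))
        vals = np.empty((n, 23))
        for j, it in enumerate(default_bank):
            t = th[:, 0] if j < 11 else th[:, 1]
            u = rng.random(n)
            vals[:, j] = 1 + (u[:, None] < boundary_prob(it, t)).sum(axis=1)
        _, ratio, ok = eigenvalue_ratio(_rm(vals))
        assert ratio < 3 and not ok


class TestResidualCorrelations:
    def test_unidimensional_data_shows_no_local_dependence(self, study_sim, default_bank):
        responses, _ = study_sim
        q3, max_abs, ok = residual_correlations(responses, default_bank)
        assert ok and max_abs < 0.70
        vals = q3.to_numpy()
        # Q3's small negative bias under local independence: mean near -1/(J-1)
        assert np.nanmean(vals) == pytest.approx(-1 / 22, abs=0.03)
        assert np.allclose(vals, vals.T, equal_nan=True)
        assert np.isnan(np.diag(vals)).all()

    def test_duplicated_item_is_flagged(self, default_bank, rng):
        config = SimulationConfig(n=800, seed=99, bank=default_bank, covariate_spec={})
        responses, _ = simulate_responses(config)
        vals = np.column_stack([responses.values, responses.values[:, 0]])
        rm = ResponseMatrix(values=vals, item_ids=responses.item_ids + ["dup"], K=5)
        dup_bank = default_bank.subset(responses.item_ids)
        items = list(dup_bank.items)
        from grmkit import ItemBank, ItemParameters
        it0 = items[0]
        items.append(ItemParameters("dup", it0.a, it0.b, it0.wording))
        bank2 = ItemBank(items=tuple(items), K=5)
        q3, max_abs, ok = residual_correlations(rm, bank2)
        assert q3.loc["dup", it0.item_id] > 0.8
        assert not ok


class TestMonotonicity:
    def test_grm_data_is_monotone(self, study_sim):
        responses, _ = study_sim
        curves, flags = monotonicity_curves(responses)
        assert not flags.any()
        assert len(curves) == 23

    def test_reverse_coded_item_is_flagged(self, study_sim):
        responses, _ = study_sim
        vals = responses.values.copy()
        vals[:, 0] = 6 - vals[:, 0]
        _, flags = monotonicity_curves(_rm(vals))
        assert flags.iloc[0]
        # the reversed item also degrades other items' rest scores a little,
        # so only require that the bulk of the bank stays clean
        assert flags.iloc[1:].sum() <= 3

    def test_constant_item_is_flat_not_flagged(self, rng):
        vals = np.column_stack([np.full(600, 3.0),
                                rng.integers(1, 6, size=(600, 3))])
        curves, flags = monotonicity_curves(_rm(vals), n_bins=5)
        assert not flags.iloc[0]
        assert np.allclose(curves["i0"].columns["mean_score"], 3.0)

    def test_too_few_persons_is_an_error(self, rng):
        rm = _rm(rng.integers(1, 6, size=(40, 4)))
        with pytest.raises(ValidationError, match="bins"):
            monotonicity_curves(rm, n_bins=10)

    def test_flags_invariant_to_rest_score_shift(self, study_sim):
        """Binning is quantile-based, so adding a constant to every rest
        score (an extra constant item) cannot change the verdicts."""
        responses, _ = study_sim
        _, flags = monotonicity_curves(responses)
        vals = np.column_stack([responses.values, np.full(responses.n_persons, 5.0)])
        _, flags2 = monotonicity_curves(_rm(vals))
        assert (flags2.iloc[:-1].to_numpy() == flags.to_numpy()).all()


def test_assumption_report_verdicts(study_sim, default_bank):
    responses, _ = study_sim
    rep = assumption_report(responses, bank=default_bank)
    assert rep.verdicts == {"unidimensional": True, "bartlett_significant": True,
                            "monotone": True, "locally_independent": True}
    summary = rep.summary()
    assert 0 <= summary["kmo"] <= 1
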