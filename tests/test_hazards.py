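"""Cox ensemble machinery: pruning, scaling, concordance, weighted HRs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import riskatlas as ra
from riskatlas.hazards import apply_zscale, ensemble_weights, inverse_zscale


class TestDropCorrelatedBiomarkers:
    def test_duplicate_column_removed_second(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        panel = pd.DataFrame({"a": x, "b": x.copy()})
        retained, removed = ra.drop_correlated_biomarkers(panel, 0.7)
        assert retained == ["a"] and removed == ["b"]

    def test_independent_columns_all_retained(self):
        panel = pd.DataFrame(
            np.random.default_rng(1).standard_normal((5000, 6)),
            columns=list("abcdef"),
        )
        retained, removed = ra.drop_correlated_biomarkers(panel, 0.7)
        assert removed == [] and retained == list("abcdef")

    def test_planted_triplet_loses_two_columns(self):
        rng = np.random.default_rng(2)
        base = rng.standard_normal(2000)
        panel = pd.DataFrame({
            "t1": base,
            "t2": base + 0.3 * rng.standard_normal(2000),  # r ~ 0.96
            "u1": rng.standard_normal(2000),
            "t3": base + 0.35 * rng.standard_normal(2000),
            "u2": rng.standard_normal(2000),
        })
        # independent oracle: brute-force pairwise |r| >= 0.7 against t1
        corr = panel.corr().abs()
        assert corr.loc["t1", "t2"] >= 0.9 and corr.loc["t1", "t3"] >= 0.9
        retained, removed = ra.drop_correlated_biomarkers(panel, 0.7)
        assert removed == ["t2", "t3"]
        assert retained == ["t1", "u1", "u2"]

    def test_constant_column_removed_with_warning(self):
        panel = pd.DataFrame({"a": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            retained, removed = ra.drop_correlated_biomarkers(panel)
        assert removed == ["c"] and retained == ["a"]

    def test_partition_property(self):
        panel = pd.DataFrame(
            np.random.default_rng(3).standard_normal((200, 8)))
        panel.columns = [f"c{i}" for i in range(8)]
        retained, removed = ra.drop_correlated_biomarkers(panel, 0.2)
        assert sorted(retained + removed) == sorted(panel.columns)


class TestZscale:
    def test_mean_zero_sd_one(self):
        panel = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        scaled, params = ra.zscale(panel)
        assert abs(scaled["x"].mean()) < 1e-12
        assert abs(scaled["x"].std(ddof=0) - 1) < 1e-12

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        x = (x - x.mean()) / x.std()
        panel = pd.DataFrame({"x": x})
        scaled, _ = ra.zscale(panel)
        assert np.allclose(scaled["x"], x, atol=1e-10)

    def test_round_trip(self):
        panel = pd.DataFrame(
            np.random.default_rng(5).normal(50, 7, (100, 3)),
            columns=list("abc"))
        scaled, params = ra.zscale(panel)
        back = inverse_zscale(scaled, params)
        pd.testing.assert_frame_equal(back, panel)

    def test_train_params_apply_to_test(self):
        rng = np.random.default_rng(6)
        train = pd.DataFrame({"x": rng.normal(10, 2, 100)})
        test = pd.DataFrame({"x": rng.normal(10, 2, 50)})
        _, params = ra.zscale(train)
        scaled_test = apply_zscale(test, params)
        expected = (test["x"] - train["x"].mean()) / train["x"].std(ddof=0)
        assert np.allclose(scaled_test["x"], expected)

    def test_zero_variance_column_named_in_error(self):
        panel = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            ra.zscale(panel)


def brute_force_cindex(risk, t, e):
    """Exhaustive Harrell enumeration: every ordered pair checked by hand."""
    num = den = 0.0
    for i in range(len(t)):
        for j in range(len(t)):
            if i == j:
                continue
            if e[i] and (t[i] < t[j] or (t[i] == t[j] and not e[j])):
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


class TestConcordanceIndex:
    def test_perfect_concordance(self):
        t = np.array([4.0, 3.0, 2.0, 1.0])
        risk = np.array([1.0, 2.0, 3.0, 4.0])
        assert ra.concordance_index(risk, t, np.ones(4)) == 1.0

    def test_all_tied_scores_give_half(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert ra.concordance_index(np.zeros(4), t, np.ones(4)) == 0.5

    def test_mixed_censoring_fixture_matches_enumeration(self):
        t = np.array([2.0, 4.0, 3.0, 1.0])
        e = np.array([1, 0, 1, 0])
        risk = np.array([0.5, -0.2, 0.1, 0.9])
        assert ra.concordance_index(risk, t, e) == pytest.approx(
            brute_force_cindex(risk, t, e), abs=1e-12)

    def test_no_comparable_pairs_is_an_error_not_half(self):
        t = np.array([1.0, 2.0])
        e = np.array([0, 0])
        with pytest.raises(ValueError, match="comparable"):
            ra.concordance_index(np.array([1.0, 2.0]), t, e)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            ra.concordance_index(np.array([1.0]), np.array([0.0]), np.array([1]))


class TestEnsembleWeights:
    @given(st.lists(st.floats(min_value=0.4, max_value=1.0), min_size=1,
                    max_size=30))
    def test_weights_normalize_and_match_formula(self, c):
        c = np.asarray(c)
        w = ensemble_weights(c)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.allclose(w * c.sum(), c, rtol=1e-12)

    def test_nonpositive_cindex_rejected(self):
        with pytest.raises(ValueError):
            ensemble_weights([0.6, 0.0])


class TestFitCoxEnsemble:
    def test_single_penalty_grid_weights_trivially(self, small_cohort):
        design = ra.ModelDesign(biomarkers=small_cohort.biomarker_ids,
                                penalty_grid=np.array([0.05]), seed=11)
        fit = ra.fit_cox_ensemble(small_cohort.table, "D000", design)
        assert fit.weights.tolist() == [1.0]
        expected = np.exp(fit.per_penalty_betas.iloc[0])
        pd.testing.assert_series_equal(fit.weighted_hr, expected,
                                       check_names=False)

    def test_weighted_hr_positive_and_weights_sum_to_one(
            self, small_cohort, small_design):
        fit = ra.fit_cox_ensemble(small_cohort.table, "D001", small_design)
        assert (fit.weighted_hr > 0).all()
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(
            fit.weights, fit.per_penalty_cindex / fit.per_penalty_cindex.sum())

    def test_shrinkage_monotone_for_single_biomarker(self):
        rng = np.random.default_rng(7)
        bm = ra.generate_biomarkers(3000, 1, 0.0, 1, seed=7)
        betas = pd.DataFrame([[0.5]], index=["D0"], columns=bm.columns)
        out = ra.simulate_survival(bm, betas, baseline_rate=0.02, horizon=12,
                                   seed=7)
        cohort = pd.concat([bm, out], axis=1)
        cohort["age"] = rng.uniform(40, 70, 3000)
        for c in ["sex", "deprivation", "bmi", "smoking", "sbp"]:
            cohort[c] = rng.standard_normal(3000)
        design = ra.ModelDesign(biomarkers=["bm_00"], fixed_covariates=[],
                                penalty_grid=np.linspace(0.01, 2.0, 6), seed=7)
        fit = ra.fit_cox_ensemble(cohort, "D0", design)
        coef = fit.per_penalty_betas["bm_00"].to_numpy()
        assert np.all(np.diff(np.abs(coef)) <= 1e-9)

    def test_planted_strong_biomarker_dominates(self, small_cohort):
        # D000 belongs to archetype 0; its largest true |beta| should carry
        # the largest weighted |log-HR| sign-consistently
        design = ra.ModelDesign(biomarkers=small_cohort.biomarker_ids,
                                penalty_grid=np.array([0.02, 0.1]), seed=11)
        truth = small_cohort.true_betas.loc["D000"]
        strongest = truth.abs().idxmax()
        fit = ra.fit_cox_ensemble(small_cohort.table, "D000", design)
        log_hr = fit.weighted_log_hr[small_cohort.biomarker_ids]
        assert np.sign(log_hr[strongest]) == np.sign(truth[strongest])
        assert spearmanr(log_hr, truth).statistic > 0.6

    def test_min_events_guard(self, small_cohort):
        design = ra.ModelDesign(biomarkers=small_cohort.biomarker_ids,
                                penalty_grid=np.array([0.05]),
                                min_events=10**6, seed=11)
        with pytest.raises(ValueError, match="events"):
            ra.fit_cox_ensemble(small_cohort.table, "D000", design)

    def test_invalid_designs_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="increasing"):
            ra.ModelDesign(biomarkers=["bm_00"],
                           penalty_grid=np.array([0.2, 0.1]))
        with pytest.raises(ValueError, match="split_fraction"):
            ra.ModelDesign(biomarkers=["bm_00"], split_fraction=1.2)


class TestBuildHazardMatrix:
    def test_threshold_zero_keeps_all(self, small_cohort, small_hazards):
        assert list(small_hazards.hr.index) == small_cohort.disease_ids
        assert small_hazards.hr.notna().all().all()
        assert (small_hazards.hr.to_numpy() > 0).all()

    def test_metadata_counts_match_fixture(self, small_cohort, small_hazards):
        for d in small_cohort.disease_ids:
            assert small_hazards.metadata.loc[d, "n_cases"] == \
                small_cohort.table[f"{d}_event"].sum()

    def test_threshold_above_all_cases_errors(self, small_cohort, small_design):
        with pytest.raises(ValueError, match="incidence_threshold"):
            ra.build_hazard_matrix(small_cohort.table, small_design,
                                   incidence_threshold=10**7)

    def test_partial_threshold_excludes_low_incidence(self, small_cohort,
                                                      small_design):
        counts = {d: small_cohort.table[f"{d}_event"].sum()
                  for d in small_cohort.disease_ids}
        cut = int(np.median(list(counts.values())))
        hm = ra.build_hazard_matrix(small_cohort.table, small_design,
                                    incidence_threshold=cut)
        expected = [d for d, n in counts.items() if n >= cut]
        assert list(hm.hr.index) == expected
        assert sorted(hm.excluded) == sorted(set(counts) - set(expected))

    def test_round_trip_tsv(self, small_hazards, tmp_path):
        from riskatlas.hazards import read_hazard_matrix, write_hazard_matrix

        write_hazard_matrix(small_hazards, tmp_path)
        back = read_hazard_matrix(tmp_path)
        pd.testing.assert_frame_equal(back.hr, small_hazards.hr)
        assert back.fixed_columns == small_hazards.fixed_columns
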