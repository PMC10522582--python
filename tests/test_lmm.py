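import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from trialomics.lmm import (
    ALL_FAMILIES,
    FAMILY_INTERACTION_ARM_RESPONSE,
    FAMILY_INTERACTION_ARM_TIME,
    FAMILY_PAIRWISE_PRE,
    FAMILY_PRE_POST,
    LMMFit,
    adjust_bh,
    build_design,
    cell_mean_vector,
    enumerate_contrasts,
    fit_protein_lmm,
    run_contrast_suite,
)
from trialomics.lmm import test_contrast as wald_contrast  # avoid pytest collection

from conftest import make_annotation, simulate_response


class TestBuildDesign:
    def test_two_level_main_effects_have_four_columns(self):
        ann = make_annotation(20, seed=1, responses=("PD", "CR"))
        d = build_design(ann, interactions="none")
        assert d.n_params == 4
        assert d.columns[0] == "Intercept"

    def test_four_response_main_effects_have_six_columns(self):
        ann = make_annotation(40, seed=2)
        d = build_design(ann, interactions="none")
        assert d.n_params == 6

    def test_arm_response_interaction_adds_three_columns(self):
        ann = make_annotation(40, seed=2)
        d = build_design(ann, interactions=("arm:response",))
        assert d.n_params == 9
        # independent indicator-matrix oracle
        sub = ann[ann["response"] != "NE"]
        for lvl in ("SD", "PR", "CR"):
            expected = (
                (sub["arm"] == "ATRA") & (sub["response"] == lvl)
            ).to_numpy(float)
            col = d.columns.index(f"arm[ATRA]:response[{lvl}]")
            np.testing.assert_array_equal(d.X[:, col], expected)

    def test_full_design_saturates_cells(self):
        ann = make_annotation(60, seed=3)
        d = build_design(ann)
        assert d.n_params == 16  # 4 responses x 2 arms x 2 times

    def test_reference_levels_lead_orderings(self):
        d = build_design(make_annotation(40, seed=4))
        assert d.response_levels[0] == "PD"
        assert d.arm_levels[0] == "placebo"
        assert d.time_levels[0] == "pre"

    def test_ne_samples_excluded(self):
        ann = make_annotation(40, seed=5, responses=("PD", "SD", "PR", "CR", "NE"))
        d = build_design(ann)
        assert "response[NE]" not in d.columns
        assert len(d.sample_ids) == 2 * (ann["response"] != "NE").sum() / 2

    def test_single_level_factor_rejected(self):
        ann = make_annotation(20, seed=6)
        ann["arm"] = "ATRA"
        with pytest.raises(ValueError, match="arm"):
            build_design(ann)

    def test_duplicate_patient_time_rejected(self):
        ann = make_annotation(10, seed=7)
        ann.loc[1, "time"] = "pre"
        with pytest.raises(ValueError, match="patient, time"):
            build_design(ann)

    def test_inconsistent_patient_response_rejected(self):
        ann = make_annotation(10, seed=8)
        ann.loc[0, "response"] = "CR"
        ann.loc[1, "response"] = "PD"
        with pytest.raises(ValueError, match="response"):
            build_design(ann)


class TestEnumerateContrasts:
    def test_family_sizes(self, design):
        contrasts = enumerate_contrasts(design)
        by_family = {}
        for c in contrasts:
            by_family.setdefault(c.family, []).append(c)
        assert len(by_family[FAMILY_PAIRWISE_PRE]) == 12  # C(4,2) x 2 arms
        assert len(by_family[FAMILY_INTERACTION_ARM_RESPONSE]) == 6
        assert len(by_family[FAMILY_PRE_POST]) == 8       # 4 responses x 2 arms
        assert len(by_family[FAMILY_INTERACTION_ARM_TIME]) == 4

    def test_labels_unique(self, design):
        labels = [c.label for c in enumerate_contrasts(design)]
        assert len(labels) == len(set(labels))

    def test_cell_means_oracle(self):
        # on a saturated noiseless fit, every contrast reproduces the
        # corresponding difference of assigned cell means
        ann = make_annotation(80, seed=9)
        d = build_design(ann)
        cells = {}
        rng = np.random.default_rng(0)
        for r in d.response_levels:
            for a in d.arm_levels:
                for t in d.time_levels:
                    cells[(r, a, t)] = float(rng.normal())
        sub = ann[ann["response"] != "NE"]
        y = np.array(
            [
                cells[(row.response, row.arm, row.time)]
                for row in sub.itertuples()
            ]
        )
        fit = fit_protein_lmm(y, d)
        pre, post = d.time_levels
        for con in enumerate_contrasts(d):
            est = float(con.vector @ fit.beta)
            m = con.meta
            if con.family == FAMILY_PAIRWISE_PRE:
                expected = cells[(m["r_hi"], m["arm"], pre)] - cells[(m["r_lo"], m["arm"], pre)]
            elif con.family == FAMILY_INTERACTION_ARM_RESPONSE:
                expected = (
                    cells[(m["r_hi"], "ATRA", pre)] - cells[(m["r_lo"], "ATRA", pre)]
                ) - (
                    cells[(m["r_hi"], "placebo", pre)] - cells[(m["r_lo"], "placebo", pre)]
                )
            elif con.family == FAMILY_PRE_POST:
                expected = cells[(m["response"], m["arm"], post)] - cells[(m["response"], m["arm"], pre)]
            else:
                expected = (
                    cells[(m["response"], "ATRA", post)] - cells[(m["response"], "ATRA", pre)]
                ) - (
                    cells[(m["response"], "placebo", post)] - cells[(m["response"], "placebo", pre)]
                )
            assert est == pytest.approx(expected, abs=1e-9), con.label

    def test_interaction_families_require_terms(self):
        ann = make_annotation(40, seed=10)
        d = build_design(ann, interactions="none")
        with pytest.raises(ValueError, match="arm:response"):
            enumerate_contrasts(d, families=(FAMILY_INTERACTION_ARM_RESPONSE,))
        with pytest.raises(ValueError, match="arm:time"):
            enumerate_contrasts(d, families=(FAMILY_INTERACTION_ARM_TIME,))

    def test_cell_mean_vector_rejects_unknown_levels(self, design):
        with pytest.raises(ValueError):
            cell_mean_vector(design, "XX", "ATRA", "pre")


class TestFitProteinLMM:
    def test_constant_response(self, design):
        y = np.full(design.X.shape[0], 3.5)
        fit = fit_protein_lmm(y, design)
        assert fit.converged and fit.boundary
        assert fit.beta[0] == pytest.approx(3.5)
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-9)
        assert fit.var_random == 0.0 and fit.var_residual == 0.0

    def test_one_observation_per_patient_equals_ols(self):
        ann = make_annotation(80, seed=11)
        ann["patient"] = ann["sample"]  # every sample its own patient
        d = build_design(ann)
        rng = np.random.default_rng(1)
        y = d.X @ rng.normal(size=d.n_params) + rng.normal(0, 0.8, d.X.shape[0])
        fit = fit_protein_lmm(y, d)
        beta_ols, *_ = np.linalg.lstsq(d.X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)
        resid = y - d.X @ beta_ols
        s2 = resid @ resid / (d.X.shape[0] - d.n_params)
        cov_ols = s2 * np.linalg.inv(d.X.T @ d.X)
        np.testing.assert_allclose(fit.cov_beta, cov_ols, rtol=1e-6)

    def test_matches_statsmodels_mixedlm(self, design):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        for _ in range(3):
            y = simulate_response(
                design, rng.normal(size=design.n_params), 0.7, 0.5, rng
            )
            fit = fit_protein_lmm(y, design)
            ref = sm.MixedLM(y, design.X, groups=design.groups).fit(reml=True)
            np.testing.assert_allclose(fit.beta, ref.fe_params, atol=1e-7)
            assert fit.var_residual == pytest.approx(ref.scale, abs=1e-4)
            cov_re = float(np.atleast_2d(np.asarray(ref.cov_re))[0, 0])
            assert fit.var_random == pytest.approx(cov_re, abs=1e-4)

    def test_simulation_recovery_bias(self):
        ann = make_annotation(200, seed=12)
        d = build_design(ann)
        rng = np.random.default_rng(3)
        beta = rng.normal(size=d.n_params)
        bias = np.zeros(d.n_params)
        n_reps = 200
        for _ in range(n_reps):
            y = simulate_response(d, beta, 0.6, 0.5, rng)
            fit = fit_protein_lmm(y, d)
            bias += fit.beta - beta
        assert np.abs(bias / n_reps).mean() < 0.05

    def test_missing_data_dropped(self, design):
        rng = np.random.default_rng(4)
        y = simulate_response(design, np.zeros(design.n_params), 0.5, 0.5, rng)
        y[rng.random(y.size) < 0.1] = np.nan
        fit = fit_protein_lmm(y, design)
        assert fit.converged
        assert fit.n_obs == int(np.isfinite(y).sum())

    def test_rank_deficiency_recorded_not_raised(self, design):
        rng = np.random.default_rng(5)
        y = simulate_response(design, np.zeros(design.n_params), 0.5, 0.5, rng)
        # wipe out every CR sample so its columns become zero
        cr = design.X[:, design.columns.index("response[CR]")] == 1
        y[cr] = np.nan
        fit = fit_protein_lmm(y, design)
        assert not fit.converged
        assert "rank" in fit.message

    def test_too_few_observations(self, design):
        y = np.full(design.X.shape[0], np.nan)
        y[: design.n_params] = 1.0
        fit = fit_protein_lmm(y, design)
        assert not fit.converged

    def test_row_permutation_invariance(self):
        ann = make_annotation(50, seed=13)
        d = build_design(ann)
        rng = np.random.default_rng(6)
        y = simulate_response(d, rng.normal(size=d.n_params), 0.7, 0.4, rng)
        perm = rng.permutation(len(ann))
        ann_p = ann.iloc[perm].reset_index(drop=True)
        d_p = build_design(ann_p)
        fit = fit_protein_lmm(y, d)
        order = [d.sample_ids.index(s) for s in d_p.sample_ids]
        fit_p = fit_protein_lmm(y[order], d_p)
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-8)
        assert fit.var_random == pytest.approx(fit_p.var_random, abs=1e-8)


class TestTestContrast:
    def _fit(self, beta, cov):
        beta = np.asarray(beta, dtype=float)
        cov = np.asarray(cov, dtype=float)
        return LMMFit(
            protein="P", beta=beta, cov_beta=cov,
            columns=[f"b{i}" for i in range(beta.size)],
            var_random=0.1, var_residual=0.2, converged=True,
            boundary=False, n_obs=100, n_groups=50,
        )

    def test_zero_vector(self):
        fit = self._fit([1.0, 2.0], [[1.0, 0.0], [0.0, 1.0]])
        res = wald_contrast(fit, [0.0, 0.0], "null", "pairwise_pre")
        assert res.estimate == 0.0 and res.p_raw == 1.0

    def test_identity_contrast_matches_wald(self):
        fit = self._fit([1.0, 0.8], [[0.5, 0.1], [0.1, 0.25]])
        res = wald_contrast(fit, [0.0, 1.0], "b1", "pairwise_pre")
        z = 0.8 / math.sqrt(0.25)
        assert res.z == pytest.approx(z)
        assert res.p_raw == pytest.approx(2 * stats.norm.sf(abs(z)))
        # z^2 equals the Wald chi-square of the coefficient
        assert res.z**2 == pytest.approx(
            stats.chi2.isf(res.p_raw, df=1), rel=1e-9
        )

    def test_difference_contrast_se_hand_arithmetic(self):
        cov = [[2.0, 0.5, 0.0], [0.5, 1.0, 0.2], [0.0, 0.2, 3.0]]
        fit = self._fit([0.0, 1.5, 0.7], cov)
        res = wald_contrast(fit, [0.0, 1.0, -1.0], "diff", "pairwise_pre")
        assert res.se == pytest.approx(math.sqrt(1.0 + 3.0 - 2 * 0.2))
        assert res.estimate == pytest.approx(0.8)

    def test_degenerate_zero_se(self):
        fit = self._fit([1.0], [[0.0]])
        res = wald_contrast(fit, [1.0], "d", "pairwise_pre")
        assert res.p_raw == 0.0 and res.degenerate

    def test_length_mismatch(self):
        fit = self._fit([1.0, 2.0], np.eye(2))
        with pytest.raises(ValueError):
            wald_contrast(fit, [1.0], "x", "pairwise_pre")


class TestAdjustBH:
    def test_single_p_unchanged(self):
        assert adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_hand_step_up_mixed_vector(self):
        # hand computation: sort (.005,.02,.03,.04,.8) -> p*n/i =
        # (.025,.05,.05,.05,.8), min-accumulate from the right, map back
        out = adjust_bh([0.005, 0.04, 0.02, 0.8, 0.03])
        np.testing.assert_allclose(out, [0.025, 0.05, 0.05, 0.8, 0.05])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(200)
        np.testing.assert_allclose(
            adjust_bh(p), multipletests(p, method="fdr_bh")[1]
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
        with pytest.raises(ValueError):
            adjust_bh([0.5, np.nan])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        adj = adjust_bh(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)
        assert np.all((adj >= 0) & (adj <= 1))
        # monotone in ranks
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestRunContrastSuite:
    def test_tidy_output_and_adjustment(self):
        from trialomics.preprocess import normalize_and_log
        from trialomics.synthetic import CohortConfig, ProteomeConfig, generate_cohort, generate_proteome

        cohort = generate_cohort(CohortConfig(n_per_arm=(25, 25), seed=21))
        matrix, ann, _ = generate_proteome(
            cohort, ProteomeConfig(n_proteins=12, n_spiked_per_archetype=1,
                                   dropout_prob=0.0, seed=22)
        )
        norm = normalize_and_log(matrix)
        res = run_contrast_suite(norm, ann)
        assert set(res["family"].unique()) == set(ALL_FAMILIES)
        assert len(res) == 12 * 30  # 12+6+8+4 contrasts per protein
        ok = res["converged"]
        assert (res.loc[ok, "p_adj"] >= res.loc[ok, "p_raw"] - 1e-12).all()
        # BH is applied within each family
        for fam in ALL_FAMILIES:
            sub = res[(res["family"] == fam) & ok]
            np.testing.assert_allclose(
                sub["p_adj"].to_numpy(),
                adjust_bh(sub["p_raw"].to_numpy()),
            )
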