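"""Design matrices, HRF, OLS fitting and the two-step polynomial route."""

import warnings

import numpy as np
import pandas as pd
import pytest

from uvconf import glm, synth
from uvconf.behavior import RESPONSES, TASKS


class TestCanonicalHRF:
    def test_shape_peak_and_undershoot(self):
        h = glm.canonical_hrf(0.1)
        t = np.arange(len(h)) * 0.1
        assert h.max() == pytest.approx(1.0)
        assert h.min() < -0.01  # undershoot
        assert 4.0 <= t[h.argmax()] <= 7.0
        assert 10.0 <= t[h.argmin()] <= 20.0

    def test_grid_refinement_converges_pointwise(self):
        coarse = glm.canonical_hrf(0.2)
        fine = glm.canonical_hrf(0.05)
        assert np.allclose(coarse, fine[::4][: len(coarse)], atol=1e-6)

    def test_matches_spm_kernel(self):
        hemodynamic_models = pytest.importorskip(
            "nilearn.glm.first_level.hemodynamic_models"
        )
        ours = glm.canonical_hrf(0.1)
        ref = hemodynamic_models.spm_hrf(0.1, oversampling=1)
        ref = ref / ref.max()
        n = min(len(ours), len(ref))
        assert np.corrcoef(ours[:n], ref[:n])[0, 1] > 0.99

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            glm.canonical_hrf(0.0)


class TestModulatorConstruction:
    def test_linear_modulator_mean_centred(self):
        conf = np.array([1, 2, 2, 5, 6, 6, 4], dtype=float)
        lin, quad = glm._centered_modulators(conf)
        assert lin.sum() == pytest.approx(0.0, abs=1e-12)
        assert quad.sum() == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_orthogonal_to_linear(self):
        conf = np.array([1, 1, 3, 4, 6, 6, 5, 2], dtype=float)
        lin, quad = glm._centered_modulators(conf)
        assert lin @ quad == pytest.approx(0.0, abs=1e-10)


class TestQCDesignMatrix:
    def test_18_regressors_of_interest(self, small_session):
        dm = glm.build_qc_dm(small_session)
        assert len(dm.of_interest) == 18
        orders = [dm.meta[n]["order"] for n in dm.of_interest]
        assert orders.count(0) == orders.count(1) == orders.count(2) == 6

    def test_absent_response_warns_and_omits(self, small_session):
        mutilated = small_session.loc[small_session["response"] != "yes"]
        with pytest.warns(UserWarning, match="yes"):
            dm = glm.build_qc_dm(mutilated)
        assert len(dm.of_interest) == 15
        assert "yes_conf2" not in dm.names

    def test_run_constants_partition_scans(self, small_session):
        dm = glm.build_qc_dm(small_session)
        run_cols = [n for n in dm.names if n.endswith("_constant")]
        assert len(run_cols) == 3
        total = sum(dm.data[c].to_numpy() for c in run_cols)
        assert np.array_equal(total, np.ones(dm.n_scans))

    def test_nuisance_columns_present(self, default_session):
        marked = default_session.copy()
        marked["excluded_block"] = marked["block"] == 1
        dm = glm.build_qc_dm(marked)
        for name in ("missed_trials", "first_trials", "excluded_trials", "instructions", "button_left"):
            assert name in dm.names
            assert name not in dm.of_interest

    def test_tsv_export_round_trip(self, small_session, tmp_path):
        dm = glm.build_qc_dm(small_session)
        dm.to_tsv(tmp_path / "dm.tsv", tmp_path / "dm.json")
        back = pd.read_csv(tmp_path / "dm.tsv", sep="\t")
        assert list(back.columns) == dm.names
        assert np.allclose(back.to_numpy(), dm.data.to_numpy(), atol=1e-6)


class TestCategoricalDesignMatrix:
    def test_twelve_dummy_modulators_one_base(self, small_session):
        dm = glm.build_categorical_dm(small_session, "detection")
        dummies = [n for n in dm.of_interest if "level" in dm.meta.get(n, {})]
        assert len(dummies) == 12
        bases = [n for n in dm.of_interest if dm.meta[n].get("order") == 0]
        assert bases == ["detection_trials"]

    def test_base_equals_sum_of_dummies(self, small_session):
        # dummy modulators are 0/1 and partition the task trials, so their
        # convolved columns sum to the base regressor
        dm = glm.build_categorical_dm(small_session, "detection")
        dummies = [n for n in dm.of_interest if "level" in dm.meta.get(n, {})]
        total = sum(dm.data[c].to_numpy() for c in dummies)
        assert np.allclose(total, dm.data["detection_trials"].to_numpy(), atol=1e-10)

    def test_unknown_task_rejected(self, small_session):
        with pytest.raises(ValueError):
            glm.build_categorical_dm(small_session, "counting")


class TestFitGLM:
    def test_noise_free_recovery(self, small_session):
        dm = glm.build_qc_dm(small_session)
        rng = np.random.default_rng(0)
        beta_true = rng.normal(size=len(dm.names))
        y = dm.data.to_numpy() @ beta_true
        fit = glm.fit_glm(y, dm)
        assert np.allclose(fit.betas.to_numpy(), beta_true, atol=1e-6)

    def test_rank_deficient_design_names_columns(self, small_session):
        dm = glm.build_qc_dm(small_session)
        dm.data["yes_copy"] = dm.data["yes"]
        dm.meta["yes_copy"] = {}
        with pytest.raises(np.linalg.LinAlgError, match="yes"):
            glm.fit_glm(dm.data["yes"].to_numpy(), dm)

    def test_constant_shift_moves_only_run_constants(self, small_session):
        dm = glm.build_qc_dm(small_session)
        rng = np.random.default_rng(1)
        y = rng.normal(size=dm.n_scans)
        f0 = glm.fit_glm(y, dm)
        f1 = glm.fit_glm(y + 5.0, dm)
        for name in dm.names:
            if name.endswith("_constant"):
                assert f1.betas[name] == pytest.approx(f0.betas[name] + 5.0, abs=1e-6)
            else:
                assert f1.betas[name] == pytest.approx(f0.betas[name], abs=1e-6)

    def test_pure_noise_of_interest_betas_average_to_zero(self, small_session):
        dm = glm.build_qc_dm(small_session)
        rng = np.random.default_rng(2)
        means = []
        for _ in range(20):
            fit = glm.fit_glm(rng.normal(size=dm.n_scans), dm)
            means.append(fit.betas[dm.of_interest].mean())
        assert np.mean(means) == pytest.approx(0.0, abs=0.05)

    def test_scan_mismatch_rejected(self, small_session):
        dm = glm.build_qc_dm(small_session)
        with pytest.raises(ValueError):
            glm.fit_glm(np.zeros(dm.n_scans - 1), dm)


class TestTwoStepPolyfit:
    def test_pure_quadratic_betas(self):
        betas = {"yes": {c: float(c**2) for c in range(1, 7)}}
        est = glm.two_step_polyfit(betas)
        row = est.coefficients.loc["yes"]
        assert row["quadratic"] == pytest.approx(1.0, abs=1e-10)
        assert row["linear"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_linear_betas(self):
        betas = {"no": {c: 2.0 * c for c in range(1, 7)}}
        est = glm.two_step_polyfit(betas)
        row = est.coefficients.loc["no"]
        assert row["linear"] == pytest.approx(2.0, abs=1e-10)
        assert row["quadratic"] == pytest.approx(0.0, abs=1e-10)

    def test_too_few_levels_skipped_with_warning(self):
        betas = {
            "yes": {1: 0.0, 2: 1.0},
            "no": {c: float(c) for c in range(1, 7)},
        }
        with pytest.warns(UserWarning, match="yes"):
            est = glm.two_step_polyfit(betas)
        assert list(est.coefficients.index) == ["no"]

    def test_noisy_polynomial_within_ci(self):
        rng = np.random.default_rng(3)
        g1, g2 = 0.4, 0.15
        lins, quads = [], []
        for _ in range(20):
            betas = {
                "yes": {
                    c: g1 * c + g2 * c**2 + rng.normal(0, 0.05)
                    for c in range(1, 7)
                }
            }
            row = glm.two_step_polyfit(betas).coefficients.loc["yes"]
            lins.append(row["linear"])
            quads.append(row["quadratic"])
        for values, truth in ((lins, g1), (quads, g2)):
            m = np.mean(values)
            half = 2.09 * np.std(values, ddof=1) / np.sqrt(len(values))
            assert m - half <= truth <= m + half

    def test_equal_weight_per_level_regardless_of_frequencies(self):
        # the fit sees one beta per level: trial frequencies cannot enter
        betas = {"yes": {c: float(3 * c) for c in range(1, 7)}}
        est = glm.two_step_polyfit(betas)
        assert est.coefficients.loc["yes", "linear"] == pytest.approx(3.0)


class TestConfidenceDistributionInvariance:
    def test_categorical_route_invariant_to_confidence_frequencies(self):
        """Two sessions whose confidence usage differs wildly but whose
        per-level amplitudes agree yield identical two-step coefficients
        (noise-free)."""
        g1, g2 = 0.3, 0.1

        def run(conf_cycle):
            rows = []
            onset = 10.0
            for i, c in enumerate(conf_cycle * 8):
                rows.append(
                    {
                        "onset": onset,
                        "duration": 0.5,
                        "task": "detection",
                        "stim_class": "present",
                        "orientation": 0.0,
                        "response": "yes",
                        "correct": True,
                        "confidence": c,
                        "missed": False,
                        "block": 1,
                        "run": 1,
                        "trial_in_block": i + 2,
                    }
                )
                onset += 14.0
            trials = pd.DataFrame(rows)
            amp = g1 * trials["confidence"] + g2 * trials["confidence"] ** 2
            y = glm._convolved_regressor(
                trials["onset"].to_numpy(),
                np.full(len(trials), glm.BOXCAR_DURATION),
                amp.to_numpy(dtype=float),
                int((onset + 32) / 2.0),
                2.0,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dm = glm.build_categorical_dm(trials, "detection", n_scans=len(y))
                fit = glm.fit_glm(y, dm, allow_rank_deficient=True)
                est = glm.two_step_polyfit(
                    glm.categorical_betas_by_response(fit, dm)
                )
            return est.coefficients.loc["yes"]

        balanced = run([1, 2, 3, 4, 5, 6])
        skewed = run([1, 5, 5, 5, 6, 6, 6, 6, 2, 3, 4, 6])
        assert balanced["quadratic"] == pytest.approx(g2, abs=1e-6)
        assert skewed["quadratic"] == pytest.approx(g2, abs=1e-6)
        assert balanced["linear"] == pytest.approx(skewed["linear"], abs=1e-6)


class TestEndToEndGainRecovery:
    def _spec(self, noise):
        return synth.NeuralSpec(
            linear_gain={t: 0.3 for t in TASKS},
            quadratic_gain={
                "discrimination": 0.1,
                "detection": 0.2,
                "tilt_recognition": 0.4,
            },
            noise_sd=noise,
        )

    def test_noise_free_bias_under_5_percent_both_routes(self, small_session):
        t = small_session
        # QC route: all tasks modulated at once, every gain recovered
        y, _ = synth.simulate_roi_timeseries(t, self._spec(0.0), 0)
        fit = glm.fit_glm(y, glm.build_qc_dm(t))
        qc = glm.qc_gain_estimates(fit, t)
        for task in TASKS:
            truth = self._spec(0.0).quadratic_gain[task]
            for response in RESPONSES[task]:
                assert abs(qc.loc[response, "quadratic"] - truth) < 0.05 * truth
                assert abs(qc.loc[response, "linear"] - 0.3) < 0.05 * 0.3
        # categorical route: modulation on the analysed task (the other
        # tasks' evoked responses sit in its baseline/nuisance columns)
        for task in TASKS:
            truth = self._spec(0.0).quadratic_gain[task]
            spec = synth.NeuralSpec(
                linear_gain={k: 0.3 if k == task else 0.0 for k in TASKS},
                quadratic_gain={k: truth if k == task else 0.0 for k in TASKS},
                noise_sd=0.0,
            )
            y_task, _ = synth.simulate_roi_timeseries(t, spec, 0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dm_cat = glm.build_categorical_dm(t, task)
                fit_cat = glm.fit_glm(y_task, dm_cat, allow_rank_deficient=True)
                est = glm.two_step_polyfit(
                    glm.categorical_betas_by_response(fit_cat, dm_cat)
                )
                cat = glm.categorical_gain_estimates(est, t)
            for response in RESPONSES[task]:
                assert abs(cat.loc[response, "quadratic"] - truth) < 0.05 * truth
                assert abs(cat.loc[response, "linear"] - 0.3) < 0.05 * 0.3

    def test_noisy_recovery_within_ci_both_routes(self):
        design = synth.SessionDesign(runs=3)
        est_qc, est_cat = [], []
        for seed in range(20):
            t = synth.simulate_session(design, lapse_rate=0.0, seed=300 + seed)
            y, _ = synth.simulate_roi_timeseries(t, self._spec(1.0), seed)
            fit = glm.fit_glm(y, glm.build_qc_dm(t))
            qc = glm.qc_gain_estimates(fit, t)
            est_qc.append(qc.loc[["yes", "no"], "quadratic"].mean())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dm_cat = glm.build_categorical_dm(t, "detection")
                fit_cat = glm.fit_glm(y, dm_cat, allow_rank_deficient=True)
                est = glm.two_step_polyfit(
                    glm.categorical_betas_by_response(fit_cat, dm_cat)
                )
            est_cat.append(est.coefficients["quadratic"].mean())
        for values in (est_qc, est_cat):
            m = np.mean(values)
            half = 2.09 * np.std(values, ddof=1) / np.sqrt(len(values))
            assert m - half <= 0.2 <= m + half


@pytest.fixture(scope="module")
def estimates():
    rng = np.random.default_rng(4)
    n = 35
    return pd.DataFrame(
        {
            "quad_discrimination": rng.normal(0.1, 0.05, n),
            "quad_detection": rng.normal(0.1, 0.05, n),
            "quad_tilt_recognition": rng.normal(0.3, 0.05, n),
        }
    )


class TestGroupContrasts:

    def test_identical_conditions_give_zero_t(self, estimates):
        st = glm.group_contrast(
            estimates,
            {"quad_detection": 1.0, "quad_detection": -0.0},  # noqa: F601
        )
        same = estimates.assign(copy=estimates["quad_detection"])
        st = glm.group_contrast(same, {"quad_detection": 1.0, "copy": -1.0})
        assert st.t == 0.0

    def test_simulated_tilt_specific_gain_detected(self, estimates):
        st = glm.group_contrast(
            estimates,
            {"quad_tilt_recognition": 1.0, "quad_discrimination": -1.0},
        )
        assert st.p < 0.001 and st.t > 0

    def test_three_task_anova_df(self, estimates):
        st = glm.group_anova(
            estimates,
            ["quad_discrimination", "quad_detection", "quad_tilt_recognition"],
        )
        assert (st.df1, st.df2) == (2, 68)

    def test_unknown_labels_rejected(self, estimates):
        with pytest.raises(KeyError):
            glm.group_contrast(estimates, {"nope": 1.0})
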