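"""Tests for the synthetic cohort and weighing-trace generator."""

import numpy as np
import pandas as pd
import pytest

from hydrohaw.cohort import (
    CohortConfig,
    TraceConfig,
    cohort_to_frame,
    generate_cohort,
    make_study,
    table1_calibration,
    write_cohort_csv,
    write_traces_csv,
)
from hydrohaw.densitometry import HV_COEFFICIENTS, Sex, body_density_hbw, water_density
from hydrohaw.traces import extract_trial, qc_session


class TestDeterminism:
    def test_same_seed_identical_cohorts(self):
        cfg = CohortConfig(sex=Sex.MALE, n=20, seed=99)
        a = cohort_to_frame(generate_cohort(cfg))
        b = cohort_to_frame(generate_cohort(cfg))
        pd.testing.assert_frame_equal(a, b)

    def test_enlarging_cohort_keeps_earlier_subjects(self):
        small = cohort_to_frame(generate_cohort(CohortConfig(sex=Sex.FEMALE, n=5, seed=7)))
        big = cohort_to_frame(generate_cohort(CohortConfig(sex=Sex.FEMALE, n=12, seed=7)))
        pd.testing.assert_frame_equal(small, big.iloc[:5].reset_index(drop=True))

    def test_traces_deterministic(self):
        cfg = CohortConfig(sex=Sex.MALE, n=3, seed=5)
        a = generate_cohort(cfg, with_traces=True)
        b = generate_cohort(cfg, with_traces=True)
        for s1, s2 in zip(a, b):
            for t1, t2 in zip(s1.traces, s2.traces):
                assert np.array_equal(t1.samples, t2.samples)


class TestCalibration:
    def test_factor_mode_marginals_match_accept_reject_oracle(self):
        """The per-subject generator agrees with an independent vectorised
        accept-reject simulation of the same truncated factor model.

        The asymmetric observed ranges shift means and attenuate the
        factor correlation, so the oracle — not the nominal calibration —
        is the reference; nominal values are approached only loosely.
        """
        n = 12_000
        cfg = CohortConfig(sex=Sex.MALE, n=n, seed=42, hv_mode="factor")
        df = cohort_to_frame(generate_cohort(cfg))
        cal = table1_calibration(Sex.MALE, "exp")
        mwdh = df["mw_haw_kg"] - df["mw_hbw_kg"]
        hg = df["head_girth_cm"]

        rng = np.random.default_rng(123456)
        reps = 200_000
        z = rng.standard_normal(reps)
        mw = cal["mwdh_kg"]
        sims = {"mwdh_kg": mw.mean + mw.sd * z}
        keep = (sims["mwdh_kg"] >= mw.min) & (sims["mwdh_kg"] <= mw.max)
        for name, c in cal.items():
            if name == "mwdh_kg":
                continue
            eps = rng.standard_normal(reps)
            v = c.mean + c.sd * (c.r_mwdh * z + np.sqrt(1 - c.r_mwdh**2) * eps)
            sims[name] = v
            keep &= (v >= c.min) & (v <= c.max)
        hg_sim = sims["head_girth_cm"][keep]
        mwdh_sim = sims["mwdh_kg"][keep]

        assert hg.mean() == pytest.approx(hg_sim.mean(), abs=0.06)
        assert hg.std() == pytest.approx(hg_sim.std(ddof=1), rel=0.04)
        assert mwdh.mean() == pytest.approx(mwdh_sim.mean(), abs=0.02)
        assert np.corrcoef(hg, mwdh)[0, 1] == pytest.approx(
            np.corrcoef(hg_sim, mwdh_sim)[0, 1], abs=0.03)
        # nominal calibration is approached up to the truncation shift
        assert hg.mean() == pytest.approx(cal["head_girth_cm"].mean, abs=0.3)
        assert mwdh.mean() == pytest.approx(mw.mean, abs=0.1)

    def test_untruncated_factor_correlation_matches_calibration(self):
        """With range truncation disabled the predictor–MWDH correlation is
        the calibrated one."""
        cal = table1_calibration(Sex.MALE, "exp")
        wide = {}
        for name, c in cal.items():
            wide[name] = type(c)(mean=c.mean, sd=c.sd, min=-1e9, max=1e9,
                                 r_mwdh=c.r_mwdh)
        cfg = CohortConfig(sex=Sex.MALE, n=5000, seed=42, hv_mode="factor",
                           calibration=wide)
        df = cohort_to_frame(generate_cohort(cfg))
        mwdh = df["mw_haw_kg"] - df["mw_hbw_kg"]
        assert np.corrcoef(df["head_girth_cm"], mwdh)[0, 1] == pytest.approx(
            0.72, abs=0.03)
        assert df["head_girth_cm"].mean() == pytest.approx(57.7, abs=4 * 1.7 / np.sqrt(5000))

    def test_perfect_factor_correlation_is_affine(self):
        cal = table1_calibration(Sex.MALE, "exp")
        cal["mass_kg"] = type(cal["mass_kg"])(mean=83.3, sd=10.6, min=-1e6, max=1e6,
                                              r_mwdh=1.0)
        cal["mwdh_kg"] = type(cal["mwdh_kg"])(mean=4.11, sd=0.38, min=-1e6, max=1e6,
                                              r_mwdh=1.0)
        cfg = CohortConfig(sex=Sex.MALE, n=50, seed=3, hv_mode="factor",
                           calibration=cal)
        df = cohort_to_frame(generate_cohort(cfg))
        mwdh = df["mw_haw_kg"] - df["mw_hbw_kg"]
        resid = np.polyfit(mwdh, df["mass_kg"], 1, full=True)[1]
        assert float(resid[0]) == pytest.approx(0.0, abs=1e-18)

    def test_subjects_within_calibration_ranges(self):
        cfg = CohortConfig(sex=Sex.FEMALE, n=200, seed=21, hv_mode="factor")
        df = cohort_to_frame(generate_cohort(cfg))
        cal = table1_calibration(Sex.FEMALE, "exp")
        for name in ("age_y", "height_cm", "mass_kg", "head_girth_cm", "face_girth_cm"):
            assert df[name].between(cal[name].min, cal[name].max).all()


class TestGroundTruthConsistency:
    def test_buskirk_identity_holds_exactly(self):
        """Implied immersed weights reproduce the drawn density exactly."""
        subjects = generate_cohort(CohortConfig(sex=Sex.FEMALE, n=25, seed=13))
        for s in subjects:
            db = body_density_hbw(s.anthropometrics.mass_kg, s.mw_hbw_kg, s.dw, s.rv_l)
            assert db == pytest.approx(s.true_db, abs=1e-12)
            mwdh = s.mw_haw_kg - s.mw_hbw_kg
            assert mwdh / s.dw == pytest.approx(s.true_hv_l, abs=1e-12)

    def test_noiseless_equation_mode_recovers_published_coefficients(self):
        from hydrohaw.regression import fit_ols
        from hydrohaw.pipeline import prepare_subject_table

        cfg = CohortConfig(sex=Sex.FEMALE, n=40, seed=8, hv_noise_sd=0.0)
        df = cohort_to_frame(generate_cohort(cfg))
        df = prepare_subject_table(df)
        model = fit_ols(df, "hv_imm_l", ["head_girth_cm", "face_girth_cm", "mass_kg"])
        (b_hg, b_fg, b_ma), b0 = HV_COEFFICIENTS[Sex.FEMALE]
        assert model.coefficients == pytest.approx([b_hg, b_fg, b_ma], abs=1e-8)
        assert model.intercept == pytest.approx(b0, abs=1e-7)


class TestTraces:
    def test_noiseless_traces_recover_masses_exactly(self):
        trace_cfg = TraceConfig(haw_noise_sd=0.0, hbw_noise_sd=0.0, trial_jitter_sd=0.0)
        cfg = CohortConfig(sex=Sex.MALE, n=4, seed=31, trace=trace_cfg)
        subjects = generate_cohort(cfg, with_traces=True)
        for s in subjects:
            trial = extract_trial(s.traces[0])
            assert trial.haw.mean == pytest.approx(s.mw_haw_kg, abs=1e-12)
            assert trial.hbw.mean == pytest.approx(s.mw_hbw_kg, abs=1e-12)

    def test_default_noise_recovery_within_standard_error(self):
        cfg = CohortConfig(sex=Sex.MALE, n=12, seed=77)
        subjects = generate_cohort(cfg, with_traces=True)
        tc = cfg.trace
        tol = 3 * np.sqrt(tc.haw_noise_sd**2 / 100 + tc.trial_jitter_sd**2)
        for s in subjects:
            trial = extract_trial(s.traces[0])
            assert abs(trial.haw.mean - s.mw_haw_kg) < tol

    def test_session_pipeline_passes_qc_at_defaults(self):
        cfg = CohortConfig(sex=Sex.FEMALE, n=8, seed=55)
        subjects = generate_cohort(cfg, with_traces=True)
        passed = 0
        for s in subjects:
            trials = [extract_trial(t) for t in s.traces]
            passed += qc_session(trials).qc_pass
        assert passed >= 6   # default jitter rarely trips the 0.5 kg rule

    def test_high_jitter_failure_rate_matches_oracle(self):
        """QC failure frequency under heavy jitter matches a direct simulation."""
        jitter = 0.4
        n = 400
        tc = TraceConfig(trial_jitter_sd=jitter)
        cfg = CohortConfig(sex=Sex.MALE, n=n, seed=909, trace=tc)
        subjects = generate_cohort(cfg, with_traces=True)
        fails = 0
        for s in subjects:
            trials = [extract_trial(t) for t in s.traces]
            fails += not qc_session(trials).qc_pass
        rate = fails / n
        # oracle: a trial's phase mean ~ N(level, jitter^2 + noise^2/100);
        # the session fails if either phase's 3-trial range exceeds 0.5 kg
        rng = np.random.default_rng(1000)
        reps = 200_000
        ok = np.ones(reps, bool)
        for noise in (tc.haw_noise_sd, tc.hbw_noise_sd):
            sd = np.sqrt(jitter**2 + noise**2 / 100)
            draws = rng.normal(0, sd, size=(reps, 3))
            ok &= (draws.max(axis=1) - draws.min(axis=1)) <= 0.5
        oracle_rate = 1 - ok.mean()
        assert rate == pytest.approx(oracle_rate, abs=0.08)


class TestMakeStudy:
    def test_disjoint_seeds_required(self):
        cfg = CohortConfig(sex=Sex.MALE, n=10, seed=1)
        with pytest.raises(ValueError, match="disjoint seeds"):
            make_study(cfg, cfg)

    def test_truth_reports_generator_equation(self):
        exp_cfg = CohortConfig(sex=Sex.MALE, n=12, seed=1)
        val_cfg = CohortConfig(sex=Sex.MALE, n=12, seed=2, group="val")
        _, _, truth = make_study(exp_cfg, val_cfg)
        (coeffs, b0) = HV_COEFFICIENTS[Sex.MALE]
        assert truth.hv_coefficients == coeffs
        assert truth.hv_intercept == b0
        assert truth.dw == pytest.approx(water_density(exp_cfg.water_temp_c))


def test_csv_writers(tmp_path):
    cfg = CohortConfig(sex=Sex.MALE, n=3, seed=2, trace=TraceConfig(trials_per_subject=2))
    subjects = generate_cohort(cfg, with_traces=True)
    write_cohort_csv(subjects, tmp_path / "subjects.csv")
    write_traces_csv(subjects, tmp_path / "traces.csv")
    subj = pd.read_csv(tmp_path / "subjects.csv")
    traces = pd.read_csv(tmp_path / "traces.csv")
    assert len(subj) == 3
    assert set(traces["trial_id"]) == {"t0", "t1"}
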