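"""Tests for exclusions, coding, mixed models and boundary-effect machinery."""

import numpy as np
import pandas as pd
import pytest

import cueweight as cw
from cueweight import perception_analysis as pa


def _cued_sim(rng, n_agents=6, w=0.3, noise_sd=4.0, shared_w=True, reps=1):
    """Small cued-perception cohort; returns (sr_trials, cued_trials)."""
    sr_tabs, cued_tabs = [], []
    for sid in range(n_agents):
        wi = w if shared_w else float(rng.uniform(0.05, 0.8))
        agent = cw.AgentParams(integration_weight=wi, noise_sd=noise_sd)
        sr = cw.make_stimulus_response_design(rng, subject_id=sid)
        sr_tabs.append(
            cw.synthetic_agents.simulate_sr_ratings(sr, agent, rng))
        d = cw.make_cued_perception_design(rng, reps, subject_id=sid)
        cued_tabs.append(cw.simulate_perception_ratings(d, agent, rng))
    return (pd.concat(sr_tabs, ignore_index=True),
            pd.concat(cued_tabs, ignore_index=True))


class TestRtExclusions:
    def test_thresholds(self):
        trials = pd.DataFrame({"rt": [0.1, 1.0, 4.6]})
        kept, report = pa.apply_rt_exclusions(trials)
        assert list(kept.rt) == [1.0]
        assert report.n_too_fast.iloc[0] == 1
        assert report.n_too_slow.iloc[0] == 1

    def test_boundaries_inclusive(self):
        trials = pd.DataFrame({"rt": [0.2, 4.5]})
        kept, _ = pa.apply_rt_exclusions(trials)
        assert len(kept) == 2

    def test_missing_rt_kept_and_counted(self):
        trials = pd.DataFrame({"rt": [np.nan, 1.0]})
        kept, report = pa.apply_rt_exclusions(trials)
        assert len(kept) == 2
        assert report.n_missing_rt.iloc[0] == 1

    def test_no_exclusions_when_all_in_range(self, rng):
        trials = pd.DataFrame({"rt": rng.uniform(0.3, 4.0, 50)})
        kept, report = pa.apply_rt_exclusions(trials)
        assert len(kept) == 50
        assert report.n_kept.iloc[0] == 50


class TestModelMatrix:
    @pytest.fixture()
    def trials(self, rng):
        _, cued = _cued_sim(rng, n_agents=3)
        return cued[cued.modality == "pain"]

    def test_pm1_coding(self, trials):
        mm = pa.build_model_matrix(trials, {"cue_sd": "pm1"}, interactions=None)
        assert set(mm.X["cue_sd"]) == {-1.0, 1.0}
        high = trials.cue_sd == 12.5
        assert (mm.X.loc[high, "cue_sd"] == 1.0).all()

    def test_skew_dummies_reference_symmetric(self, trials):
        mm = pa.build_model_matrix(trials, {"cue_skew": "skew"},
                                   interactions=None)
        sym = trials.cue_skew == "symmetric"
        assert (mm.X.loc[sym, ["cue_skew_neg", "cue_skew_pos"]] == 0).all().all()
        assert (mm.X.loc[trials.cue_skew == "negative", "cue_skew_neg"] == 1).all()

    def test_zscored_columns(self, trials):
        mm = pa.build_model_matrix(trials, {"trial_overall": "zscore"},
                                   interactions=None)
        col = mm.X["trial_overall"]
        assert col.mean() == pytest.approx(0.0, abs=1e-9)
        assert col.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_interaction_products(self, trials):
        mm = pa.build_model_matrix(
            trials, {"cue_mean": "pm1", "cue_sd": "pm1"}, interactions="all")
        np.testing.assert_allclose(mm.X["cue_mean:cue_sd"],
                                   mm.X["cue_mean"] * mm.X["cue_sd"])

    def test_unknown_level_raises(self, trials):
        bad = trials.copy()
        bad.loc[bad.index[0], "cue_skew"] = "bimodal"
        with pytest.raises(ValueError, match="bimodal"):
            pa.build_model_matrix(bad, {"cue_skew": "skew"}, interactions=None)


class TestFitLmm:
    def test_noiseless_recovery_intercept_randoms(self, rng):
        # subject intercepts + exact common slopes, no residual noise
        n_subj, n_tr = 8, 40
        rows = []
        for sid in range(n_subj):
            x1 = rng.choice([-1.0, 1.0], n_tr)
            x2 = rng.normal(0, 1, n_tr)
            y = 2.0 + 0.5 * sid + 0.8 * x1 - 0.3 * x2
            rows.append(pd.DataFrame({
                "subject_id": sid, "x1": x1, "x2": x2, "y": y}))
        df = pd.concat(rows, ignore_index=True)
        mm = pa.ModelMatrix(y=df.y, X=df[["x1", "x2"]], groups=df.subject_id)
        table = pa.fit_lmm(mm, random_spec=[])
        assert table.loc["x1", "beta"] == pytest.approx(0.8, abs=1e-6)
        assert table.loc["x2", "beta"] == pytest.approx(-0.3, abs=1e-6)

    def test_balanced_no_random_slope_matches_ols(self, rng):
        n_subj, n_tr = 6, 30
        rows = []
        for sid in range(n_subj):
            x = np.tile([-1.0, 1.0], n_tr // 2)
            y = 0.4 * x + rng.normal(0, 0.5, n_tr)
            rows.append(pd.DataFrame({"subject_id": sid, "x": x, "y": y}))
        df = pd.concat(rows, ignore_index=True)
        mm = pa.ModelMatrix(y=df.y, X=df[["x"]], groups=df.subject_id)
        table = pa.fit_lmm(mm, random_spec=[])
        ols_slope = np.polyfit(df.x, df.y, 1)[0]
        # balanced design with shared slope: GLS and OLS coincide
        assert table.loc["x", "beta"] == pytest.approx(ols_slope, abs=1e-6)

    def test_simulation_coverage_of_known_effect(self):
        """True effect recovered within 2 SE in >= 95% of simulations."""
        hits = 0
        n_sim = 100
        rng = np.random.default_rng(7)
        for _ in range(n_sim):
            rows = []
            for sid in range(20):
                x = rng.choice([-1.0, 1.0], 24)
                y = (0.25 + rng.normal(0, 0.1)) * x + rng.normal(0, 1, 24)
                rows.append(pd.DataFrame({"subject_id": sid, "x": x, "y": y}))
            df = pd.concat(rows, ignore_index=True)
            mm = pa.ModelMatrix(y=df.y, X=df[["x"]], groups=df.subject_id)
            table = pa.fit_lmm(mm, random_spec=["x"])
            beta, se = table.loc["x", "beta"], table.loc["x", "se"]
            if abs(beta - 0.25) <= 2 * se:
                hits += 1
        assert hits >= 95

    def test_random_structure_reported(self, rng):
        _, cued = _cued_sim(rng, n_agents=4)
        sub = cued[cued.modality == "pain"]
        mm = pa.build_model_matrix(sub, {"cue_mean": "pm1"}, interactions=None)
        table = pa.fit_lmm(mm, random_spec="maximal")
        assert "random_structure" in table.attrs


class TestSubjectiveValues:
    def test_cell_means(self):
        sr = pd.DataFrame({
            "subject_id": [0, 0, 0], "modality": ["pain"] * 3,
            "stimulus_intensity": [45.0, 45.0, 46.0],
            "rating": [40.0, 50.0, 70.0]})
        out = pa.subjective_stimulus_values(sr)
        cell = out[(out.stimulus_intensity == 45.0)]
        assert cell.subjective_value.iloc[0] == 45.0
        single = out[(out.stimulus_intensity == 46.0)]
        assert single.subjective_value.iloc[0] == 70.0

    def test_full_design_yields_ten_cells(self, rng):
        agent = cw.AgentParams(noise_sd=0.0)
        sr = cw.make_stimulus_response_design(rng, subject_id=0)
        sim = cw.synthetic_agents.simulate_sr_ratings(sr, agent, rng)
        out = pa.subjective_stimulus_values(sim)
        assert len(out) == 10  # 2 modalities x 5 intensities

    def test_interpolation_extends_map(self, rng):
        agent = cw.AgentParams(noise_sd=0.0)
        sr = cw.make_stimulus_response_design(rng, subject_id=0)
        sim = cw.synthetic_agents.simulate_sr_ratings(sr, agent, rng)
        out = pa.interpolate_subjective_values(
            pa.subjective_stimulus_values(sim), {"vision": [60.0]})
        row = out[(out.modality == "vision") & (out.stimulus_intensity == 60.0)]
        # noiseless identity map: interpolated value equals the contrast
        assert row.subjective_value.iloc[0] == pytest.approx(60.0, abs=1e-9)


class TestBoundaryVariables:
    def test_arithmetic(self):
        cued = pd.DataFrame({
            "subject_id": [0], "modality": ["pain"],
            "stimulus_intensity": [47.0], "cue_mean": [30.0],
            "rating": [48.0]})
        sub = pd.DataFrame({
            "subject_id": [0], "modality": ["pain"],
            "stimulus_intensity": [47.0], "subjective_value": [55.0]})
        out = pa.boundary_variables(cued, sub)
        assert out.cue_pe.iloc[0] == 25.0
        assert out.experienced_pe.iloc[0] == -7.0

    def test_rating_reconstruction_identity(self, rng):
        sr, cued = _cued_sim(rng, n_agents=3)
        sub = pa.interpolate_subjective_values(
            pa.subjective_stimulus_values(sr),
            {"pain": [47.0, 48.0], "vision": [50.0, 60.0]})
        out = pa.boundary_variables(cued, sub)
        np.testing.assert_allclose(out.experienced_pe + out.subjective_value,
                                   out.rating, atol=1e-9)

    def test_uncovered_cell_raises(self):
        cued = pd.DataFrame({
            "subject_id": [0], "modality": ["pain"],
            "stimulus_intensity": [48.0], "cue_mean": [30.0],
            "rating": [48.0]})
        sub = pd.DataFrame({
            "subject_id": [0], "modality": ["pain"],
            "stimulus_intensity": [47.0], "subjective_value": [55.0]})
        with pytest.raises(ValueError, match="48"):
            pa.boundary_variables(cued, sub)


class TestBoundaryModel:
    def _linear_assimilation_data(self, rng, slope=-0.4, n_subj=20, n_tr=100,
                                  noise=2.0):
        rows = []
        for sid in range(n_subj):
            cue_pe = rng.uniform(-40, 40, n_tr)
            epe = (slope * cue_pe + rng.normal(0, 2)  # random intercept
                   + rng.normal(0, noise, n_tr))
            rows.append(pd.DataFrame({
                "subject_id": sid, "modality": "pain",
                "trial_overall": np.arange(1, n_tr + 1),
                "cue_pe": cue_pe, "experienced_pe": epe}))
        return pd.concat(rows, ignore_index=True)

    def test_linear_generating_slope_recovered(self, rng):
        df = self._linear_assimilation_data(rng)
        table = pa.fit_boundary_model(df, complex_model=False)
        assert table.loc["cue_pe", "beta"] == pytest.approx(
            -0.4, abs=2 * table.loc["cue_pe", "se"])
        for term in ("cue_pe^2", "cue_pe^3"):
            assert abs(table.loc[term, "beta"]) <= 2.5 * table.loc[term, "se"]

    def test_zero_experienced_pe_gives_zero_coefficients(self, rng):
        df = self._linear_assimilation_data(rng, slope=0.0, noise=0.0)
        df["experienced_pe"] = 0.0
        table = pa.fit_boundary_model(df, complex_model=False)
        assert np.allclose(table.beta, 0.0, atol=1e-8)

    def test_complex_model_terms_present(self, rng):
        df = self._linear_assimilation_data(rng, n_subj=8, n_tr=40)
        table = pa.fit_boundary_model(df, complex_model=True)
        assert {"cue_pe^4", "trial", "cue_pe^3:trial"} <= set(table.index)

    def test_hard_boundary_detected_by_cubic(self, rng):
        # assimilation flat beyond |cue_pe| > 25: cubic term must pick it up
        detections = 0
        n_sim = 20
        for _ in range(n_sim):
            rows = []
            for sid in range(20):
                cue_pe = rng.uniform(-40, 40, 100)
                effect = np.where(np.abs(cue_pe) > 25, 0.0, -0.5 * cue_pe)
                epe = effect + rng.normal(0, 2, 100)
                rows.append(pd.DataFrame({
                    "subject_id": sid, "modality": "pain",
                    "trial_overall": np.arange(100),
                    "cue_pe": cue_pe, "experienced_pe": epe}))
            df = pd.concat(rows, ignore_index=True)
            table = pa.fit_boundary_model(df, complex_model=False)
            if table.loc["cue_pe^3", "p"] < 0.05:
                detections += 1
        assert detections >= 0.8 * n_sim


class TestCueEffectCorrelation:
    def test_identical_effect_vectors(self, rng):
        sr, cued = _cued_sim(rng, n_agents=6, shared_w=False)
        pain = cued[cued.modality == "pain"]
        out = pa.subject_cue_effect_correlation(pain, pain.copy())
        assert out["r"] == pytest.approx(1.0)

    def test_shared_integration_weight_gives_positive_r(self, rng):
        sr, cued = _cued_sim(rng, n_agents=12, shared_w=False, noise_sd=2.0)
        out = pa.subject_cue_effect_correlation(
            cued[cued.modality == "pain"], cued[cued.modality == "vision"])
        assert out["r"] > 0.5

    def test_too_few_subjects_raises(self, rng):
        sr, cued = _cued_sim(rng, n_agents=2)
        with pytest.raises(ValueError):
            pa.subject_cue_effect_correlation(
                cued[cued.modality == "pain"],
                cued[cued.modality == "vision"])
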