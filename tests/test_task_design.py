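"""Tests for cue generation and the three factorial task designs."""

import numpy as np
import pytest
from scipy.stats import skew

import cueweight as cw
from cueweight.task_design import (
    CUE_SDS,
    CueGenerationError,
    EXPECTATION_MEANS,
    SKEW_CLASSES,
    sample_base_values,
)

CUE_COLS = [f"cue_v{i}" for i in range(1, 11)]


class TestStandardizeMoments:
    def test_two_point_affine(self):
        np.testing.assert_allclose(
            cw.standardize_moments([0.0, 1.0], 50.0, 5.0), [45.0, 55.0])

    def test_exact_target_moments(self, rng):
        for _ in range(50):
            v = rng.normal(30, 9, size=10)
            out = cw.standardize_moments(v, 62.5, 7.25)
            assert out.mean() == pytest.approx(62.5, abs=1e-9)
            assert out.std() == pytest.approx(7.25, abs=1e-9)

    def test_skewness_invariant_under_affine(self, rng):
        v = rng.lognormal(0, 0.6, size=10)
        out = cw.standardize_moments(v, 40.0, 12.5)
        assert skew(out, bias=False) == pytest.approx(
            skew(v, bias=False), abs=1e-9)

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError):
            cw.standardize_moments(np.full(10, 3.0), 50, 5)


class TestSampleBaseValues:
    def test_skewed_draw_contains_injected_extreme(self, rng):
        spec = cw.CueSpec(30, 12.5, "positive")
        v = sample_base_values(spec, rng)
        base, extreme = v[:9], v[9]
        z = (extreme - base.mean()) / base.std()
        assert 2.0 <= z <= 2.5

    def test_negative_skew_extreme_below_mean(self, rng):
        v = sample_base_values(cw.CueSpec(50, 5, "negative"), rng)
        base, extreme = v[:9], v[9]
        z = (base.mean() - extreme) / base.std()
        assert 2.0 <= z <= 2.5

    def test_seeded_determinism(self):
        spec = cw.CueSpec(50, 5, "symmetric")
        a = sample_base_values(spec, np.random.default_rng(2))
        b = sample_base_values(spec, np.random.default_rng(2))
        np.testing.assert_array_equal(a, b)


class TestGenerateCue:
    @pytest.mark.parametrize("skew_class, check", [
        ("negative", lambda s: s < -0.3),
        ("positive", lambda s: s > 0.3),
        ("symmetric", lambda s: -0.035 <= s <= 0.035),
    ])
    def test_skewness_bands_and_moments(self, rng, skew_class, check):
        for mean in (30.0, 50.0, 70.0):
            for sd in CUE_SDS:
                for _ in range(20):
                    cue = cw.generate_cue(cw.CueSpec(mean, sd, skew_class), rng)
                    v = cue.array
                    assert len(v) == 10
                    assert v.min() >= 0 and v.max() <= 100
                    assert v.mean() == pytest.approx(mean, abs=1e-9)
                    assert v.std() == pytest.approx(sd, abs=1e-9)
                    assert check(cue.skewness)

    @pytest.mark.parametrize("skew_class", ["negative", "positive"])
    def test_skewed_cue_contains_extreme_value(self, rng, skew_class):
        # leave-one-out z-score is affine invariant, so the injected
        # extreme keeps its >= 2 SD offset through standardization
        for _ in range(20):
            cue = cw.generate_cue(cw.CueSpec(50, 5, skew_class), rng)
            v = cue.array
            i = v.argmin() if skew_class == "negative" else v.argmax()
            rest = np.delete(v, i)
            z = abs(v[i] - rest.mean()) / rest.std()
            assert z >= 2.0

    def test_reproducible_under_fixed_seed(self):
        spec = cw.CueSpec(50, 5, "symmetric")
        a = cw.generate_cue(spec, np.random.default_rng(7))
        b = cw.generate_cue(spec, np.random.default_rng(7))
        assert a.values == b.values

    def test_exhausted_attempts_reports_spec(self, rng):
        spec = cw.CueSpec(2.0, 12.5, "negative")  # extreme < 0 always: infeasible
        with pytest.raises(CueGenerationError) as err:
            cw.generate_cue(spec, rng, max_attempts=50)
        assert "2.0" in str(err.value)


class TestDesigns:
    def test_stimulus_response_structure(self, rng):
        d = cw.make_stimulus_response_design(rng)
        assert len(d) == 50
        pain = d[d.modality == "pain"]
        assert pain.groupby("stimulus_intensity").size().to_dict() == {
            45.0: 5, 46.0: 5, 47.0: 5, 48.0: 5, 49.0: 5}
        vision = d[d.modality == "vision"]
        assert set(vision.stimulus_intensity) == {5.0, 27.5, 50.0, 72.5, 95.0}
        assert d.cue_v1.isna().all()  # no cues in the calibration task

    def test_expectation_design_counts(self, rng):
        d = cw.make_expectation_design(rng, 6)
        assert len(d) == 360
        combos = d.groupby(["modality", "cue_mean", "cue_sd", "cue_skew"]).size()
        assert len(combos) == 60
        assert (combos == 6).all()
        assert d.stimulus_intensity.isna().all()
        # three consecutive blocks per modality
        block_mod = d.groupby("block")["modality"].nunique()
        assert (block_mod == 1).all()
        assert d.groupby("modality")["block"].nunique().to_dict() == {
            "pain": 3, "vision": 3}

    def test_expectation_design_single_rep(self, rng):
        assert len(cw.make_expectation_design(rng, 1)) == 60

    def test_cued_design_counts_and_blocks(self, rng):
        d = cw.make_cued_perception_design(rng, 3)
        assert len(d) == 144
        combos = d.groupby(["modality", "stimulus_intensity", "cue_mean",
                            "cue_sd", "cue_skew"]).size()
        assert len(combos) == 48
        assert (combos == 3).all()
        for _, block in d.groupby("block"):
            assert len(block) == 24
            # two single-modality mini-blocks of 12
            runs = (block.modality != block.modality.shift()).cumsum()
            assert runs.value_counts().to_dict() == {1: 12, 2: 12}

    def test_factor_orthogonality(self, rng):
        d = cw.make_expectation_design(rng, 2)
        codes = {
            "modality": d.modality.map({"pain": -1, "vision": 1}),
            "mean": d.cue_mean,
            "sd": d.cue_sd.map({5.0: -1, 12.5: 1}),
            "skew": d.cue_skew.map({"negative": -1, "symmetric": 0, "positive": 1}),
        }
        names = list(codes)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert abs(np.corrcoef(codes[a], codes[b])[0, 1]) < 1e-12

    def test_design_determinism(self):
        a = cw.make_cued_perception_design(np.random.default_rng(3), 1)
        b = cw.make_cued_perception_design(np.random.default_rng(3), 1)
        assert a.equals(b)

    def test_cues_in_design_satisfy_constraints(self, rng):
        d = cw.make_expectation_design(rng, 1)
        vals = d[CUE_COLS].to_numpy(float)
        assert np.allclose(vals.mean(axis=1), d.cue_mean, atol=1e-9)
        assert np.allclose(vals.std(axis=1), d.cue_sd, atol=1e-9)
        sk = skew(vals, axis=1, bias=False)
        neg = d.cue_skew == "negative"
        pos = d.cue_skew == "positive"
        sym = d.cue_skew == "symmetric"
        assert (sk[neg] < -0.3).all()
        assert (sk[pos] > 0.3).all()
        assert (np.abs(sk[sym]) <= 0.035).all()
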