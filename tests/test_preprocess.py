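import numpy as np
import pytest

from morphprint import age_correct, fit_age_model, normalize
from morphprint.errors import MissingDataError, ProvenanceError, ValidationError
from morphprint.preprocess import AgeModel, preprocess_pipeline

from conftest import make_table

KEY = ("Hippocampus", "left", "volume")


def linear_controls(ages, slope=-0.5, intercept=100.0, region_rows=None):
    rows = []
    subjects = {}
    for i, age in enumerate(ages):
        sid = f"c{i}"
        subjects[sid] = {"age": float(age)}
        rows.append((sid, "Hippocampus", "left", "volume", intercept + slope * age))
        if region_rows:
            rows += [(sid, *r) for r in region_rows]
    return make_table(rows, subjects=subjects)


class TestFitAgeModel:
    def test_noiseless_linear_recovery(self):
        table = linear_controls([30, 40, 50, 60, 70])
        model = fit_age_model(table)
        assert model.params.loc[KEY, "slope"] == pytest.approx(-0.5, abs=1e-12)
        assert model.reference_age == pytest.approx(50.0)

    def test_constant_values_give_zero_slope(self):
        table = linear_controls([30, 40, 50], slope=0.0)
        model = fit_age_model(table)
        assert model.params.loc[KEY, "slope"] == 0.0

    def test_noisy_recovery_within_sampling_error(self, rng):
        # oracle: OLS slope sampling SD = noise_sd / (sd(age) * sqrt(n))
        n, true_slope, noise_sd = 100, -2.0, 5.0
        ages = rng.uniform(20, 80, n)
        rows = []
        subjects = {}
        for i in range(n):
            sid = f"c{i}"
            subjects[sid] = {"age": float(ages[i])}
            value = 4000.0 + true_slope * ages[i] + rng.normal(0, noise_sd)
            rows.append((sid, "Hippocampus", "left", "volume", value))
        model = fit_age_model(make_table(rows, subjects=subjects))
        se = noise_sd / (ages.std() * np.sqrt(n))
        assert abs(model.params.loc[KEY, "slope"] - true_slope) < max(0.5, 4 * se)

    def test_too_few_controls_forces_zero_slope(self, caplog):
        table = linear_controls([40, 60])
        with caplog.at_level("WARNING"):
            model = fit_age_model(table)
        assert model.params.loc[KEY, "slope"] == 0.0
        assert "slope forced to 0" in caplog.text

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            fit_age_model(make_table([], subjects={"c0": {}}).select_subjects([]))

    def test_non_control_subjects_rejected(self):
        table = make_table(
            [("a1", "Hippocampus", "left", "volume", 4000.0)],
            subjects={"a1": {"group": "AD", "age": 70.0}},
        )
        with pytest.raises(ValidationError):
            fit_age_model(table)

    def test_tsv_round_trip(self, tmp_path):
        model = fit_age_model(linear_controls([30, 40, 50, 60]))
        path = tmp_path / "model.tsv"
        model.to_tsv(path)
        back = AgeModel.from_tsv(path)
        assert back.reference_age == model.reference_age
        assert np.allclose(back.params["slope"], model.params["slope"])


class TestAgeCorrect:
    def test_identity_at_reference_age(self):
        controls = linear_controls([30, 50, 70])
        model = fit_age_model(controls)
        probe = make_table(
            [("p1", "Hippocampus", "left", "volume", 123.0)],
            subjects={"p1": {"age": model.reference_age}},
        )
        corrected = age_correct(probe, model)
        assert corrected.data["value"].iloc[0] == pytest.approx(123.0)

    def test_arithmetic_by_definition(self):
        # slope -0.5, ten years past reference: 100 - (-0.5 * 10) = 105
        controls = linear_controls([30, 50, 70])
        model = fit_age_model(controls)
        probe = make_table(
            [("p1", "Hippocampus", "left", "volume", 100.0)],
            subjects={"p1": {"age": model.reference_age + 10.0}},
        )
        corrected = age_correct(probe, model)
        assert corrected.data["value"].iloc[0] == pytest.approx(105.0, abs=1e-9)

    def test_refit_after_self_correction_is_flat(self):
        controls = linear_controls([25, 35, 45, 55, 65, 75])
        model = fit_age_model(controls)
        corrected = age_correct(controls, model)
        refit = corrected.with_data(corrected.data, frozenset())
        assert abs(fit_age_model(refit).params.loc[KEY, "slope"]) < 1e-9

    def test_missing_key_errors(self):
        controls = linear_controls([30, 50, 70])
        model = fit_age_model(controls)
        probe = make_table([("p1", "Amygdala", "left", "volume", 1700.0)])
        with pytest.raises(MissingDataError):
            age_correct(probe, model)

    def test_requires_raw_table(self):
        controls = linear_controls([30, 50, 70])
        model = fit_age_model(controls)
        corrected = age_correct(controls, model)
        with pytest.raises(ProvenanceError):
            age_correct(corrected, model)


class TestNormalize:
    def _corrected(self, rows, subjects=None):
        from morphprint.io_morphometry import PROV_AGE_CORRECTED

        return make_table(rows, subjects=subjects, provenance=frozenset({PROV_AGE_CORRECTED}))

    def test_subfield_over_parent_ratio(self):
        table = self._corrected(
            [
                ("s1", "Fimbria", "left", "volume", 60.0),
                ("s1", "Whole hippocampus", "left", "volume", 3000.0),
            ]
        )
        out = normalize(table)
        values = out.data.set_index("region")["value"]
        assert values.loc["Fimbria"] == pytest.approx(0.02)

    def test_whole_hippocampus_over_icv(self):
        table = self._corrected(
            [("s1", "Whole hippocampus", "left", "volume", 4000.0)],
            subjects={"s1": {"icv": 1.6e6}},
        )
        out = normalize(table)
        assert out.data["value"].iloc[0] == pytest.approx(2.5e-3)

    def test_head_size_invariance(self):
        # identical regional fractions, different ICVs -> identical output
        table = self._corrected(
            [
                ("s1", "Hippocampus", "left", "volume", 1.4e6 * 0.0026),
                ("s2", "Hippocampus", "left", "volume", 1.8e6 * 0.0026),
            ],
            subjects={"s1": {"icv": 1.4e6}, "s2": {"icv": 1.8e6}},
        )
        out = normalize(table)
        v = out.data["value"]
        assert v.iloc[0] == pytest.approx(v.iloc[1], rel=1e-12)

    def test_icv_rescaling_invariance_exact(self):
        rows = [("s1", "Hippocampus", "left", "volume", 4000.0)]
        base = normalize(self._corrected(rows, subjects={"s1": {"icv": 1.5e6}}))
        scaled = normalize(
            self._corrected(
                [("s1", "Hippocampus", "left", "volume", 4000.0 * 2.0)],
                subjects={"s1": {"icv": 1.5e6 * 2.0}},
            )
        )
        assert scaled.data["value"].iloc[0] == base.data["value"].iloc[0]

    def test_thickness_passes_through(self):
        table = self._corrected([("s1", "Entorhinal", "left", "thickness", 3.2)])
        out = normalize(table)
        assert out.data["value"].iloc[0] == 3.2

    def test_refuses_raw_table(self):
        table = make_table([("s1", "Hippocampus", "left", "volume", 4000.0)])
        with pytest.raises(ProvenanceError):
            normalize(table)

    def test_refuses_double_normalization(self):
        table = self._corrected([("s1", "Hippocampus", "left", "volume", 4000.0)])
        out = normalize(table)
        with pytest.raises(ProvenanceError):
            normalize(out)

    def test_missing_parent_denominator_errors(self):
        table = self._corrected([("s1", "Fimbria", "left", "volume", 60.0)])
        with pytest.raises(MissingDataError, match="s1"):
            normalize(table)

    def test_hemisphere_matched_parent(self):
        table = self._corrected(
            [
                ("s1", "Fimbria", "left", "volume", 60.0),
                ("s1", "Fimbria", "right", "volume", 90.0),
                ("s1", "Whole hippocampus", "left", "volume", 3000.0),
                ("s1", "Whole hippocampus", "right", "volume", 4500.0),
            ]
        )
        out = normalize(table)
        values = out.data.set_index(["region", "hemisphere"])["value"]
        assert values.loc[("Fimbria", "left")] == pytest.approx(0.02)
        assert values.loc[("Fimbria", "right")] == pytest.approx(0.02)


def test_pipeline_order_and_provenance(default_sim):
    controls = default_sim.table.select_group("control")
    model = fit_age_model(controls)
    out = preprocess_pipeline(controls, model)
    assert out.provenance == {"age_corrected", "normalized"}


def test_post_correction_control_slopes_near_zero(default_sim):
    controls = default_sim.table.select_group("control")
    model = fit_age_model(controls)
    corrected = age_correct(controls, model)
    refit = fit_age_model(corrected.with_data(corrected.data, frozenset()))
    scale = np.maximum(np.abs(model.params["intercept"]), 1.0)
    assert (np.abs(refit.params["slope"]) / scale < 1e-6).all()
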