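import numpy as np
import pandas as pd
import pytest

from morphprint import default_cohort_config, null_config, simulate_cohorts
from morphprint.errors import ValidationError
from morphprint.io_morphometry import write_long_tsv
from morphprint.pipeline import derive_fingerprint
from morphprint.synthetic import (
    SpikeSpec,
    config_from_yaml,
    config_to_yaml,
)


class TestConfig:
    def test_default_demographics(self):
        config = default_cohort_config()
        exposed = config.cohorts["exposed"].age
        assert exposed.mean == 48.4 and exposed.sd == 12.2
        ad = config.cohorts["AD"].age
        assert ad.mean == 75.5 and ad.sd == 6.6
        control = config.cohorts["control"].age
        assert (control.low, control.high) == (18.0, 81.0)

    def test_default_disease_effects(self):
        config = default_cohort_config()
        assert config.region_effects[("Entorhinal", "volume")].effect("AD") == pytest.approx(0.73)
        assert config.region_effects[("Entorhinal", "thickness")].effect("AD") == pytest.approx(
            1 - 0.191
        )
        assert config.region_effects[("Inf-Lat-Vent", "volume")].effect("AD") == pytest.approx(
            2.247
        )
        assert config.region_effects[("Fimbria", "volume")].effect("AD") == pytest.approx(0.763)
        assert config.region_effects[("Hippocampal fissure", "volume")].effect(
            "AD"
        ) == pytest.approx(1.112)

    def test_every_registry_region_parameterized(self, registry):
        config = default_cohort_config()
        for desc in registry:
            for metric in desc.metrics:
                assert (desc.name, metric) in config.region_effects

    def test_validation_rejects_bad_fields(self):
        config = default_cohort_config()
        config.hemisphere_rho = 1.5
        with pytest.raises(ValidationError):
            config.validate()
        config = default_cohort_config()
        config.region_effects[("Entorhinal", "volume")].cv = 0.0
        with pytest.raises(ValidationError):
            config.validate()
        config = default_cohort_config()
        config.spike = SpikeSpec(prevalence=0.5, n_regions=3, regions=(("Nope", "volume"),))
        with pytest.raises(ValidationError):
            config.validate()

    def test_yaml_round_trip(self, tmp_path):
        config = default_cohort_config()
        path = tmp_path / "config.yaml"
        config_to_yaml(config, path)
        back = config_from_yaml(path)
        assert back.cohorts == config.cohorts
        assert back.region_effects == config.region_effects
        assert back.spike == config.spike
        assert back.cognition == config.cognition
        assert back.hemisphere_rho == config.hemisphere_rho


class TestDeterminism:
    def test_same_seed_bit_identical(self, tmp_path):
        config = default_cohort_config(n_control=12, n_ad=8, n_exposed=8)
        a = simulate_cohorts(config, seed=42)
        b = simulate_cohorts(config, seed=42)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_long_tsv(a.table, pa)
        write_long_tsv(b.table, pb)
        assert pa.read_bytes() == pb.read_bytes()
        assert a.anam.equals(b.anam)
        assert a.truth.subjects.equals(b.truth.subjects)

    def test_different_seeds_differ(self):
        config = default_cohort_config(n_control=12, n_ad=8, n_exposed=8)
        a = simulate_cohorts(config, seed=1)
        b = simulate_cohorts(config, seed=2)
        assert not a.table.data["value"].equals(b.table.data["value"])


class TestGeneratedStructure:
    def test_table_validates_against_registry(self, default_sim, registry):
        default_sim.table.validate(registry)

    def test_cohort_sizes_and_groups(self, default_sim):
        groups = default_sim.table.subjects["group"].value_counts()
        assert groups["control"] == 114
        assert groups["AD"] == 58
        assert groups["exposed"] == 46

    def test_ages_within_bounds(self, default_sim):
        subjects = default_sim.table.subjects
        control_ages = subjects.loc[subjects["group"] == "control", "age"]
        assert control_ages.between(18, 81).all()
        exposed_ages = subjects.loc[subjects["group"] == "exposed", "age"]
        assert exposed_ages.between(29, 75).all()

    def test_icv_coupling_removed_by_normalization(self, default_sim, derived):
        controls = default_sim.table.select_group("control")
        raw = controls.data
        icv = controls.subjects["icv"]
        key = raw[(raw["region"] == "Hippocampus") & (raw["hemisphere"] == "left")]
        raw_corr = np.corrcoef(key.set_index("subject_id")["value"].reindex(icv.index), icv)[0, 1]
        assert raw_corr > 0.5
        norm = derived["controls_n"].data
        key_n = norm[(norm["region"] == "Hippocampus") & (norm["hemisphere"] == "left")]
        norm_corr = np.corrcoef(
            key_n.set_index("subject_id")["value"].reindex(icv.index), icv
        )[0, 1]
        assert abs(norm_corr) < 0.35

    def test_hemisphere_correlation_near_rho(self, default_sim):
        controls = default_sim.table.select_group("control").data
        sub = controls[(controls["region"] == "Hippocampus") & (controls["metric"] == "volume")]
        wide = sub.pivot(index="subject_id", columns="hemisphere", values="value")
        observed = np.corrcoef(wide["left"], wide["right"])[0, 1]
        assert observed == pytest.approx(0.8, abs=0.15)

    def test_subfield_fraction_recovered_after_normalization(self, derived):
        # configured fimbria fraction is 0.025 of the whole hippocampus
        norm = derived["controls_n"].data
        fimbria = norm[(norm["region"] == "Fimbria") & (norm["hemisphere"] == "left")]["value"]
        assert fimbria.mean() == pytest.approx(0.025, rel=0.15)

    def test_spike_recorded_in_truth_ledger(self, default_sim):
        truth = default_sim.truth.subjects
        exposed = truth[truth["cohort"] == "exposed"]
        affected = exposed[exposed["affected"]]
        assert (affected["true_burden"] == 8).all()
        assert (exposed.loc[~exposed["affected"], "true_burden"] == 0).all()
        assert affected["spiked_regions"].str.contains(r"\|volume").all()

    def test_spiked_subjects_shifted_in_disease_direction(self, default_sim):
        truth = default_sim.truth.subjects.set_index("subject_id")
        exposed = default_sim.table.select_group("exposed")
        data = exposed.data
        key = data[
            (data["region"] == "Entorhinal")
            & (data["metric"] == "volume")
            & (data["hemisphere"] == "left")
        ].set_index("subject_id")["value"]
        spiked = truth.reindex(key.index)["spiked_regions"].str.contains("Entorhinal")
        assert key[spiked].mean() < key[~spiked].mean()

    def test_missingness_rate_applied(self):
        config = default_cohort_config(n_control=60, n_ad=8, n_exposed=8)
        config.missingness = {"hippocampal_subfield": 0.4}
        result = simulate_cohorts(config, seed=3, cohorts=("control",))
        data = result.table.data
        with_subfields = set(data.loc[data["region"] == "Fimbria", "subject_id"])
        n_missing = 60 - len(with_subfields)
        assert 10 <= n_missing <= 38  # ~24 expected

    def test_truth_ledger_directions(self, default_sim):
        regions = default_sim.truth.regions
        ent = regions[
            (regions["region"] == "Entorhinal")
            & (regions["metric"] == "volume")
            & (regions["cohort"] == "AD")
        ].iloc[0]
        assert ent["direction"] == "atrophy" and ent["effect"] == pytest.approx(0.73)
        vent = regions[
            (regions["region"] == "Inf-Lat-Vent") & (regions["cohort"] == "AD")
        ].iloc[0]
        assert vent["direction"] == "dilation"


class TestCalibration:
    def test_null_config_rejection_rate_near_alpha(self):
        config = null_config(n_per_cohort=50)
        result = simulate_cohorts(config, seed=21, cohorts=("control", "AD"))
        fp, stats, _ = derive_fingerprint(
            result.table.select_group("control"), result.table.select_group("AD")
        )
        rate = np.mean([s.p_value <= 0.05 for s in stats])
        assert 0.02 <= rate <= 0.09
        assert fp.entry_count() <= 15

    def test_entorhinal_deficit_mean_over_replicates(self):
        # light version of the acceptance-scale 200-replicate calibration
        config = default_cohort_config()
        pcts = []
        for rep in range(20):
            result = simulate_cohorts(config, seed=1000 + rep, cohorts=("control", "AD"))
            fp, stats, _ = derive_fingerprint(
                result.table.select_group("control"), result.table.select_group("AD")
            )
            pcts += [
                s.percent_change
                for s in stats
                if s.region == "Entorhinal" and s.metric == "volume"
            ]
        assert np.mean(pcts) == pytest.approx(27.0, abs=1.5)

    def test_uniform_exposed_model_group_means(self):
        config = default_cohort_config(exposed_model="uniform")
        assert config.spike.prevalence == 0.0
        result = simulate_cohorts(config, seed=5, cohorts=("control", "exposed"))
        fp, stats, _ = derive_fingerprint(
            result.table.select_group("control"), result.table.select_group("exposed")
        )
        pct = [
            s.percent_change
            for s in stats
            if s.region == "Entorhinal" and s.metric == "volume"
        ]
        assert np.mean(pct) == pytest.approx(15.7, abs=5.0)


def test_requesting_unconfigured_cohort_errors():
    config = default_cohort_config()
    del config.cohorts["exposed"]
    with pytest.raises(ValidationError):
        simulate_cohorts(config, cohorts=("exposed",))
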