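import numpy as np
import pandas as pd
import pytest

from morphprint import (
    build_control_reference,
    classify_cohort,
    risk_cutoff,
    score_cohort,
    score_subject,
)
from morphprint.errors import (
    DegenerateReferenceError,
    DegenerateStatisticsError,
    MissingDataError,
    ValidationError,
)
from morphprint.fingerprint import RegionStat, build_fingerprint
from morphprint.scoring import OutlierProfile

from conftest import NORMALIZED, make_table


def _fp(entries):
    """entries: list of (region, direction_pct, metric, hemispheric)."""
    stats = []
    for region, pct, metric, hemispheric in entries:
        hemis = ("left", "right") if hemispheric else ("none",)
        for h in hemis:
            stats.append(
                RegionStat(
                    region=region,
                    hemisphere=h,
                    metric=metric,
                    case_mean=100.0 - pct,
                    control_mean=100.0,
                    percent_change=pct,
                    t_statistic=4.0,
                    p_value=0.001,
                    n_case=20,
                    n_control=20,
                )
            )
    return build_fingerprint(stats)


_EMPTY_RECORDS = pd.DataFrame(
    columns=["region", "metric", "hemisphere", "direction", "z", "flagged"]
)


def prof(sid, count):
    """Minimal OutlierProfile with a given count (classification tests)."""
    return OutlierProfile(sid, _EMPTY_RECORDS.copy(), count, count)



def controls_for(fp, values_by_key):
    rows = []
    n = len(next(iter(values_by_key.values())))
    for (region, hemi, metric), values in values_by_key.items():
        rows += [(f"c{i}", region, hemi, metric, v) for i, v in enumerate(values)]
    return make_table(rows, provenance=NORMALIZED)


class TestControlReference:
    def test_hand_computed_mean_sd(self):
        fp = _fp([("Hippocampus", 10.0, "volume", True)])
        controls = controls_for(
            fp,
            {
                ("Hippocampus", "left", "volume"): [10.0, 12.0, 14.0],
                ("Hippocampus", "right", "volume"): [10.0, 12.0, 14.0],
            },
        )
        ref = build_control_reference(controls, fp)
        row = ref.params.loc[("Hippocampus", "left", "volume")]
        assert row["mean"] == pytest.approx(12.0)
        assert row["sd"] == pytest.approx(2.0)  # sample SD
        assert row["n"] == 3

    def test_degenerate_reference_errors(self):
        fp = _fp([("Hippocampus", 10.0, "volume", True)])
        controls = controls_for(
            fp,
            {
                ("Hippocampus", "left", "volume"): [10.0, 10.0, 10.0],
                ("Hippocampus", "right", "volume"): [10.0, 12.0, 14.0],
            },
        )
        with pytest.raises(DegenerateReferenceError):
            build_control_reference(controls, fp)

    def test_keys_exactly_cover_fingerprint(self, derived):
        ref = build_control_reference(derived["controls_n"], derived["fingerprint"])
        expected = {
            (e.region, s.hemisphere, e.metric)
            for e in derived["fingerprint"].entries
            for s in e.stats()
        }
        assert set(ref.params.index) == expected

    def test_tsv_round_trip(self, derived, tmp_path):
        from morphprint.scoring import ControlReference

        ref = build_control_reference(derived["controls_n"], derived["fingerprint"])
        path = tmp_path / "ref.tsv"
        ref.to_tsv(path)
        back = ControlReference.from_tsv(path)
        assert np.allclose(back.params["mean"], ref.params["mean"])
        assert np.allclose(back.params["sd"], ref.params["sd"])


def subject_table(values_by_key, sid="p1"):
    rows = [(sid, region, hemi, metric, v) for (region, hemi, metric), v in values_by_key.items()]
    return make_table(rows, provenance=NORMALIZED)


@pytest.fixture
def simple_setup():
    fp = _fp(
        [
            ("Hippocampus", 10.0, "volume", True),
            ("Amygdala", 10.0, "volume", True),
            ("Entorhinal", 10.0, "volume", True),
            ("Fusiform", 10.0, "volume", True),
            ("Lateral-ventricle", -10.0, "volume", True),  # dilation entry
        ]
    )
    keys = {
        (e.region, s.hemisphere, e.metric) for e in fp.entries for s in e.stats()
    }
    rng = np.random.default_rng(5)
    controls = controls_for(fp, {k: 100.0 + rng.normal(0, 10, 20) for k in sorted(keys)})
    ref = build_control_reference(controls, fp)
    return fp, ref


class TestScoreSubject:
    def test_subject_at_control_mean_scores_zero(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        profile = score_subject(subject_table(values), "p1", fp, ref)
        assert profile.outlier_count == 0

    def test_constructed_four_region_count(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        # 3 SDs below control mean on the LEFT side of 4 atrophy entries
        for region in ("Hippocampus", "Amygdala", "Entorhinal", "Fusiform"):
            key = (region, "left", "volume")
            values[key] = ref.params.loc[key, "mean"] - 3 * ref.params.loc[key, "sd"]
        profile = score_subject(subject_table(values), "p1", fp, ref)
        assert profile.outlier_count == 4
        assert profile.region_count == 4

    def test_wrong_direction_not_flagged(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        key = ("Hippocampus", "left", "volume")
        values[key] = ref.params.loc[key, "mean"] + 3 * ref.params.loc[key, "sd"]
        profile = score_subject(subject_table(values), "p1", fp, ref)
        assert profile.outlier_count == 0

    def test_dilation_entry_flags_above(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        key = ("Lateral-ventricle", "right", "volume")
        values[key] = ref.params.loc[key, "mean"] + 3 * ref.params.loc[key, "sd"]
        profile = score_subject(subject_table(values), "p1", fp, ref)
        assert profile.outlier_count == 1
        assert profile.flagged_entries() == [("Lateral-ventricle", "volume")]

    def test_either_hemisphere_counts_once(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        for hemi in ("left", "right"):
            key = ("Hippocampus", hemi, "volume")
            values[key] = ref.params.loc[key, "mean"] - 3 * ref.params.loc[key, "sd"]
        profile = score_subject(subject_table(values), "p1", fp, ref)
        assert profile.outlier_count == 1

    def test_missing_key_lenient_vs_strict(self, simple_setup):
        fp, ref = simple_setup
        values = {tuple(k): ref.params.loc[k, "mean"] for k in ref.params.index}
        values.pop(("Fusiform", "left", "volume"))
        table = subject_table(values)
        profile = score_subject(table, "p1", fp, ref)
        assert profile.n_missing == 1
        assert profile.outlier_count == 0
        with pytest.raises(MissingDataError):
            score_subject(table, "p1", fp, ref, strict=True)

    def test_score_cohort_matches_score_subject(self, derived):
        fp = derived["fingerprint"]
        ref = build_control_reference(derived["controls_n"], fp)
        table = derived["exposed_n"]
        profiles = score_cohort(table, fp, ref)
        for profile in profiles[:5]:
            single = score_subject(table, profile.subject_id, fp, ref)
            assert single.outlier_count == profile.outlier_count
            assert single.region_count == profile.region_count

    @pytest.mark.parametrize("thresholds", [(1.0, 1.5, 2.0, 2.5, 3.0)])
    def test_monotone_in_threshold(self, derived, thresholds):
        fp = derived["fingerprint"]
        ref = build_control_reference(derived["controls_n"], fp)
        table = derived["exposed_n"]
        previous = None
        for z in thresholds:
            counts = np.array([p.outlier_count for p in score_cohort(table, fp, ref, z)])
            if previous is not None:
                assert (counts <= previous).all()
            previous = counts

    def test_z_oracle_brute_force(self, derived):
        # z-scores recomputed from raw control values to 1e-12
        fp = derived["fingerprint"]
        controls_n = derived["controls_n"]
        ref = build_control_reference(controls_n, fp)
        table = derived["exposed_n"]
        profile = score_cohort(table, fp, ref)[0]
        sub = table.data[table.data["subject_id"] == profile.subject_id]
        values = sub.set_index(["region", "hemisphere", "metric"])["value"]
        ctl = controls_n.data
        for row in profile.records.head(30).itertuples(index=False):
            key = (row.region, row.hemisphere, row.metric)
            pool = ctl[
                (ctl["region"] == key[0])
                & (ctl["hemisphere"] == key[1])
                & (ctl["metric"] == key[2])
            ]["value"].to_numpy()
            expected = (values.loc[key] - pool.mean()) / pool.std(ddof=1)
            assert row.z == pytest.approx(expected, abs=1e-12)


class TestClassification:
    def test_cutoff_from_reported_moments(self):
        # mean 1.78, sample SD 1.83 -> cutoff 5.44
        counts = [1.78 - 1.83, 1.78, 1.78 + 1.83]
        assert risk_cutoff(counts) == pytest.approx(5.44, abs=1e-12)

    def test_19_of_46_is_41_percent(self):
        controls = [prof(f"c{i}", c) for i, c in enumerate([0, 2, 2, 4, 1, 2])]
        cutoff = risk_cutoff([0, 2, 2, 4, 1, 2])
        cases = [prof(f"p{i}", 10 if i < 19 else 0) for i in range(46)]
        cls = classify_cohort(cases, controls)
        assert cls.cutoff == pytest.approx(cutoff)
        assert cls.n == 46 and cls.n_at_risk == 19
        assert cls.percent_at_risk == pytest.approx(100 * 19 / 46)
        assert round(cls.percent_at_risk) == 41

    def test_all_zero_controls_boundary(self):
        controls = [prof(f"c{i}", 0) for i in range(5)]
        cases = [prof("p0", 1), prof("p1", 0)]
        cls = classify_cohort(cases, controls)
        assert cls.cutoff == 0.0
        assert list(cls.cases["at_risk"]) == [True, False]

    def test_too_few_controls_errors(self):
        profs = [prof(f"c{i}", 0) for i in range(2)]
        with pytest.raises(DegenerateStatisticsError):
            classify_cohort(profs, profs)

    def test_strict_inequality_at_cutoff(self):
        # control counts {1,2,3} -> mean 2, sd 1 -> cutoff 4
        controls = [prof(f"c{i}", c) for i, c in enumerate([1, 2, 3])]
        cases = [prof("p0", 4), prof("p1", 5)]
        cls = classify_cohort(cases, controls)
        assert list(cls.cases["at_risk"]) == [False, True]

    def test_null_self_scoring_rate_small(self, derived):
        fp = derived["fingerprint"]
        ref = build_control_reference(derived["controls_n"], fp)
        controls = score_cohort(derived["controls_n"], fp, ref)
        cls = classify_cohort(controls, controls)
        assert cls.percent_at_risk <= 10.0

    def test_mean_plus_2sd_flag_rate_bounds(self, rng):
        # approximately normal count distributions: flag rate ~2-5 %
        rates = []
        for _ in range(300):
            counts = rng.binomial(40, 0.05, size=100)
            cutoff = risk_cutoff(counts)
            fresh = rng.binomial(40, 0.05, size=100)
            rates.append((fresh > cutoff).mean())
        assert 0.01 <= np.mean(rates) <= 0.08


class TestLeaveOneOut:
    def test_loo_matches_manual_recomputation(self, derived):
        fp = derived["fingerprint"]
        controls_n = derived["controls_n"]
        ref = build_control_reference(controls_n, fp)
        profile = score_cohort(controls_n, fp, ref, leave_one_out=True)[0]
        ctl = controls_n.data
        row = profile.records.iloc[0]
        key = (row["region"], row["hemisphere"], row["metric"])
        pool = ctl[
            (ctl["region"] == key[0])
            & (ctl["hemisphere"] == key[1])
            & (ctl["metric"] == key[2])
        ].set_index("subject_id")["value"]
        others = pool.drop(profile.subject_id).to_numpy()
        expected = (pool.loc[profile.subject_id] - others.mean()) / others.std(ddof=1)
        assert row["z"] == pytest.approx(expected, abs=1e-9)

    def test_loo_counts_not_below_naive(self, derived):
        fp = derived["fingerprint"]
        controls_n = derived["controls_n"]
        ref = build_control_reference(controls_n, fp)
        naive = np.array(
            [p.outlier_count for p in score_cohort(controls_n, fp, ref)]
        )
        loo = np.array(
            [p.outlier_count for p in score_cohort(controls_n, fp, ref, leave_one_out=True)]
        )
        assert loo.sum() >= naive.sum()
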