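import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailtyburst import (
    CohortDesign,
    DEFAULT_GENERATING_PARAMS,
    DeficitPanel,
    FISeries,
    cohort_isd_summary,
    deficit_iiqr,
    fluctuation_class,
    group_isd_contrast,
    imean_isd,
    simulate_cohort,
    threshold_inconsistency,
    variability_profiles,
)


def series(vals, burst=1):
    return FISeries("p1", burst, np.arange(1, len(vals) + 1), np.asarray(vals))


class TestImeanIsd:
    def test_constant_series(self):
        assert imean_isd(series([0.2, 0.2, 0.2])) == (pytest.approx(0.2), pytest.approx(0.0))

    def test_two_point_closed_form(self):
        imean, isd = imean_isd(series([0.1, 0.2]))
        assert imean == pytest.approx(0.15)
        assert isd == pytest.approx(np.sqrt((0.05**2 + 0.05**2) / 1))

    def test_narrated_participant_series(self):
        # one participant's quoted FI path: between 0.35 and 0.50, then 0.25
        vals = [0.35, 0.50, 0.35, 0.50, 0.25]
        imean, isd = imean_isd(series(vals))
        assert imean == pytest.approx(0.39)
        dev = np.array(vals) - np.mean(vals)
        assert isd == pytest.approx(np.sqrt(np.sum(dev**2) / 4))

    def test_single_observation_isd_missing_not_zero(self):
        _, isd = imean_isd(series([0.3]))
        assert np.isnan(isd)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=14), st.randoms(use_true_random=False))
    def test_order_invariance(self, vals, rnd):
        shuffled = list(vals)
        rnd.shuffle(shuffled)
        a, b = imean_isd(series(vals)), imean_isd(series(shuffled))
        assert a == (pytest.approx(b[0]), pytest.approx(b[1]))


class TestCohortSummary:
    def test_deficit_unit_conversion(self):
        profiles = pd.DataFrame({"iSD": [0.04, 0.04, 0.04]})
        out = cohort_isd_summary(profiles, n_items=40, baseline_between_sd=0.14)
        assert out["deficit_units"] == pytest.approx(1.6)
        assert out["ratio_to_between_pct"] == 29

    def test_constant_series_summarise_to_zero(self):
        out = cohort_isd_summary(pd.DataFrame({"iSD": [0.0, 0.0]}), n_items=40)
        assert out["mean"] == 0.0 and out["deficit_units"] == 0.0

    def test_no_defined_isd_raises(self):
        with pytest.raises(ValueError):
            cohort_isd_summary(pd.DataFrame({"iSD": [np.nan]}))


class TestDeficitIIQR:
    def test_constant_item_class_none(self, toy_frame, schema):
        frame = toy_frame([{"wave": w, "pain": 0.5} for w in range(1, 8)])
        panel = DeficitPanel.from_frame(frame, schema=schema)
        table = deficit_iiqr(panel, person_id="p1", burst=1).set_index("deficit")
        assert table.loc["pain", "iIQR"] == 0.0
        assert table.loc["pain", "fluctuation_class"] == "none"

    def test_alternating_binary_item_class_high(self, toy_frame, schema):
        vals = [0, 1, 0, 1, 0, 1, 0]
        frame = toy_frame([{"wave": w + 1, "memory": v} for w, v in enumerate(vals)])
        panel = DeficitPanel.from_frame(frame, schema=schema)
        table = deficit_iiqr(panel).set_index("deficit")
        # type-7 quartiles of [0,0,0,0,1,1,1]: Q1=0, Q3=1
        assert table.loc["memory", "iIQR"] == pytest.approx(1.0)
        assert table.loc["memory", "fluctuation_class"] == "high"

    def test_ordinal_item_with_stable_middle_class_none(self, toy_frame, schema):
        vals = [0, 0.5, 0.5, 0.5, 0.5, 0.5, 1]
        frame = toy_frame([{"wave": w + 1, "tiredness": v} for w, v in enumerate(vals)])
        panel = DeficitPanel.from_frame(frame, schema=schema)
        table = deficit_iiqr(panel).set_index("deficit")
        assert table.loc["tiredness", "iIQR"] == pytest.approx(0.0)
        assert table.loc["tiredness", "fluctuation_class"] == "none"

    def test_single_observation_gives_missing(self, toy_frame, schema):
        frame = toy_frame([{"wave": 1}])
        table = deficit_iiqr(DeficitPanel.from_frame(frame, schema=schema))
        assert table["iIQR"].isna().all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=14))
    def test_iiqr_bounded_by_range(self, vals):
        arr = np.array(vals)
        iiqr = np.quantile(arr, 0.75) - np.quantile(arr, 0.25)
        assert 0.0 <= iiqr <= arr.max() - arr.min() + 1e-12

    def test_class_counts_partition_defined_profiles(self, rendered_cohort, schema):
        frame, _ = rendered_cohort
        panel = DeficitPanel.from_frame(frame, schema=schema)
        table = deficit_iiqr(panel)
        defined = table[table["fluctuation_class"] != "undefined"]
        counts = defined.groupby("deficit")["fluctuation_class"].value_counts().unstack(fill_value=0)
        assert (counts.sum(axis=1) == defined.groupby("deficit").size()).all()
        assert set(counts.columns) <= {"none", "some", "high"}


class TestThresholdInconsistency:
    def test_stable_robust_series(self):
        assert threshold_inconsistency(series([0.10, 0.15, 0.20])) is False

    def test_crossing_series(self):
        assert threshold_inconsistency(series([0.20, 0.30])) is True

    def test_single_observation_undefined(self):
        assert threshold_inconsistency(series([0.3])) is None

    def test_cohort_rate_matches_bruteforce_scan(self, fi_cohort):
        frame, _ = fi_cohort
        profiles = variability_profiles(frame)
        b1 = profiles[(profiles["burst"] == 1) & (profiles["n_obs"] >= 2)]
        rate = b1["crossed_threshold"].mean()
        # oracle: direct scan of each person's burst-1 values
        expect = []
        for pid, grp in frame[frame["burst"] == 1].groupby("person_id"):
            v = grp["fi"].to_numpy()
            if len(v) >= 2:
                expect.append((v >= 0.25).any() and (v < 0.25).any())
        assert rate == pytest.approx(np.mean(expect))
        assert 0.0 < rate < 1.0


class TestGroupContrast:
    def test_identical_groups_zero_difference(self):
        profiles = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(20)], "burst": 1, "iSD": [0.04] * 20}
        )
        groups = {f"p{i}": i % 2 for i in range(20)}
        out = group_isd_contrast(profiles, groups, n_boot=200, seed=1)
        assert out["diff"] == pytest.approx(0.0)

    def test_empty_stratum_error_names_it(self):
        profiles = pd.DataFrame({"person_id": ["p1"], "burst": 1, "iSD": [0.04]})
        with pytest.raises(ValueError, match="unexposed"):
            group_isd_contrast(profiles, {"p1": 1})

    def test_single_member_stratum_warns(self):
        profiles = pd.DataFrame(
            {"person_id": ["p1", "p2", "p3"], "burst": 1, "iSD": [0.02, 0.04, 0.06]}
        )
        with pytest.warns(UserWarning, match="single member"):
            group_isd_contrast(profiles, {"p1": 1, "p2": 0, "p3": 0}, n_boot=100, seed=0)

    def test_generating_scale_contrast_detected(self):
        # exposed cohort generated with a 1.3x residual-SD intercept
        params = {k: dict(v) for k, v in DEFAULT_GENERATING_PARAMS.items()}
        params["gamma"] = dict(params["gamma"])
        params["gamma"]["intercept"] = float(np.log(0.04 * 1.3))
        base, _ = simulate_cohort(
            CohortDesign(n_persons=120, render_deficits=False), seed=21
        )
        exposed, _ = simulate_cohort(
            CohortDesign(n_persons=120, render_deficits=False, params=params), seed=22
        )
        exposed = exposed.assign(person_id="x" + exposed["person_id"])
        profiles = variability_profiles(pd.concat([base, exposed], ignore_index=True))
        groups = {pid: pid.startswith("x") for pid in profiles["person_id"].unique()}
        out = group_isd_contrast(profiles, groups, n_boot=500, seed=3)
        assert out["diff"] > 0
        assert out["ci_low"] > 0
        assert out["pct_diff"] > 10


def test_fluctuation_class_boundaries():
    assert fluctuation_class(0.0) == "none"
    assert fluctuation_class(0.5) == "some"
    assert fluctuation_class(0.500001) == "high"
    assert fluctuation_class(float("nan")) == "undefined"
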