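"""Loading, validity filtering, aggregation and lagging of beep tables."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esm_mediation import (
    IntegrityError,
    SchemaError,
    apply_compliance_filter,
    apply_lateness_filter,
    build_lagged_pairs,
    compute_aggregates,
    load_esm_table,
)
from esm_mediation.simulate import GeneratorConfig, generate_dataset

from conftest import beep_row, make_dataset


def _csv_of(ds) -> io.StringIO:
    buf = io.StringIO()
    ds.frame.drop(columns="valid").to_csv(buf, index=False)
    buf.seek(0)
    return buf


class TestLoading:
    def test_roundtrip_preserves_subjects_and_values(self, tiny_dataset):
        loaded = load_esm_table(_csv_of(tiny_dataset))
        assert loaded.n_subjects == 3
        assert len(loaded.frame) == len(tiny_dataset.frame)
        pd.testing.assert_series_equal(
            loaded.frame["stress"], tiny_dataset.frame["stress"]
        )

    def test_missing_group_column_is_schema_error(self, tiny_dataset):
        buf = io.StringIO()
        tiny_dataset.frame.drop(columns=["valid", "group"]).to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(SchemaError, match="group"):
            load_esm_table(buf)

    def test_duplicate_beep_is_integrity_error_naming_offender(self):
        rows = [beep_row(subject="s1", day=2, beep=b) for b in (4, 5)]
        rows.append(beep_row(subject="s1", day=2, beep=5, stress=4.0))
        frame = pd.DataFrame(rows)
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        with pytest.raises(IntegrityError, match=r"s1 day 2 beep 5"):
            load_esm_table(buf)

    def test_unparseable_rows_rejected_with_report(self, tiny_dataset):
        frame = tiny_dataset.frame.drop(columns="valid").copy()
        frame["group"] = frame["group"].astype(str)
        frame.loc[0, "group"] = "martian"
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        ds = load_esm_table(buf)
        assert len(ds.frame) == len(frame) - 1
        assert ds.filter_report["rejected_rows"][0]["reason"].startswith(
            "unparseable group"
        )

    def test_column_mapping(self, tiny_dataset):
        frame = tiny_dataset.frame.drop(columns="valid").rename(
            columns={"stress": "evt_stress"}
        )
        buf = io.StringIO()
        frame.to_csv(buf, index=False)
        buf.seek(0)
        ds = load_esm_table(buf, schema={"stress": "evt_stress"})
        assert ds.frame["stress"].notna().all()

    def test_score_outside_scale_is_integrity_error(self):
        with pytest.raises(IntegrityError, match="1-7"):
            make_dataset([beep_row(stress=8.5)])


class TestLatenessFilter:
    @pytest.mark.parametrize(
        "delay,expected_valid",
        [(16.0, False), (0.0, True), (15.0, True), (15.01, False)],
    )
    def test_boundary(self, delay, expected_valid):
        ds = apply_lateness_filter(make_dataset([beep_row(delay_min=delay)]))
        assert bool(ds.frame["valid"].iloc[0]) is expected_valid

    def test_missing_completion_is_invalid(self):
        ds = apply_lateness_filter(make_dataset([beep_row(answered=False)]))
        assert not ds.frame["valid"].iloc[0]

    def test_negative_delay_warns_and_invalidates(self):
        ds = make_dataset([beep_row(delay_min=-3.0)])
        with pytest.warns(UserWarning, match="before the scheduled"):
            out = apply_lateness_filter(ds)
        assert not out.frame["valid"].iloc[0]

    def test_idempotent_and_monotone(self):
        rows = [beep_row(beep=b, delay_min=5.0 * b) for b in range(1, 11)]
        once = apply_lateness_filter(make_dataset(rows))
        twice = apply_lateness_filter(once)
        pd.testing.assert_series_equal(once.frame["valid"], twice.frame["valid"])
        assert once.frame["valid"].sum() <= len(rows)
        assert len(once.frame) == len(rows)  # records retained, not removed

    @given(delays=st.lists(st.floats(0, 60, allow_subnormal=False),
                           min_size=1, max_size=10, unique=True))
    @settings(derandomize=True, max_examples=50)
    def test_validity_matches_rule_for_arbitrary_delays(self, delays):
        rows = [beep_row(beep=b + 1, delay_min=d) for b, d in enumerate(delays)]
        out = apply_lateness_filter(make_dataset(rows))
        expected = [d <= 15.0 for d in delays]
        assert list(out.frame["valid"]) == expected


class TestComplianceFilter:
    def _subject(self, sid, n_valid):
        rows = []
        k = 0
        for day in range(1, 7):
            for beep in range(1, 11):
                rows.append(
                    beep_row(subject=sid, day=day, beep=beep, answered=k < n_valid)
                )
                k += 1
        return rows

    @pytest.mark.parametrize(
        "n_valid,kept", [(20, True), (19, False), (60, True), (0, False)]
    )
    def test_one_third_boundary(self, n_valid, kept):
        # 20 of 60 scheduled beeps is exactly one third ("at least")
        ds = apply_lateness_filter(make_dataset(self._subject("s1", n_valid)))
        out = apply_compliance_filter(ds)
        assert (out.n_subjects == 1) is kept

    def test_drops_only_offending_subject(self):
        rows = self._subject("s1", 60) + self._subject("s2", 10)
        out = apply_compliance_filter(apply_lateness_filter(make_dataset(rows)))
        assert sorted(out.frame["subject_id"].unique()) == ["s1"]
        assert out.filter_report["compliance"]["n_subjects_dropped"] == 1


class TestAggregates:
    def test_person_mean_over_valid_beeps(self):
        rows = [
            beep_row(beep=1, stress=2.0),
            beep_row(beep=2, stress=4.0),
            beep_row(beep=3, stress=6.0, answered=False),
        ]
        ds = apply_lateness_filter(make_dataset(rows))
        agg = compute_aggregates(ds)
        assert agg.person_means["stress"].iloc[0] == pytest.approx(3.0)

    def test_single_subject_groups_report_point_difference(self):
        rows = [beep_row(subject="a", group="patient", beep=b, stress=3.0) for b in (1, 2)]
        rows += [beep_row(subject="b", group="control", beep=b, stress=5.0) for b in (1, 2)]
        agg = compute_aggregates(make_dataset(rows))
        rec = agg.comparisons.query(
            "comparison == 'patient v. control' and measure == 'stress'"
        ).iloc[0]
        assert rec["diff"] == pytest.approx(-2.0)
        assert np.isnan(rec["ci_lower"])  # CI undefined with n=1 per side

    def test_invariant_to_record_order(self, tiny_dataset):
        agg1 = compute_aggregates(tiny_dataset)
        shuffled = tiny_dataset.copy()
        shuffled.frame = shuffled.frame.sample(frac=1.0, random_state=7).reset_index(
            drop=True
        )
        agg2 = compute_aggregates(shuffled)
        pd.testing.assert_frame_equal(agg1.group_table, agg2.group_table)

    def test_recovers_generator_mean_shift(self):
        # patients' stress mean is configured 0.8 above controls
        means = {
            "control": (3.0, 3.0, 3.0),
            "relative": (3.0, 3.0, 3.0),
            "patient": (3.8, 3.0, 3.0),
        }
        cfg = GeneratorConfig(
            n_subjects={"control": 100, "relative": 5, "patient": 100},
            means=means,
            beta_age=(0, 0, 0),
            beta_female=(0, 0, 0),
            seed=11,
        )
        ds, _ = generate_dataset(cfg)
        ds = apply_compliance_filter(apply_lateness_filter(ds))
        agg = compute_aggregates(ds)
        rec = agg.comparisons.query(
            "comparison == 'patient v. control' and measure == 'stress'"
        ).iloc[0]
        assert rec["ci_lower"] <= 0.8 <= rec["ci_upper"]
        assert rec["diff"] == pytest.approx(0.8, abs=0.15)


class TestLaggedPairs:
    def test_adjacent_valid_beeps_pair_up(self):
        rows = [beep_row(beep=b) for b in (1, 2, 3)]
        lp = build_lagged_pairs(apply_lateness_filter(make_dataset(rows)))
        assert lp.n_pairs == 2
        assert (lp.frame["beep_to"] == lp.frame["beep_from"] + 1).all()

    def test_invalid_intermediate_beep_breaks_chain(self):
        rows = [
            beep_row(beep=1),
            beep_row(beep=2, answered=False),
            beep_row(beep=3),
        ]
        lp = build_lagged_pairs(apply_lateness_filter(make_dataset(rows)))
        assert lp.n_pairs == 0

    def test_no_overnight_pairs_and_full_subject_count(self):
        rows = [
            beep_row(day=d, beep=b) for d in range(1, 7) for b in range(1, 11)
        ]
        lp = build_lagged_pairs(apply_lateness_filter(make_dataset(rows)))
        # 9 adjacent pairs per day x 6 days
        assert lp.n_pairs == 54
        per_day = lp.frame.groupby("day").size()
        assert (per_day <= 9).all()

    def test_pair_values_align_with_source_beeps(self):
        rows = [
            beep_row(beep=1, stress=2.0, pe=1.5),
            beep_row(beep=2, stress=4.0, pe=2.5),
        ]
        lp = build_lagged_pairs(apply_lateness_filter(make_dataset(rows)))
        rec = lp.frame.iloc[0]
        assert (rec["X_lag"], rec["X_t"]) == (2.0, 4.0)
        assert (rec["Y_lag"], rec["Y_t"]) == (1.5, 2.5)

    def test_empty_dataset_allowed(self):
        rows = [beep_row(answered=False)]
        lp = build_lagged_pairs(apply_lateness_filter(make_dataset(rows)))
        assert lp.n_pairs == 0
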