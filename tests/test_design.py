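"""Response tables, design generation, reverse coding, exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sliderirt.design import (
    DRS,
    VAS,
    DesignSpec,
    ExclusionConfig,
    ExclusionReport,
    ResponseRecord,
    ResponseTable,
    SchemaError,
    ValidationError,
    apply_exclusions,
    apply_reverse_coding,
    make_design,
    read_responses,
    reverse_code,
    write_responses,
)


def _rec(pid="P1", item="E01", occ=1, fmt=VAS, lo=50.0, hi=None, **kw):
    hi = lo if hi is None else hi
    return ResponseRecord(
        person_id=pid, item_id=item, trait=item[0], occasion=occ,
        format=fmt, value_low=lo, value_high=hi, **kw,
    )


class TestRecordInvariants:
    def test_vas_requires_equal_bounds(self):
        with pytest.raises(ValidationError):
            _rec(fmt=VAS, lo=10.0, hi=20.0)

    def test_low_above_high_rejected(self):
        with pytest.raises(ValidationError):
            _rec(fmt=DRS, lo=60.0, hi=40.0)

    def test_drs_interval_ok(self):
        r = _rec(fmt=DRS, lo=40.0, hi=90.0)
        assert (r.value_low, r.value_high) == (40.0, 90.0)


class TestIO:
    def _table(self):
        return ResponseTable.from_records(
            [
                _rec("P1", "E01", 1, VAS, 65.0),
                _rec("P1", "E02", 1, DRS, 40.0, 90.0),
                _rec("P2", "E01", 1, VAS, 30.0),
                _rec("P2", "E02", 1, DRS, 10.0, 20.0),
            ]
        )

    def test_roundtrip(self, tmp_path):
        table = self._table()
        path = tmp_path / "r.csv"
        write_responses(table, path)
        back = read_responses(path)
        assert back == table
        assert len(back) == 4

    def test_validation_error_names_row(self, tmp_path):
        table = self._table()
        path = tmp_path / "r.csv"
        write_responses(table, path)
        df = pd.read_csv(path)
        df.loc[1, "value_low"] = 95.0  # above value_high=90
        df.to_csv(path, index=False)
        with pytest.raises(ValidationError, match="1"):
            read_responses(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("person_id,item_id\nP1,E01\n")
        with pytest.raises(SchemaError):
            read_responses(path)

    def test_dialect_mapping(self, tmp_path):
        table = self._table()
        path = tmp_path / "r.csv"
        write_responses(table, path)
        df = pd.read_csv(path).rename(columns={"person_id": "subject"})
        df.to_csv(path, index=False)
        back = read_responses(path, dialect={"person_id": "subject"})
        assert back == table

    def test_empty_table_header_only(self, tmp_path):
        table = ResponseTable.from_records([])
        path = tmp_path / "e.csv"
        write_responses(table, path)
        text = path.read_text().strip().splitlines()
        assert len(text) == 1 and text[0].startswith("person_id,")

    def test_write_deterministic(self, tmp_path):
        table = self._table()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_responses(table, p1)
        write_responses(table, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_value_out_of_scale_rejected(self):
        with pytest.raises(ValidationError):
            ResponseTable.from_records([_rec(lo=120.0)])

    def test_format_consistency_across_occasions(self):
        recs = [
            _rec("P1", "E01", 1, VAS, 50.0),
            _rec("P1", "E01", 2, DRS, 40.0, 60.0),
        ]
        with pytest.raises(ValidationError, match="format"):
            ResponseTable.from_records(recs)


class TestMakeDesign:
    def test_paper_scale_slot_count(self):
        design = make_design(224, 42, 2, ("E", "C"), seed=0)
        assert design.n_slots == 37_632

    def test_forced_split(self):
        design = make_design(1, 2, 1, ("E",), seed=0)
        fmts = sorted(design.format_assignment.values())
        assert fmts == [DRS, VAS]

    def test_determinism(self):
        a = make_design(20, 6, 2, ("E", "C"), seed=5)
        b = make_design(20, 6, 2, ("E", "C"), seed=5)
        assert a.format_assignment == b.format_assignment
        assert a.block_order == b.block_order

    def test_odd_items_rejected(self):
        with pytest.raises(ValueError):
            make_design(10, 7, 2, ("E",), seed=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_equal_halves_every_seed(self, seed):
        design = make_design(5, 6, 2, ("E", "C"), seed=seed)
        for pid in design.person_ids:
            for trait in design.traits:
                fmts = [
                    design.format_assignment[(pid, item)]
                    for item in design.item_ids(trait)
                ]
                assert fmts.count(VAS) == fmts.count(DRS) == 3


class TestReverseCode:
    def test_vas_reflection(self):
        r = _rec(lo=70.0, reverse_coded=True)
        out = reverse_code(r, 100.0)
        assert out.value_low == out.value_high == 30.0
        assert not out.reverse_coded

    def test_drs_reflection_preserves_width(self):
        r = _rec(fmt=DRS, lo=40.0, hi=90.0, reverse_coded=True)
        out = reverse_code(r, 100.0)
        assert (out.value_low, out.value_high) == (10.0, 60.0)
        assert out.value_high - out.value_low == 50.0

    def test_involution(self):
        r = _rec(fmt=DRS, lo=25.0, hi=35.0, reverse_coded=True)
        once = reverse_code(r, 100.0)
        again = reverse_code(
            ResponseRecord(**{**vars(once), "reverse_coded": True}), 100.0
        )
        assert (again.value_low, again.value_high) == (25.0, 35.0)

    @given(
        lo=st.floats(0, 100),
        width=st.floats(0, 100),
    )
    @settings(max_examples=100)
    def test_width_preserved_exactly(self, lo, width):
        hi = min(lo + width, 100.0)
        r = _rec(fmt=DRS, lo=lo, hi=hi, reverse_coded=True)
        out = reverse_code(r, 100.0)
        assert out.value_high - out.value_low == pytest.approx(hi - lo, abs=1e-9)
        assert out.value_low <= out.value_high

    def test_endpoints_map_onto_each_other(self):
        r = _rec(lo=0.0, reverse_coded=True)
        assert reverse_code(r, 100.0).value_low == 100.0

    def test_table_level(self):
        t = ResponseTable.from_records(
            [_rec(lo=70.0, reverse_coded=True), _rec("P2", lo=20.0)]
        )
        out = apply_reverse_coding(t)
        assert out.df.loc[0, "value_low"] == 30.0
        assert out.df.loc[1, "value_low"] == 20.0
        assert not out.df["reverse_coded"].any()


def _two_occasion_records(pid, base=50.0, time=6.0, serious=True):
    recs = []
    for occ in (1, 2):
        for j, fmt in ((1, VAS), (2, DRS)):
            lo = base if fmt == VAS else base - 5
            hi = base if fmt == VAS else base + 5
            recs.append(
                ResponseRecord(
                    person_id=pid, item_id=f"E{j:02d}", trait="E", occasion=occ,
                    format=fmt, value_low=lo, value_high=hi,
                    response_time_s=time, serious=serious,
                )
            )
    return recs


class TestExclusions:
    def _base_table(self, n=10):
        recs = []
        rng = np.random.default_rng(0)
        for i in range(n):
            recs.extend(
                _two_occasion_records(f"P{i:02d}", base=45 + 2 * i, time=5.0 + rng.uniform())
            )
        return ResponseTable.from_records(recs)

    def test_duplicates_removed_and_counted(self):
        table = self._base_table()
        dup = pd.concat([table.df, table.df.iloc[:4]], ignore_index=True)
        table2 = ResponseTable(dup)
        cfg = ExclusionConfig(fast_quantile=None, slow_quantile=None, outlier_z=None)
        clean, report = apply_exclusions(table2, cfg)
        assert not clean.has_duplicates
        assert report.n_removed_by_rule["duplicates"]["respondents"] == 1
        assert len(clean) == len(table)

    def test_non_serious_removed_entirely(self):
        recs = _two_occasion_records("A") + _two_occasion_records("B")
        # flag B only at occasion 2; all of B's records must go
        recs = [
            r if not (r.person_id == "B" and r.occasion == 2)
            else ResponseRecord(**{**vars(r), "serious": False})
            for r in recs
        ]
        table = ResponseTable.from_records(recs)
        cfg = ExclusionConfig(fast_quantile=None, slow_quantile=None, outlier_z=None)
        clean, report = apply_exclusions(table, cfg)
        assert clean.persons == ["A"]
        assert report.n_removed_by_rule["non_serious"] == {
            "respondents": 1,
            "entries": 2,
        }

    def test_fast_person_removed_matches_quantile_oracle(self):
        recs = []
        times = {}
        for i in range(20):
            t = 5.0 + i * 0.1
            times[f"P{i:02d}"] = t
            recs.extend(_two_occasion_records(f"P{i:02d}", time=t))
        # the extreme-fast person (slightly different per occasion so the
        # quantile interpolates between their two entry times)
        fast = [
            ResponseRecord(**{**vars(r), "response_time_s": 0.05 if r.occasion == 1 else 0.06})
            for r in _two_occasion_records("PXX")
        ]
        recs.extend(fast)
        table = ResponseTable.from_records(recs)
        cfg = ExclusionConfig(fast_quantile=0.01, slow_quantile=None, outlier_z=None)
        clean, report = apply_exclusions(table, cfg)
        assert "PXX" not in clean.persons
        assert report.n_removed_by_rule["fast"]["respondents"] == 1
        # oracle: entry completion time is 2 records x per-record time
        entry_times = sorted(
            [2 * t for t in times.values() for _ in (1, 2)] + [2 * 0.05, 2 * 0.06]
        )
        threshold = np.quantile(entry_times, 0.01)
        assert 2 * 0.05 < threshold

    def test_time_rule_without_times_errors(self):
        recs = [
            ResponseRecord(**{**vars(r), "response_time_s": None})
            for r in _two_occasion_records("A") + _two_occasion_records("B")
        ]
        table = ResponseTable.from_records(recs)
        with pytest.raises(ValueError, match="missing"):
            apply_exclusions(table, ExclusionConfig())

    def test_outlier_person_removed(self):
        recs = []
        for i in range(15):
            recs.extend(_two_occasion_records(f"P{i:02d}", base=50 + (i % 3)))
        recs.extend(_two_occasion_records("PEX", base=5.0))
        table = ResponseTable.from_records(recs)
        cfg = ExclusionConfig(fast_quantile=None, slow_quantile=None, outlier_z=3.5)
        clean, report = apply_exclusions(table, cfg)
        assert "PEX" not in clean.persons
        assert report.n_removed_by_rule["outlier"]["respondents"] >= 1

    def test_retention_and_attrition(self):
        recs = []
        for i in range(4):
            recs.extend(_two_occasion_records(f"B{i}"))
        # one person with only occasion 1
        solo = [r for r in _two_occasion_records("S0") if r.occasion == 1]
        recs.extend(solo)
        table = ResponseTable.from_records(recs)
        cfg = ExclusionConfig(fast_quantile=None, slow_quantile=None, outlier_z=None)
        clean, report = apply_exclusions(table, cfg)
        assert report.n_retained_both == 4
        assert report.n_retained_t1_only == 1
        assert report.attrition_pct == pytest.approx(100 * 1 / 5)
        assert clean.persons == [f"B{i}" for i in range(4)]

    def test_attrition_formula_published_counts(self):
        report = ExclusionReport(n_retained_both=224, n_retained_t1_only=84)
        assert round(report.attrition_pct, 1) == 27.3

    def test_idempotent(self):
        recs = []
        for i in range(12):
            recs.extend(_two_occasion_records(f"P{i:02d}", base=45 + i, time=5 + 0.2 * i))
        recs.extend(_two_occasion_records("FAST", time=0.01))
        recs.extend(_two_occasion_records("BAD", serious=False))
        table = ResponseTable.from_records(recs)
        cfg = ExclusionConfig()
        clean1, _ = apply_exclusions(table, cfg)
        clean2, rep2 = apply_exclusions(clean1, cfg)
        assert clean1 == clean2
        assert all(
            v["respondents"] == 0 for v in rep2.n_removed_by_rule.values()
        )

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ExclusionConfig(fast_quantile=0.9, slow_quantile=0.1)
        with pytest.raises(ValueError):
            ExclusionConfig(outlier_z=-1.0)
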