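"""Curation pipeline: thermodynamics, replicate filters, end-to-end reports."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from memddg.curation import (
    AffinityRecord,
    CurationConfig,
    Mutation,
    RemovalReason,
    assign_pseudonyms,
    compare_reports,
    curate,
    delta_g_from_kd,
    drop_missing_ddg,
    filter_replicate_sd,
    merge_duplicates,
    parse_mutation,
    read_affinity_table,
    recompute_ddg,
    renumber_and_validate,
    resolve_sign_conflicts,
    write_affinity_table,
)
from memddg.synthetic import DefectPlan, messy_affinity_table

CFG = CurationConfig()


def rec(**kw):
    defaults = dict(complex_id="1ABC", partner_a_id="P1", partner_b_id="P2",
                    mutation_raw="A1G", ddg=0.1)
    defaults.update(kw)
    return AffinityRecord(**defaults)


class TestDeltaG:
    def test_unit_kd_gives_zero(self):
        assert delta_g_from_kd(1.0, CFG) == 0.0

    def test_nanomolar_affinity(self):
        # RT ln(1e-9) with R=1.987e-3 kcal/(mol K), T=298.15 K
        expected = 1.987e-3 * 298.15 * math.log(1e-9)
        assert delta_g_from_kd(1e-9, CFG) == pytest.approx(expected)
        assert delta_g_from_kd(1e-9, CFG) == pytest.approx(-12.28, abs=0.01)

    @given(st.floats(1e-15, 1e3), st.floats(1e-15, 1e3))
    def test_monotone_in_kd(self, kd1, kd2):
        if kd1 < kd2:
            assert delta_g_from_kd(kd1, CFG) < delta_g_from_kd(kd2, CFG)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            delta_g_from_kd(0.0, CFG)
        with pytest.raises(ValueError):
            delta_g_from_kd(-1.0, CFG)


class TestRecomputeDdg:
    def test_equal_dg_gives_zero(self):
        out = recompute_ddg(rec(dg_wt=-9.0, dg_mut=-9.0, ddg=None), CFG)
        assert out.ddg == 0.0

    def test_stated_ddg_overridden_by_dg_difference(self):
        out = recompute_ddg(rec(dg_wt=-10.0, dg_mut=-8.5, ddg=-1.5), CFG)
        assert out.ddg == pytest.approx(1.5)

    def test_only_stated_ddg_retained(self):
        out = recompute_ddg(rec(ddg=0.7), CFG)
        assert out.ddg == 0.7

    def test_no_value_source_left_for_missing_filter(self):
        out = recompute_ddg(rec(ddg=None), CFG)
        assert out.ddg is None
        kept, removed = drop_missing_ddg([out])
        assert not kept and removed[0][1] is RemovalReason.MISSING_DDG

    @given(st.floats(1e-12, 1e-2), st.floats(1e-12, 1e-2))
    def test_sign_convention_from_kd_pair(self, kd_wt, kd_mut):
        """Weaker binding of the mutant (larger K_D) means destabilizing ΔΔG > 0."""
        if kd_wt == kd_mut:
            return
        out = recompute_ddg(rec(kd_wt=kd_wt, kd_mut=kd_mut, ddg=None), CFG)
        assert (out.ddg > 0) == (kd_mut > kd_wt)

    def test_closed_form_agreement_on_random_pairs(self, rng):
        """ΔΔG from K_D pairs matches RT·ln(kd_mut/kd_wt) to 1e-9 kcal/mol."""
        kds = 10 ** rng.uniform(-12, -2, size=(1000, 2))
        for kd_wt, kd_mut in kds:
            out = recompute_ddg(rec(kd_wt=kd_wt, kd_mut=kd_mut, ddg=None), CFG)
            direct = CFG.gas_constant_R * CFG.temperature_T * math.log(kd_mut / kd_wt)
            assert abs(out.ddg - direct) < 1e-9


class TestPseudonyms:
    def test_same_partners_share_pseudonym(self):
        a = rec(complex_id="", partner_a_id="U1", partner_b_id="U2")
        b = rec(complex_id="", partner_a_id="U1", partner_b_id="U2")
        out = assign_pseudonyms([a, b])
        assert out[0].complex_id == out[1].complex_id != ""

    def test_existing_id_untouched(self):
        out = assign_pseudonyms([rec(complex_id="1ABC")])
        assert out[0].complex_id == "1ABC"

    def test_disjoint_partners_distinct(self):
        a = rec(complex_id="", partner_a_id="U1", partner_b_id="U2")
        b = rec(complex_id="", partner_a_id="U3", partner_b_id="U4")
        out = assign_pseudonyms([a, b])
        assert out[0].complex_id != out[1].complex_id


class TestReplicateSD:
    def test_low_spread_group_kept(self):
        recs = [rec(ddg=1.0), rec(ddg=1.2)]
        kept, removed = filter_replicate_sd(recs, CFG)
        assert len(kept) == 2 and not removed

    def test_high_spread_group_removed(self):
        recs = [rec(ddg=0.0), rec(ddg=2.0)]  # sample SD ~ 1.414
        kept, removed = filter_replicate_sd(recs, CFG)
        assert not kept and len(removed) == 2

    def test_singleton_kept(self):
        kept, removed = filter_replicate_sd([rec(ddg=5.0)], CFG)
        assert len(kept) == 1 and not removed


class TestSignConflicts:
    @pytest.mark.parametrize(
        "values,expect_removed",
        [
            ([0.6, -0.6], 2),    # opposite signs, both beyond threshold
            ([0.3, -0.3], 0),    # opposite signs but small
            ([0.6, 0.7], 0),     # same sign
            ([0.6, -0.6, 0.2], 3),   # size-3 mixed signs, one beyond threshold
            ([0.2, -0.2, 0.1, -0.1], 0),  # size-4 mixed but all small
        ],
    )
    def test_small_group_rules(self, values, expect_removed):
        recs = [rec(ddg=v) for v in values]
        kept, removed = resolve_sign_conflicts(recs, CFG)
        assert len(removed) == expect_removed
        assert len(kept) == len(values) - expect_removed

    def test_large_group_outlier_trimming(self):
        recs = [rec(ddg=v) for v in [0.1, 0.15, 0.2, 0.12, 2.5]]
        kept, removed = resolve_sign_conflicts(recs, CFG)
        assert len(removed) == 1 and removed[0][0].ddg == 2.5
        assert len(kept) == 4

    def test_large_group_many_outliers_untouched(self):
        recs = [rec(ddg=v) for v in [0.0, 3.0, -3.0, 4.0, -4.0]]
        kept, removed = resolve_sign_conflicts(recs, CFG)
        assert len(kept) == 5 and not removed


class TestMergeDuplicates:
    def test_mean_merge(self):
        kept, removed = merge_duplicates([rec(ddg=1.0), rec(ddg=1.2)])
        assert len(kept) == 1 and kept[0].ddg == pytest.approx(1.1)
        assert len(removed) == 1

    def test_singleton_unchanged(self):
        kept, removed = merge_duplicates([rec(ddg=0.5)])
        assert kept[0].ddg == 0.5 and not removed

    @given(st.lists(st.floats(-3, 3), min_size=2, max_size=8))
    def test_mean_invariant_under_row_order(self, values):
        recs = [rec(ddg=round(v, 6)) for v in values]
        kept1, _ = merge_duplicates(recs)
        kept2, _ = merge_duplicates(list(reversed(recs)))
        assert kept1[0].ddg == pytest.approx(kept2[0].ddg, abs=1e-12)

    def test_no_duplicate_keys_in_output(self):
        recs = [rec(ddg=1.0), rec(ddg=2.0), rec(complex_id="2XYZ", ddg=3.0)]
        kept, _ = merge_duplicates(recs)
        keys = [r.group_key() for r in kept]
        assert len(keys) == len(set(keys))


class TestRenumber:
    def test_identity_map_wt_match(self):
        r = rec(mutation_raw="K2A")
        out, reason = renumber_and_validate(r, "MKT")
        assert reason is None and out.mutation.position == 2

    def test_identity_map_wt_mismatch_flagged(self):
        r = rec(mutation_raw="R2A")
        _, reason = renumber_and_validate(r, "MKT")
        assert reason is RemovalReason.RESIDUE_MISMATCH

    def test_offset_map_renumbers_then_checks(self):
        r = rec(mutation_raw="K6A")
        out, reason = renumber_and_validate(r, "MKT", {5: 1, 6: 2, 7: 3})
        assert reason is None and out.mutation.position == 2

    def test_unmapped_position_flagged(self):
        r = rec(mutation_raw="K9A")
        _, reason = renumber_and_validate(r, "MKT", {5: 1})
        assert reason is RemovalReason.UNMAPPABLE_POSITION


class TestParseMutation:
    @pytest.mark.parametrize("text", ["A123G", "A 123 G"])
    def test_accepted_dialects(self, text):
        m = parse_mutation(text)
        assert (m.wt_aa, m.position, m.mut_aa) == ("A", 123, "G")

    @pytest.mark.parametrize("text", ["123AG", "A123A", "B123G", "A-1G", "A123GH", ""])
    def test_rejected_forms(self, text):
        with pytest.raises(ValueError):
            parse_mutation(text)


class TestCurateEndToEnd:
    def test_report_conservation_and_chaining(self):
        table = messy_affinity_table(DefectPlan(duplicate_groups=2), seed=11)
        _, report = curate(table.records, table.sequences)
        for stage in report.stages:
            assert stage.records_in - stage.records_removed == stage.records_out
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev.records_out == nxt.records_in

    def test_planted_defect_counts_recovered(self):
        table = messy_affinity_table(DefectPlan(missing_ddg=2, duplicate_groups=1), seed=3)
        _, report = curate(table.records, table.sequences)
        assert compare_reports(report, table.expected_counts) == {}

    def test_idempotence(self):
        table = messy_affinity_table(seed=5)
        clean, _ = curate(table.records, table.sequences)
        clean2, report2 = curate(clean, table.sequences)
        assert len(clean2) == len(clean)
        assert all(s.records_removed == 0 for s in report2.stages)

    def test_compare_reports_surfaces_diffs(self):
        table = messy_affinity_table(seed=9)
        _, report = curate(table.records, table.sequences)
        wrong = dict(table.expected_counts)
        wrong["drop_missing_ddg"] += 3
        diffs = compare_reports(report, wrong)
        assert "drop_missing_ddg" in diffs


class TestTableIO:
    def test_csv_round_trip(self, tmp_path):
        table = messy_affinity_table(seed=2)
        path = tmp_path / "table.csv"
        write_affinity_table(table.records, path)
        back = read_affinity_table(path)
        assert len(back) == len(table.records)
        for a, b in zip(table.records, back):
            assert a.complex_id == b.complex_id
            assert a.mutation_raw == b.mutation_raw
            assert (a.ddg is None) == (b.ddg is None)
            if a.ddg is not None:
                assert a.ddg == pytest.approx(b.ddg)
            assert a.n_chains == b.n_chains

    def test_unknown_columns_passthrough(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "complex_id,mutation,ddg,n_chains,my_note\n1ABC,A1G,0.5,2,hello\n"
        )
        records = read_affinity_table(path)
        assert records[0].extra["my_note"] == "hello"
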