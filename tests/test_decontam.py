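import numpy as np
import pytest
from hypothesis import given, strategies as st

import treedna as td

from conftest import make_otu_table

ONE_SAMPLE = [("S1", "sample", "roller", "t1", 1, "E1", "P1", "siteA")]


def table_with(rows):
    return make_otu_table(rows, ONE_SAMPLE)


class TestThresholdEdges:
    @pytest.mark.parametrize("total,kept", [(9, False), (10, True)])
    def test_read_count_boundary(self, total, kept):
        t = table_with([("o1", "x", 100, 120, {"S1": total})])
        out = td.filter_low_count_short(t, td.FilterConfig())
        assert ("o1" in out.otu_ids) is kept

    @pytest.mark.parametrize("length,kept", [(79, False), (80, True)])
    def test_sequence_length_boundary(self, length, kept):
        t = table_with([("o1", "x", length, 120, {"S1": 50})])
        out = td.filter_low_count_short(t, td.FilterConfig())
        assert ("o1" in out.otu_ids) is kept

    @pytest.mark.parametrize("insert,kept", [(200, False), (199, True)])
    def test_insert_length_boundary(self, insert, kept):
        t = table_with([("o1", "x", 100, insert, {"S1": 50})])
        out = td.filter_insert_length(t, td.FilterConfig())
        assert ("o1" in out.otu_ids) is kept

    @pytest.mark.parametrize("total,kept", [(19, False), (20, True), (21, True), (5, False)])
    def test_low_abundance_boundary(self, total, kept):
        t = table_with([("o1", "x", 100, 120, {"S1": total})])
        out = td.drop_low_abundance_otus(t, td.FilterConfig())
        assert ("o1" in out.otu_ids) is kept

    def test_insert_mixed_table(self):
        rows = [(f"o{i}", "x", 100, ins, {"S1": 50})
                for i, ins in enumerate([100, 150, 200, 250, 199])]
        out = td.filter_insert_length(table_with(rows), td.FilterConfig())
        assert len(out.otu_ids) == 3

    def test_empty_table_passes_through(self):
        t = table_with([("o1", "x", 100, 120, {"S1": 50})])
        empty = t.replace(features=t.features.iloc[:0], counts=t.counts.iloc[:0])
        cfg = td.FilterConfig()
        assert len(td.filter_low_count_short(empty, cfg).otu_ids) == 0
        assert len(td.drop_low_abundance_otus(empty, cfg).otu_ids) == 0


class TestContaminantTaxa:
    def test_listed_taxa_removed(self):
        rows = [("o1", "Homo sapiens", 100, 120, {"S1": 50}),
                ("o2", "Glaucomys volans", 100, 120, {"S1": 50})]
        out = td.remove_contaminant_taxa(table_with(rows), td.FilterConfig())
        assert out.otu_ids == ["o2"]

    def test_empty_list_is_identity(self):
        rows = [("o1", "Homo sapiens", 100, 120, {"S1": 50})]
        out = td.remove_contaminant_taxa(
            table_with(rows), td.FilterConfig(contaminant_taxa=())
        )
        assert out.otu_ids == ["o1"]

    def test_two_of_six_listed(self):
        taxa = ["Homo sapiens", "Bos taurus", "a", "b", "c", "d"]
        rows = [(f"o{i}", t, 100, 120, {"S1": 50}) for i, t in enumerate(taxa)]
        out = td.remove_contaminant_taxa(table_with(rows), td.FilterConfig())
        assert len(out.otu_ids) == 4


class TestNegativeControls:
    def test_subtract_rule_by_hand(self, batch_table):
        """7 reads in the batch-B PCR negative: a 5-read batch-B sample goes
        to 0, a 100-read one to 93; batch-C samples are untouched."""
        out = td.subtract_negative_controls(batch_table)
        assert out.counts.loc["o1", "S1"] == 0
        assert out.counts.loc["o1", "S2"] == 93
        assert out.counts.loc["o1", "S3"] == 40
        assert out.counts.loc["o1", "S4"] == 40
        assert out.counts.loc["o2"].tolist() == [50, 60, 70, 80, 0, 0, 0, 0]
        assert (out.counts[["PN_B", "PN_C", "EN1", "FN_A"]] == 0).all().all()

    def test_threshold_rule_keeps_counts_above_threshold(self, batch_table):
        out = td.subtract_negative_controls(batch_table, rule="threshold")
        assert out.counts.loc["o1", "S1"] == 0     # 5 <= 7 -> zeroed
        assert out.counts.loc["o1", "S2"] == 100   # 100 > 7 -> kept whole

    def test_unlinked_sample_warns_and_passes(self, caplog):
        t = make_otu_table(
            [("o1", "x", 100, 120, {"S1": 30})],
            [("S1", "sample", "roller", "t1", 1, "E9", "P9", "siteZ"),
             ("PN1", "pcr_negative", "roller", "", 0, "", "P1", "")],
        )
        import logging
        with caplog.at_level(logging.WARNING):
            out = td.subtract_negative_controls(t)
        assert out.counts.loc["o1", "S1"] == 30
        assert any("no linked negative" in r.message for r in caplog.records)

    def test_clean_negatives_identity_on_samples(self):
        table, _ = td.simulate_otu_table(td.OtuSimConfig(contam_rate=0.0, seed=1))
        out = td.subtract_negative_controls(table)
        sids = table.true_sample_ids
        assert out.counts[sids].equals(table.counts[sids])


class TestPipeline:
    def test_identity_on_clean_table_with_generous_thresholds(self):
        rows = [("o1", "x", 100, 120, {"S1": 50}), ("o2", "y", 90, 110, {"S1": 40})]
        cfg = td.FilterConfig(min_read_count=0, min_length_bp=0, min_otu_total=0)
        out, audit = td.run_filter_pipeline(table_with(rows), cfg)
        assert out.counts.equals(table_with(rows).counts)
        assert audit.reads_in == audit.reads_out == 90

    def test_audit_read_conservation(self):
        table, _ = td.simulate_otu_table(td.OtuSimConfig(seed=3, contam_rate=0.1))
        _, audit = td.run_filter_pipeline(table)
        for s in audit.stages:
            assert s.reads_out <= s.reads_in
            assert sum(s.removed_by_reason.values()) == s.reads_in - s.reads_out
        # stages chain: reads_out of one equals reads_in of the next
        for a, b in zip(audit.stages, audit.stages[1:]):
            assert a.reads_out == b.reads_in

    def test_pipeline_monotone_and_idempotent(self):
        table, _ = td.simulate_otu_table(td.OtuSimConfig(seed=4, contam_rate=0.05))
        once, _ = td.run_filter_pipeline(table)
        shared = once.counts.index
        assert (once.counts.loc[shared] <= table.counts.loc[shared]).all().all()
        twice, _ = td.run_filter_pipeline(once)
        assert twice.counts.equals(once.counts)

    def test_negative_observed_otus_are_thresholded_in_linked_samples(self):
        """Any OTU with reads in a negative loses at least that many reads
        from every linked true sample (or hits zero)."""
        table, _ = td.simulate_otu_table(td.OtuSimConfig(seed=5, contam_rate=0.15))
        out = td.subtract_negative_controls(table)
        from treedna.decontam import _linked_negatives
        negs = table.ids_with_role(
            "field_negative", "extraction_negative", "pcr_negative"
        )
        for sid in table.true_sample_ids[:20]:
            linked = _linked_negatives(table.samples, sid, negs)
            t = table.counts[linked].max(axis=1)
            before, after = table.counts[sid], out.counts[sid]
            assert ((after == (before - t).clip(lower=0))).all()

    @given(st.integers(0, 60), st.integers(0, 60))
    def test_subtraction_never_increases_counts(self, neg_count, samp_count):
        t = make_otu_table(
            [("o1", "x", 100, 120, {"S1": samp_count, "PN1": neg_count})],
            ONE_SAMPLE + [("PN1", "pcr_negative", "roller", "", 0, "", "P1", "")],
        )
        out = td.subtract_negative_controls(t)
        assert out.counts.loc["o1", "S1"] == max(0, samp_count - neg_count)
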