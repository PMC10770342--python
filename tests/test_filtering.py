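"""Filter pipeline: VAF arithmetic, gates, origin classification, adjudication,
ledger bookkeeping."""

import pytest
from hypothesis import given, settings, strategies as st

from ctdna_mrd.cohort_io import DdpcrAssay, Source, TargetRegion, VariantKey
from ctdna_mrd.ddpcr import DdpcrCall, call_ddpcr_batch
from ctdna_mrd.errors import ConfigError, DataError, UndefinedVafError
from ctdna_mrd.filtering import (
    FilterConfig, Origin, apply_ddpcr_adjudication, classify_origin, compute_vaf,
    filter_by_rf_score, filter_by_vaf_window, restrict_to_targets,
    run_filter_pipeline,
)
from ctdna_mrd.fixtures import filter_ledger_fixture
from conftest import make_call


class TestComputeVaf:
    @pytest.mark.parametrize("ta,tr,to,expected", [
        (0, 100, 0, 0.0),
        (5, 5, 0, 50.0),
        (10, 985, 5, 1.0),      # 10 / 1000 reads
        (78, 21, 1, 78.0),
    ])
    def test_hand_arithmetic(self, ta, tr, to, expected):
        assert compute_vaf(ta, tr, to) == pytest.approx(expected)

    def test_all_zero_counts_is_an_error(self):
        with pytest.raises(UndefinedVafError):
            compute_vaf(0, 0, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(0, 10**6), st.integers(0, 10**6))
    def test_range_and_no_other_allele_limit(self, ta, tr, to):
        if ta + tr + to == 0:
            return
        v = compute_vaf(ta, tr, to)
        assert 0.0 <= v <= 100.0
        if to == 0:
            assert v == pytest.approx(100.0 * ta / (ta + tr))


class TestRfGate:
    def test_boundary_inclusive_on_keep_side(self):
        kept, removed = filter_by_rf_score(
            [make_call(rf=0.70), make_call(rf=0.69, pos=2)])
        assert [c.rf_score for c in kept] == [0.70]
        assert [c.rf_score for c in removed] == [0.69]

    def test_empty_input(self):
        assert filter_by_rf_score([]) == ([], [])

    def test_missing_score_policy(self):
        calls = [make_call(rf=None)]
        assert filter_by_rf_score(calls, missing="remove")[1] == calls
        assert filter_by_rf_score(calls, missing="keep")[0] == calls


class TestVafWindow:
    @pytest.mark.parametrize("vaf,bin", [
        (1.0, "kept"), (40.0, "kept"), (40.1, "high"), (0.7, "low"), (0.99, "low"),
    ])
    def test_boundaries(self, vaf, bin):
        kept, low, high = filter_by_vaf_window([make_call(vaf_pct=vaf)])
        got = "kept" if kept else ("low" if low else "high")
        assert got == bin

    def test_inverted_window_rejected(self):
        with pytest.raises(ConfigError):
            filter_by_vaf_window([], min_vaf=40, max_vaf=1)


class TestClassifyOrigin:
    def test_buffy_not_saliva_is_clonal_hematopoiesis(self):
        plasma = [make_call(vaf_pct=1.0)]
        buffy = [make_call(source=Source.BUFFY_COAT, vaf_pct=1.0)]
        (label,) = classify_origin(plasma, buffy, saliva_calls=[])
        assert label.label is Origin.CLONAL_HEMATOPOIESIS
        assert label.evidence == {Source.PLASMA, Source.BUFFY_COAT}

    def test_without_saliva_buffy_hit_is_flagged_germline(self):
        plasma = [make_call(vaf_pct=1.0)]
        buffy = [make_call(source=Source.BUFFY_COAT, vaf_pct=1.0)]
        (label,) = classify_origin(plasma, buffy, saliva_calls=None)
        assert label.label is Origin.GERMLINE and label.ch_indeterminate

    def test_buffy_and_saliva_is_germline(self):
        plasma = [make_call(gene="EGFR", chrom="chr7", pos=55259450, ref="G", alt="A",
                            vaf_pct=49.0)]
        buffy = [make_call(source=Source.BUFFY_COAT, gene="EGFR", chrom="chr7",
                           pos=55259450, ref="G", alt="A", vaf_pct=50.0)]
        saliva = [make_call(source=Source.SALIVA, gene="EGFR", chrom="chr7",
                            pos=55259450, ref="G", alt="A", vaf_pct=51.0)]
        (label,) = classify_origin(plasma, buffy, saliva)
        assert label.label is Origin.GERMLINE and not label.ch_indeterminate

    def test_saliva_only_is_germline(self):
        plasma = [make_call(vaf_pct=2.0)]
        saliva = [make_call(source=Source.SALIVA, vaf_pct=50.0)]
        (label,) = classify_origin(plasma, [], saliva)
        assert label.label is Origin.GERMLINE

    def test_absent_from_normals_is_somatic(self):
        (label,) = classify_origin([make_call(vaf_pct=2.0)], [], [])
        assert label.label is Origin.SOMATIC

    def test_mixed_participants_rejected(self):
        with pytest.raises(DataError):
            classify_origin([make_call(pid="P1")],
                            [make_call(pid="P2", source=Source.BUFFY_COAT)])


class TestRestrictToTargets:
    REGION = TargetRegion("chr17", 7577000, 7577100, "TP53")

    @pytest.mark.parametrize("pos,kept", [
        (7577001, True),    # 1-based 7577001 == 0-based 7577000, first base
        (7577100, True),    # last base inside the half-open interval
        (7577101, False),   # 0-based 7577100 == end -> outside
        (7577000, False),
    ])
    def test_coordinate_conversion(self, pos, kept):
        got, _ = restrict_to_targets([make_call(pos=pos)], [self.REGION])
        assert bool(got) is kept

    def test_chromosome_compared_verbatim(self):
        _, removed = restrict_to_targets(
            [make_call(chrom="17", pos=7577001)], [self.REGION])
        assert removed

    def test_empty_calls(self):
        assert restrict_to_targets([], [self.REGION]) == ([], [])


class TestDdpcrAdjudication:
    def _call(self, key, positive):
        return DdpcrCall(key=key, participant_id="P1", positive=positive, reason="")

    def test_positive_overrides_low_vaf_removal(self):
        low = make_call(vaf_pct=0.5)
        kept, added, excluded = apply_ddpcr_adjudication(
            [], [low], [self._call(low.key, True)])
        assert kept == [low] and added == [low] and excluded == []

    def test_negative_overrides_retention(self):
        c = make_call(vaf_pct=2.0)
        kept, _, excluded = apply_ddpcr_adjudication([c], [], [self._call(c.key, False)])
        assert kept == [] and excluded == [c]

    def test_unassayed_variants_keep_their_fate(self):
        c = make_call(vaf_pct=2.0)
        low = make_call(vaf_pct=0.5, pos=7577002)
        kept, added, excluded = apply_ddpcr_adjudication([c], [low], [])
        assert kept == [c] and added == [] and excluded == []

    def test_conflicting_duplicates_rejected(self):
        c = make_call(vaf_pct=2.0)
        with pytest.raises(DataError):
            apply_ddpcr_adjudication(
                [c], [], [self._call(c.key, True), self._call(c.key, False)])


class TestPipeline:
    def test_clean_somatic_call_survives(self):
        cs = run_filter_pipeline(
            [make_call(vaf_pct=2.0, rf=0.9)],
            regions=[TargetRegion("chr17", 7577000, 7577100, "TP53")])
        assert len(cs.surviving) == 1
        assert cs.fates[("P1", cs.surviving[0].key)] == "kept"

    def test_negative_ddpcr_excludes_despite_good_vaf(self):
        call = make_call(vaf_pct=19.4, rf=0.9)
        cs = run_filter_pipeline(
            [call], regions=[TargetRegion("chr17", 7577000, 7577100, "TP53")],
            ddpcr_calls=[DdpcrCall(call.key, "P1", False, "")])
        assert cs.surviving == []
        assert cs.fates[("P1", call.key)] == "removed:ddpcr_negative"

    def test_confirmed_high_vaf_exempt_from_germline_gate(self):
        call = make_call(vaf_pct=78.4, rf=0.9)
        cs = run_filter_pipeline(
            [call], regions=[TargetRegion("chr17", 7577000, 7577100, "TP53")],
            ddpcr_calls=[DdpcrCall(call.key, "P1", True, "")])
        assert cs.surviving == [call]

    def test_confirmed_ch_variant_stays_excluded(self):
        """ddPCR confirms presence, not somatic origin: a buffy-concordant
        low-VAF variant must not re-enter via add-back."""
        call = make_call(vaf_pct=0.8, rf=0.9)
        buffy = make_call(source=Source.BUFFY_COAT, vaf_pct=0.9)
        cs = run_filter_pipeline(
            [call], [buffy], saliva_calls=[],
            regions=[TargetRegion("chr17", 7577000, 7577100, "TP53")],
            ddpcr_calls=[DdpcrCall(call.key, "P1", True, "")])
        assert cs.surviving == []
        (label,) = cs.origin_labels
        assert label.label is Origin.CLONAL_HEMATOPOIESIS

    def test_ledger_fixture_bookkeeping(self):
        plasma, buffy, saliva, tumour, regions, assays = filter_ledger_fixture()
        cs = run_filter_pipeline(plasma, buffy, saliva, tumour, regions,
                                 call_ddpcr_batch(assays))
        assert [s.name for s in cs.ledger] == [
            "rf_score_gate", "low_vaf_gate", "germline_ch_exclusion",
            "on_target_restriction", "ddpcr_adjudication", "high_vaf_gate"]
        # conservation: n_in[k+1] = n_in[k] - removed[k] + added[k]
        for prev, nxt in zip(cs.ledger, cs.ledger[1:]):
            assert nxt.n_in == prev.n_in - prev.n_removed + prev.n_added
        assert [(s.n_removed, s.n_added) for s in cs.ledger] == [
            (3, 0), (3, 0), (2, 0), (2, 0), (2, 1), (1, 0)]
        assert len(cs.surviving) == 8

    def test_only_ddpcr_step_ever_adds(self):
        plasma, buffy, saliva, tumour, regions, assays = filter_ledger_fixture()
        cs = run_filter_pipeline(plasma, buffy, saliva, tumour, regions,
                                 call_ddpcr_batch(assays))
        for step in cs.ledger:
            if step.name != "ddpcr_adjudication":
                assert step.n_added == 0
        assert {c.key for c in cs.surviving} <= {c.key for c in plasma}

    def test_adjudication_order_is_neutral_for_unassayed_variants(self):
        """Without ddPCR evidence the pipeline's outcome equals the plain gate
        cascade: adjudication placement only matters for assayed variants."""
        plasma, buffy, saliva, tumour, regions, _ = filter_ledger_fixture()
        with_step = run_filter_pipeline(plasma, buffy, saliva, tumour, regions, [])
        kept, _ = filter_by_rf_score(plasma)
        kept, _, _ = filter_by_vaf_window(kept)
        labels = classify_origin(kept, buffy, saliva, tumour)
        somatic = {l.key for l in labels if l.label is Origin.SOMATIC}
        kept = [c for c in kept if c.key in somatic]
        kept, _ = restrict_to_targets(kept, regions)
        kept = [c for c in kept if not (compute_vaf(c.ta, c.tr, c.to) > 40.0)]
        assert {c.key for c in with_step.surviving} == {c.key for c in kept}

    def test_missing_rf_policy_is_configurable(self):
        call = make_call(rf=None, vaf_pct=2.0)
        regions = [TargetRegion("chr17", 7577000, 7577100, "TP53")]
        assert run_filter_pipeline([call], regions=regions).surviving == []
        cfg = FilterConfig(missing_rf="keep")
        assert run_filter_pipeline([call], regions=regions, config=cfg).surviving == [call]
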