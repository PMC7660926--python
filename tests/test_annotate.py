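import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stabscan.annotate import (AnnotationError, ClinicalCategory,
                               MotifPatternError, StabilityClass,
                               build_fishtail, classify_stability,
                               compile_motif, fishtail_to_tsv, heatmap_matrix,
                               load_clinical_table, load_frequency_table,
                               scan_usp7_motifs)
from stabscan.ddg import DdgRecord
from stabscan.variants import Variant, VariantKind, parse_variant


def rec(label, ddg):
    return DdgRecord(variant=parse_variant(label), ddg_kcal=ddg, raw_stat=ddg * 2.9)


class TestClassifyStability:
    def test_near_neutral_value(self):
        assert classify_stability(0.02) is StabilityClass.NEUTRAL

    def test_destabilized_value(self):
        assert classify_stability(5.0) is StabilityClass.DESTABILIZED

    def test_boundary_inclusive_on_destabilized_side(self):
        assert classify_stability(3.0) is StabilityClass.DESTABILIZED

    def test_intermediate_band(self):
        assert classify_stability(2.0) is StabilityClass.INTERMEDIATE

    def test_neutral_boundary_exclusive(self):
        assert classify_stability(1.0) is StabilityClass.INTERMEDIATE

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            classify_stability(0.0, neutral_max=4.0, destabilized_min=3.0)

    @given(st.lists(st.floats(-5, 10), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_ddg(self, values):
        order = {StabilityClass.NEUTRAL: 0, StabilityClass.INTERMEDIATE: 1,
                 StabilityClass.DESTABILIZED: 2}
        ranks = [order[classify_stability(v)] for v in sorted(values)]
        assert ranks == sorted(ranks)


class TestLoadFrequencyTable:
    HEADER = "variant\tallele_count\tallele_number\tfrequency\n"

    def test_direct_parse(self):
        records, rejects = load_frequency_table(
            self.HEADER + "K508R\t20\t100000\t2.0e-4\n")
        assert rejects == []
        assert len(records) == 1
        assert records[0].frequency == pytest.approx(2.0e-4)
        assert records[0].variant == parse_variant("K508R")

    def test_inconsistent_frequency_rejected(self):
        records, rejects = load_frequency_table(
            self.HEADER + "K508R\t20\t100000\t5.0e-4\n")
        assert records == []
        assert len(rejects) == 1 and "inconsistent" in rejects[0]

    def test_empty_file_with_header(self):
        records, rejects = load_frequency_table(self.HEADER)
        assert records == [] and rejects == []

    def test_missing_column_raises(self):
        with pytest.raises(AnnotationError, match="frequency"):
            load_frequency_table("variant\tallele_count\tallele_number\nK508R\t1\t2\n")

    def test_bad_variant_label_goes_to_rejects(self):
        records, rejects = load_frequency_table(
            self.HEADER + "XYZ\t20\t100000\t2.0e-4\n")
        assert records == [] and len(rejects) == 1


class TestLoadClinicalTable:
    def test_paper_style_aliases(self):
        tsv = ("variant\tcategory\n"
               "R362C\tVUS\nK508R\tLike. benign\nΔK508\tPathogenic\n"
               "V400I\tConflicting\n")
        labels = load_clinical_table(tsv)
        assert [l.category for l in labels] == [
            ClinicalCategory.VUS, ClinicalCategory.LIKELY_BENIGN,
            ClinicalCategory.PATHOGENIC, ClinicalCategory.CONFLICTING]

    def test_unknown_category_rejected(self):
        with pytest.raises(AnnotationError, match="unknown clinical category"):
            load_clinical_table("variant\tcategory\nR362C\tSPOOKY\n")


class TestBuildFishtail:
    def test_ddg_only_rows_have_absent_annotations(self):
        result = build_fishtail([rec("R362C", 2.9), rec("ΔK508", 5.0)])
        assert len(result.rows) == 2
        assert all(r.frequency is None and r.category is None for r in result.rows)

    def test_join_never_drops_records(self):
        records = [rec(f"A{i}V", 0.5) for i in range(1, 30)]
        freq, _ = load_frequency_table(
            "variant\tallele_count\tallele_number\tfrequency\nA5V\t1\t100000\t1e-5\n")
        result = build_fishtail(records, freq=freq)
        assert len(result.rows) == len(records)

    def test_known_neutral_variant_attached(self):
        freq, _ = load_frequency_table(
            "variant\tallele_count\tallele_number\tfrequency\nV400I\t4\t160000\t2.5e-5\n")
        result = build_fishtail([rec("V400I", 0.7)], freq=freq)
        row = result.rows[0]
        assert row.frequency == pytest.approx(2.5e-5)
        assert row.stability_class is StabilityClass.NEUTRAL

    def test_duplicate_annotation_raises_with_variant_name(self):
        freq, _ = load_frequency_table(
            "variant\tallele_count\tallele_number\tfrequency\n"
            "V400I\t4\t160000\t2.5e-5\nV400I\t8\t160000\t5e-5\n")
        with pytest.raises(AnnotationError, match="V400I"):
            build_fishtail([rec("V400I", 0.7)], freq=freq)

    def test_unmatched_annotations_reported(self):
        freq, _ = load_frequency_table(
            "variant\tallele_count\tallele_number\tfrequency\nW99G\t1\t100000\t1e-5\n")
        result = build_fishtail([rec("V400I", 0.7)], freq=freq)
        assert result.unmatched_frequency == ["W99G"]

    def test_rows_sorted_by_position(self):
        result = build_fishtail([rec("ΔK508", 5.0), rec("R362C", 2.9), rec("K508R", 0.02)])
        assert [str(r.variant) for r in result.rows] == ["R362C", "K508R", "ΔK508"]

    def test_enrichment_on_synthetic_tables(self):
        from stabscan.synthetic import (SyntheticAnnotationSpec,
                                        make_annotation_tables,
                                        truth_to_ddg_records)
        spec = SyntheticAnnotationSpec(n_common=60, n_rare_pathogenic=30, seed=3)
        freq_tsv, label_tsv, truth = make_annotation_tables(spec)
        freq, rejects = load_frequency_table(freq_tsv)
        assert rejects == []
        labels = load_clinical_table(label_tsv)
        result = build_fishtail(truth_to_ddg_records(truth), freq=freq, labels=labels)
        strata = dict(zip(truth["variant"], truth["stratum"]))
        a = b = c = d = 0  # destabilized/other x pathogenic/common
        for row in result.rows:
            dest = row.stability_class is StabilityClass.DESTABILIZED
            path = strata[str(row.variant)] == "rare_pathogenic"
            if dest and path:
                a += 1
            elif dest:
                b += 1
            elif path:
                c += 1
            else:
                d += 1
        odds_ratio = (a * d) / max(1, b * c)
        assert odds_ratio > 1

    def test_tsv_export_has_log_frequency(self):
        freq, _ = load_frequency_table(
            "variant\tallele_count\tallele_number\tfrequency\nV400I\t1\t100000\t1e-5\n")
        tsv = fishtail_to_tsv(build_fishtail([rec("V400I", 0.7)], freq=freq))
        assert "log10_frequency" in tsv.splitlines()[0]
        assert "-5.0000" in tsv


class TestHeatmapMatrix:
    def test_range_column_count(self):
        assert 520 - 490 + 1 == 31
        records = [rec("A500V", 1.0)]
        m = heatmap_matrix(records, 490, 520)
        assert len(m.positions) == 31
        assert m.values.shape == (21, 31)

    def test_toy_full_matrix(self, fast_spec):
        from stabscan.ddg import ProtocolConfig, saturation_scan
        from stabscan.synthetic import make_ideal_helix
        h = make_ideal_helix(5, "LKALE")
        cfg = ProtocolConfig(n_models=2, n_traj=1, n_iter_missense=1, master_seed=2)
        recs = saturation_scan(h, fast_spec, cfg)
        m = heatmap_matrix(recs, 1, 5)
        assert m.values.shape == (21, 5)
        assert m.rows[0] == "del"
        # identity cells exactly zero
        for j, pos in enumerate(m.positions):
            wt = h.find(pos).key.aa
            assert m.values[m.rows.index(wt), j] == 0.0
        assert not np.isnan(m.values).any()

    def test_deletion_cell_lookup(self):
        m = heatmap_matrix([rec("ΔK508", 5.0)], 505, 510)
        assert m.values[0, m.positions.index(508)] == 5.0

    def test_empty_range_raises(self):
        with pytest.raises(AnnotationError):
            heatmap_matrix([rec("A500V", 1.0)], 1, 10)

    def test_tsv_round_shape(self):
        m = heatmap_matrix([rec("A500V", 1.0)], 499, 501)
        lines = m.to_tsv().strip().splitlines()
        assert len(lines) == 22

    def test_render_writes_png(self, tmp_path):
        m = heatmap_matrix([rec("A500V", 1.0)], 499, 501)
        out = tmp_path / "hm.png"
        m.render(str(out))
        assert out.stat().st_size > 0


def motif_oracle(sequence, pattern_classes):
    """Brute-force sliding window matcher."""
    hits = []
    k = len(pattern_classes)
    for i in range(len(sequence) - k + 1):
        window = sequence[i:i + k]
        if all(cls is None or window[j] in cls for j, cls in enumerate(pattern_classes)):
            hits.append((i + 1, window))
    return hits


class TestMotifScan:
    def test_traf_motif_at_anchor_position(self):
        seq = "G" * 235 + "AARS" + "G" * 20
        hits = scan_usp7_motifs(seq, {"TRAF": "[PA]xxS"})
        assert ("TRAF", 236, "AARS") in hits

    def test_ubl_consensus_matches_known_site(self):
        seq = "GGGKVKVLFKGGG"
        hits = scan_usp7_motifs(seq, {"UBL12": "KxKxxxK"})
        assert ("UBL12", 4, "KVKVLFK") in hits

    def test_empty_sequence_no_matches(self):
        assert scan_usp7_motifs("", None) == []

    def test_overlapping_matches_reported(self):
        hits = scan_usp7_motifs("ASSS", {"M": "[PA]xxS"})
        assert [h[1] for h in hits] == [1]
        hits = scan_usp7_motifs("PAPSAS", {"M": "[PA]xxS"})
        assert [h[1] for h in hits] == [1, 3]

    def test_invalid_pattern_syntax(self):
        with pytest.raises(MotifPatternError):
            compile_motif("[PA")
        with pytest.raises(MotifPatternError):
            compile_motif("")

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_equal_bruteforce_oracle(self, seq):
        pattern = "[PA]x[ST]"
        classes = compile_motif(pattern)
        got = [(pos, m) for _, pos, m in scan_usp7_motifs(seq, {"P": pattern})]
        assert got == motif_oracle(seq, classes)
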