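"""Pseudogene criteria: alignment, event detection, hydrophobicity, lift."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pseudoplast.codons import SENSE_CODONS, revcomp, translate
from pseudoplast.io import PlastomeRecord, extract_cds
from pseudoplast.scan import (ScanConfig, align_gene_to_reference,
                              annotate_by_homology, detect_events,
                              hydrophobic_fraction, hydrophobicity_ci,
                              scan_genome)
from pseudoplast.simulate import inject_degradation


class TestPairwiseAlignment:
    def test_identical_sequences_gapless(self):
        aln = align_gene_to_reference("ATGAAATAG", "ATGAAATAG")
        assert aln.ref == aln.focal == "ATGAAATAG"
        assert aln.identity() == 1.0

    @pytest.mark.parametrize("gap_len", [1, 3])
    def test_single_deletion_single_gap(self, gap_len):
        ref = "ATGAAACCCGGGAAACCCGGGTGGTAA"
        focal = ref[:9] + ref[9 + gap_len:]
        import itertools

        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        assert aln.focal.count("-") == gap_len
        n_runs = sum(1 for k, _ in itertools.groupby(aln.focal) if k == "-")
        assert n_runs == 1
        n = len(ref)
        assert aln.identity() == pytest.approx((n - gap_len) / n)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            align_gene_to_reference("", "ATG")


class TestDetectEvents:
    def test_identical_no_events(self):
        aln = align_gene_to_reference("ATGAAACCCTAA", "ATGAAACCCTAA")
        assert detect_events(aln) == []

    def test_hand_traced_frameshift_and_lost_stop(self):
        """One-base deletion in codon 3 shifts the frame; no downstream
        in-frame stop remains, so the canonical stop is lost too."""
        ref = "ATGAAACCCGGGTGGTAA"
        focal = "ATGAAACCGGGTGGTAA"
        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        kinds = {e.kind for e in detect_events(aln)}
        assert kinds == {"frameshift", "lost_canonical_stop"}

    def test_point_mutation_stop_without_frameshift(self):
        ref = "ATG" + "AAA" * 20 + "TGGCTT" + "AAA" * 10 + "TAA"
        focal = ref.replace("TGGCTT", "TGACTT")  # TGG -> TGA mid-gene
        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        kinds = [e.kind for e in detect_events(aln)]
        assert kinds == ["premature_stop"]

    def test_in_frame_large_deletion_is_sole_primary_event(self):
        ref = "ATG" + "GAACAT" * 60 + "TAA"
        focal = ref[:30] + ref[30 + 120:]
        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        events = detect_events(aln)
        assert [e.kind for e in events] == ["large_deletion"]
        assert "length=120" in events[0].detail

    def test_deletion_below_threshold_not_large(self):
        ref = "ATG" + "GAACAT" * 60 + "TAA"
        focal = ref[:30] + ref[30 + 99:]
        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        assert "large_deletion" not in {e.kind for e in detect_events(aln)}


def test_frameshift_detector_matches_three_frame_translation_oracle():
    """Brute-force oracle: translate the lesioned gene in all three frames;
    the frame is shifted iff the reference C-terminal peptide is only
    recoverable in a non-zero frame.  200 random single-indel fixtures."""
    rng = np.random.default_rng(42)
    agree = 0
    for trial in range(200):
        codons = rng.choice(len(SENSE_CODONS), size=80)
        ref = "ATG" + "".join(SENSE_CODONS[c] for c in codons) + "TAA"
        indel = int(rng.choice([-3, -2, -1, 1, 2, 3]))
        pos = int(rng.integers(12, len(ref) - 30))
        if indel > 0:
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=indel)])
            focal = ref[:pos] + ins + ref[pos:]
        else:
            focal = ref[:pos] + ref[pos - indel:]
        tail_peptide = translate(ref[:-3])[-8:]
        frames = [i for i in range(3) if tail_peptide in translate(focal[i:])]
        oracle_shifted = 0 not in frames
        aln = align_gene_to_reference(focal, ref, free_ref_end_gaps=False)
        detected = any(e.kind == "frameshift" for e in detect_events(aln))
        assert detected == oracle_shifted, (trial, indel, pos)
        agree += 1
    assert agree == 200


class TestHydrophobicity:
    @pytest.mark.parametrize("protein,expected", [
        ("LLLL", 1.0), ("KRKR", 0.0), ("LKLK", 0.5)])
    def test_fraction_known_values(self, protein, expected):
        assert hydrophobic_fraction(protein) == expected

    def test_stops_and_x_excluded_from_denominator(self):
        assert hydrophobic_fraction("LK*X") == 0.5

    def test_empty_countable_rejected(self):
        with pytest.raises(ValueError):
            hydrophobic_fraction("XX**")

    @given(st.permutations(list("LKAVREDFIM")))
    @settings(max_examples=30, deadline=None)
    def test_fraction_order_invariant(self, residues):
        assert hydrophobic_fraction("".join(residues)) == \
            hydrophobic_fraction("LKAVREDFIM")

    def test_ci_matches_t_quantile_oracle(self):
        low, high = hydrophobicity_ci([0.50, 0.52, 0.54], 0.95)
        # oracle: mean +- t_{0.975,2} * sd / sqrt(3), computed independently
        x = np.array([0.50, 0.52, 0.54])
        tq = sps.t.ppf(0.975, 2)
        assert low == pytest.approx(x.mean() - tq * x.std(ddof=1) / np.sqrt(3))
        assert (round(low, 4), round(high, 4)) == (0.4703, 0.5697)

    def test_ci_degenerate_panel_collapses_to_point(self):
        low, high = hydrophobicity_ci([0.4, 0.4, 0.4])
        assert low == pytest.approx(0.4) and high == pytest.approx(0.4)

    def test_wider_level_nests_narrower(self):
        panel = [0.48, 0.53, 0.55, 0.60]
        l95, h95 = hydrophobicity_ci(panel, 0.95)
        l99, h99 = hydrophobicity_ci(panel, 0.99)
        assert l99 < l95 < h95 < h99

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            hydrophobicity_ci([0.5, 0.6])


class TestAnnotateByHomology:
    def test_identical_target_gets_identical_coordinates(self, panel):
        ref = panel.records["panel_1"]
        target = PlastomeRecord(id="t", sequence=ref.sequence)
        lifted = annotate_by_homology(target, ref)
        for f in ref.features:
            lf = lifted.gene(f.gene_name)
            assert lf.segments == f.segments or \
                extract_cds(lifted, f.gene_name) == extract_cds(ref, f.gene_name)

    def test_upstream_insertion_shifts_all_models(self, panel):
        ref = panel.records["panel_1"]
        pad = "".join(np.array(list("ACGT"))[
            np.random.default_rng(3).integers(0, 4, size=500)])
        target = PlastomeRecord(id="t", sequence=pad + ref.sequence)
        lifted = annotate_by_homology(target, ref)
        for f in ref.features:
            if f.kind == "rRNA":
                continue  # IR duplicates: either copy is a valid hit
            lf = lifted.gene(f.gene_name)
            assert lf.segments == [(f.segments[0][0] + 500, f.segments[0][1] + 500)]

    def test_diverged_panel_member_fully_lifted(self, panel):
        ref = panel.records["panel_1"]
        other = panel.records["panel_4"]
        target = PlastomeRecord(id="t", sequence=other.sequence)
        lifted = annotate_by_homology(target, ref)
        assert lifted.meta["missing_genes"] == []
        idents = lifted.meta["lift_identity"]
        assert all(v >= 0.70 for v in idents.values())


class TestScanGenome:
    def test_clean_focal_zero_pseudogene_verdicts(self, panel, panel_records):
        report = scan_genome(panel.focal, panel_records)
        assert report.flagged() == []

    def test_injected_lesions_flag_exactly_those_genes(self, panel, panel_records):
        spec = [("rbcL", "premature_stop", {}), ("matK", "frameshift", {}),
                ("petA", "large_deletion", {"length": 150})]
        focal, truth = inject_degradation(panel.focal, spec, seed=3)
        report = scan_genome(focal, panel_records)
        assert report.flagged() == ["matK", "petA", "rbcL"]

    def test_inversion_reported_on_injected_gene(self, panel, panel_records):
        focal, _ = inject_degradation(panel.focal, [("psaA", "short_inversion",
                                                     {"length": 60})], seed=9)
        report = scan_genome(focal, panel_records)
        assert any(e.kind == "short_inversion"
                   for e in report.per_gene["psaA"].events)

    def test_termination_shift_reports_extension_length(self, panel, panel_records):
        focal, _ = inject_degradation(panel.focal, [("cemA", "termination_shift",
                                                     {"extension": 138})], seed=2)
        report = scan_genome(focal, panel_records)
        kinds = {e.kind: e for e in report.per_gene["cemA"].events}
        assert "lost_canonical_stop" in kinds
        assert "extension=138" in kinds["novel_termination"].detail

    def test_empty_panel_rejected(self, panel):
        with pytest.raises(ValueError, match="panel"):
            scan_genome(panel.focal, [])

    def test_excluded_boundary_genes_not_scanned(self, panel, panel_records):
        config = ScanConfig(excluded_genes=("rbcL",))
        report = scan_genome(panel.focal, panel_records, config)
        assert "rbcL" not in report.per_gene
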