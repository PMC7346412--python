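"""Synthetic-data generator: determinism, model forcing, ledger round trips."""

import numpy as np
import pytest
from scipy import stats as sps

from pseudoplast.codons import SENSE_CODONS, translate
from pseudoplast.io import extract_cds
from pseudoplast.selection import (CodonModelParams, compile_tree,
                                   tree_from_newick)
from pseudoplast.simulate import (SyntheticConfig, _stationary_pi,
                                  build_synthetic_plastome, inject_degradation,
                                  simulate_codon_evolution)


class TestSimulateCodonEvolution:
    def _tree(self, t=0.2):
        return compile_tree(tree_from_newick(f"(a:{t},b:{t},c:{t});"))

    def test_omega_zero_forbids_nonsynonymous_changes(self):
        ct = self._tree(0.5)
        params = CodonModelParams(kappa=2.0, pi=_stationary_pi(),
                                  branch_lengths={}, omegas=0.0)
        seqs, counts = simulate_codon_evolution(ct, params, 200, seed=3)
        assert all(nn == 0 for _, nn in counts.values())
        assert sum(ns for ns, _ in counts.values()) > 0
        prot = {t: translate(s) for t, s in seqs.items()}
        assert len(set(prot.values())) == 1  # synonymous-only evolution

    def test_zero_branch_lengths_identical_tips(self):
        ct = self._tree(0.0)
        params = CodonModelParams(kappa=2.0, pi=_stationary_pi(),
                                  branch_lengths={}, omegas=0.5)
        seqs, counts = simulate_codon_evolution(ct, params, 100, seed=3)
        assert len(set(seqs.values())) == 1
        assert all(c == (0, 0) for c in counts.values())

    def test_long_branch_reaches_stationarity(self):
        """Tip codon frequencies after a very long branch are consistent with
        pi by a chi-square goodness-of-fit test at alpha = 0.01."""
        pi = _stationary_pi()
        ct = compile_tree(tree_from_newick("(a:0.001,b:25.0);"))
        params = CodonModelParams(kappa=2.0, pi=pi, branch_lengths={},
                                  omegas=1.0)
        seqs, _ = simulate_codon_evolution(ct, params, 4000, seed=5)
        idx = {c: i for i, c in enumerate(SENSE_CODONS)}
        obs = np.zeros(61)
        b = seqs["b"]
        for k in range(0, len(b), 3):
            obs[idx[b[k:k + 3]]] += 1
        stat, p = sps.chisquare(obs, f_exp=pi * obs.sum())
        assert p > 0.01

    def test_mean_substitutions_match_branch_length(self):
        """Simulator/likelihood consistency: expected substitutions per codon
        equal the branch length (rate matrix is normalized), within 3 SE."""
        ct = self._tree(0.15)
        params = CodonModelParams(kappa=2.0, pi=_stationary_pi(),
                                  branch_lengths={}, omegas=0.4)
        n_codons, reps = 100, 200
        per_branch = {k: [] for k in ct.edge_keys}
        for r in range(reps):
            _, counts = simulate_codon_evolution(ct, params, n_codons, seed=900 + r)
            for k, (ns, nn) in counts.items():
                per_branch[k].append((ns + nn) / n_codons)
        for k, vals in per_branch.items():
            vals = np.array(vals)
            se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - 0.15) < 3 * se + 1e-9


class TestBuildSyntheticPlastome:
    def test_same_seed_byte_identical(self):
        a = build_synthetic_plastome(SyntheticConfig(seed=33))
        b = build_synthetic_plastome(SyntheticConfig(seed=33))
        assert {t: r.sequence for t, r in a.records.items()} == \
            {t: r.sequence for t, r in b.records.items()}

    def test_adding_a_gene_does_not_perturb_other_genes(self):
        base = SyntheticConfig(seed=33)
        extended = SyntheticConfig(seed=33,
                                   genes=base.genes + [("petB", 110)])
        a = build_synthetic_plastome(base)
        b = build_synthetic_plastome(extended)
        for gene, rows in a.gene_alignments.items():
            assert b.gene_alignments[gene] == rows

    def test_planted_ir_recovered_by_detector(self, panel):
        from pseudoplast.structure import detect_inverted_repeat

        rec = panel.records["panel_5"]
        s = detect_inverted_repeat(rec.sequence, max_mismatch_frac=0.0)
        assert s.ir_length == panel.config.ir_length
        assert (s.irb, s.ira) == (rec.meta["regions"]["irb"],
                                  rec.meta["regions"]["ira"])

    def test_oversized_rrna_content_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            build_synthetic_plastome(SyntheticConfig(seed=1, ir_length=1000))

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            build_synthetic_plastome(SyntheticConfig(seed=1, genes=[],
                                                     ssc_genes=[]))


class TestInjectDegradation:
    def test_empty_spec_is_identity(self, panel):
        rec, truth = inject_degradation(panel.focal, [], seed=1)
        assert rec.sequence == panel.focal.sequence
        assert truth.events == []

    def test_ledger_records_each_event_once(self, panel):
        spec = [("rbcL", "premature_stop", {}), ("matK", "frameshift", {}),
                ("atpB", "large_deletion", {"length": 150})]
        rec, truth = inject_degradation(panel.focal, spec, seed=2)
        assert len(truth.events) == 3
        assert truth.genes_with("premature_stop") == {"rbcL"}
        assert truth.genes_with("large_deletion") == {"atpB"}

    def test_downstream_annotations_shifted_consistently(self, panel):
        """After a 150 bp deletion, every downstream gene still extracts an
        intact CDS (coordinates were updated)."""
        rec, _ = inject_degradation(panel.focal,
                                    [("psbA", "large_deletion", {"length": 150})],
                                    seed=3)
        assert rec.length == panel.focal.length - 150
        for gene in rec.gene_names("protein_coding"):
            if gene == "psbA":
                continue
            assert extract_cds(rec, gene) == extract_cds(panel.focal, gene)

    def test_impossible_stop_creation_reported(self):
        from pseudoplast.io import GeneModel, PlastomeRecord

        seq = "ATG" + "CCC" * 60 + "TAA"  # no codon one substitution from a stop
        rec = PlastomeRecord(id="x", sequence=seq + "ACGT" * 50,
                             features=[GeneModel("g", "protein_coding",
                                                 [(0, len(seq))], "+")])
        with pytest.raises(ValueError, match="no codon mutable"):
            inject_degradation(rec, [("g", "premature_stop", {})], seed=1)

    def test_focal_genome_is_smaller_than_panel(self, panel):
        sizes = [r.length for r in panel.panel_records()]
        assert panel.focal.length < min(sizes)
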