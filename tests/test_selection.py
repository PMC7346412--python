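"""GY94 codon-model likelihood, branch fits, LRT, Hochberg adjustment."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.linalg import expm

from pseudoplast.selection import (CodonAlignment, CodonModelParams, GY94,
                                   ModelFit, build_codon_alignment,
                                   compile_tree, fit_branch_model,
                                   gy94_loglik, hochberg_adjust, lrt,
                                   tip_edge_key, tree_from_newick)
from pseudoplast.simulate import _stationary_pi, simulate_codon_evolution


def brute_force_loglik(aln, ct, kappa, pi, t_by_key, omega_by_key):
    """Independent oracle: explicit summation over all internal-node codon
    assignments (no pruning recursion)."""
    model = GY94(pi)
    P = {}
    for i in ct.postorder:
        if i == ct.root:
            continue
        key = ct.edge_key[i]
        t = 0.0 if i == ct.merged_root_child else t_by_key[key]
        P[i] = model.transition_matrix(kappa, omega_by_key[key], t)
    internals = [i for i in ct.postorder if ct.tip_label[i] is None]
    tips = {i: aln.taxa.index(ct.tip_label[i]) for i in ct.postorder
            if ct.tip_label[i] is not None}
    ll = 0.0
    for site in range(aln.length):
        total = 0.0
        for combo in itertools.product(range(61), repeat=len(internals)):
            state = dict(zip(internals, combo))
            for i, row in tips.items():
                state[i] = int(aln.states[row, site])
            prob = model.pi[state[ct.root]]
            for i in ct.postorder:
                if i != ct.root:
                    prob *= P[i][state[ct.parent[i]], state[i]]
            total += prob
        ll += np.log(total)
    return ll


class TestGy94Loglik:
    def test_zero_branch_lengths_closed_form(self):
        pi = np.ones(61) / 61
        states = np.array([[0, 5, 10]] * 3)
        aln = CodonAlignment(taxa=["a", "b", "c"], states=states, pi=pi)
        ct = compile_tree(tree_from_newick("(a:0,b:0,c:0);"))
        params = CodonModelParams(kappa=2.0, pi=pi,
                                  branch_lengths={k: 0.0 for k in ct.edge_keys},
                                  omegas=0.3)
        expected = np.log(GY94(pi).pi[[0, 5, 10]]).sum()
        assert gy94_loglik(aln, ct, params) == pytest.approx(expected, abs=1e-9)

    def test_two_taxon_matches_matrix_exponential_oracle(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(61))
        kappa, omega, t = 3.1, 0.4, 0.7
        states = np.array([[0, 7, 20, 60, 33], [2, 7, 19, 60, 5]])
        aln = CodonAlignment(taxa=["a", "b"], states=states, pi=pi)
        ct = compile_tree(tree_from_newick(f"(a:{t / 2},b:{t / 2});"))
        params = CodonModelParams(kappa=kappa, pi=pi,
                                  branch_lengths={k: t for k in ct.edge_keys},
                                  omegas=omega)
        model = GY94(pi)
        P = expm(model.rate_matrix(kappa, omega) * t)
        oracle = sum(np.log(model.pi[i] * P[i, j]) for i, j in states.T)
        assert gy94_loglik(aln, ct, params) == pytest.approx(oracle, abs=1e-8)

    def test_four_taxon_matches_brute_force(self):
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(61) * 5)
        ct = compile_tree(tree_from_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.05);"))
        om = {k: float(rng.uniform(0.05, 2.0)) for k in ct.edge_keys}
        tl = {k: float(rng.uniform(0.05, 0.5)) for k in ct.edge_keys}
        aln = CodonAlignment(taxa=list("abcd"),
                             states=rng.integers(0, 61, size=(4, 5)), pi=pi)
        params = CodonModelParams(kappa=2.5, pi=pi, branch_lengths=tl, omegas=om)
        oracle = brute_force_loglik(aln, ct, 2.5, pi, tl, om)
        assert gy94_loglik(aln, ct, params) == pytest.approx(oracle, abs=1e-8)

    def test_missing_states_marginalized(self):
        pi = np.ones(61) / 61
        states = np.array([[4], [-1]])
        aln = CodonAlignment(taxa=["a", "b"], states=states, pi=pi)
        ct = compile_tree(tree_from_newick("(a:0.2,b:0.2);"))
        params = CodonModelParams(kappa=2.0, pi=pi,
                                  branch_lengths={k: 0.4 for k in ct.edge_keys},
                                  omegas=0.5)
        # with one tip missing, the site likelihood is just pi[observed]
        assert gy94_loglik(aln, ct, params) == pytest.approx(np.log(1 / 61), abs=1e-10)

    def test_taxa_mismatch_rejected(self):
        pi = np.ones(61) / 61
        aln = CodonAlignment(taxa=["a", "x"], states=np.zeros((2, 1), int), pi=pi)
        ct = compile_tree(tree_from_newick("(a:0.1,b:0.1);"))
        with pytest.raises(ValueError, match="mismatch"):
            gy94_loglik(aln, ct, CodonModelParams(2.0, pi, {}, 0.5))


def test_loglik_invariant_to_root_placement():
    """Reversibility: rerooting the same unrooted tree (edge set and per-edge
    parameters unchanged) leaves the likelihood identical."""
    pi = _stationary_pi()
    nw = "((a:0.1,b:0.2):0.12,(c:0.05,d:0.3):0.07,e:0.15);"
    ct = compile_tree(tree_from_newick(nw))
    rng = np.random.default_rng(9)
    om = {k: float(rng.uniform(0.05, 1.5)) for k in ct.edge_keys}
    params = CodonModelParams(kappa=2.5, pi=pi, branch_lengths={}, omegas=om)
    seqs, _ = simulate_codon_evolution(ct, params, 40, seed=9)
    aln = build_codon_alignment(seqs, min_remaining=30)
    lls = [gy94_loglik(aln, ct, params)]
    for tip in ["a", "c", "e"]:
        t = tree_from_newick(nw)
        e = t.find_node_with_taxon_label(tip).edge
        t.reroot_at_edge(e, length1=e.length / 2, length2=e.length / 2)
        lls.append(gy94_loglik(aln, compile_tree(t), params))
    assert max(lls) - min(lls) < 1e-8


class TestBuildCodonAlignment:
    def _seqs(self):
        return {"a": "ATGAAACCC", "b": "ATGAAACCC", "c": "ATGAAGCCC",
                "d": "ATGAAACCG"}

    def test_no_masking_all_retained(self):
        aln = build_codon_alignment(self._seqs(), min_remaining=9)
        assert aln.taxa == ["a", "b", "c", "d"] and aln.length == 3

    def test_short_sequence_dropped_after_masking(self):
        seqs = {k: v * 30 for k, v in self._seqs().items()}  # 270 bp
        seqs["b"] = "-" * 120 + seqs["b"][120:]
        aln = build_codon_alignment(seqs, min_remaining=200)
        assert "b" not in aln.taxa and len(aln.taxa) == 3

    def test_internal_stops_recoded_missing_row_kept(self):
        seqs = {k: v * 30 for k, v in self._seqs().items()}
        stopped = list(seqs["a"])
        stopped[30:33] = "TAA"
        stopped[60:63] = "TGA"
        seqs["a"] = "".join(stopped)
        aln = build_codon_alignment(seqs, min_remaining=100)
        assert "a" in aln.taxa
        assert aln.n_recoded_stops == 2
        row = aln.states[aln.taxa.index("a")]
        assert row[10] == -1 and row[20] == -1

    def test_mask_removes_columns(self):
        seqs = {k: v for k, v in self._seqs().items()}
        mask = np.zeros(9, bool)
        mask[0:3] = True
        aln = build_codon_alignment(seqs, min_remaining=6, ambiguous_mask=mask)
        assert aln.length == 2

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            build_codon_alignment({"a": "ATG", "b": "ATG"}, min_remaining=3)


@pytest.fixture(scope="module")
def null_fit():
    nw = "((focal:0.1,a:0.1):0.1,b:0.1,c:0.1);"
    ct = compile_tree(tree_from_newick(nw))
    params = CodonModelParams(kappa=2.0, pi=_stationary_pi(),
                              branch_lengths={}, omegas=0.2)
    seqs, _ = simulate_codon_evolution(ct, params, 300, seed=17)
    aln = build_codon_alignment(seqs, min_remaining=200)
    fit_c = fit_branch_model(aln, ct, "focal", constrained=True,
                             n_starts=1, seed=0)
    fit_f = fit_branch_model(aln, ct, "focal", constrained=False,
                             n_starts=1, seed=0, warm_start=fit_c)
    return ct, fit_c, fit_f


class TestFitBranchModel:
    def test_constrained_likelihood_bounded_by_full(self, null_fit):
        _, fit_c, fit_f = null_fit
        assert fit_f.logL >= fit_c.logL - 1e-6

    def test_parameters_within_bounds_and_plausible(self, null_fit):
        ct, _, fit_f = null_fit
        p = fit_f.params
        assert 0.5 < p.kappa < 10
        assert all(t > 0 for t in p.branch_lengths.values())
        fkey = tip_edge_key(ct, "focal")
        assert 1e-6 <= p.omegas[fkey] <= 999

    def test_null_data_gives_small_statistic(self, null_fit):
        _, fit_c, fit_f = null_fit
        res = lrt(fit_f, fit_c)
        assert res.statistic < 10  # no selection-regime shift simulated

    def test_single_codon_alignment_documented_degenerate_case(self):
        ct = compile_tree(tree_from_newick("((focal:0.1,a:0.1):0.1,b:0.1,c:0.1);"))
        pi = np.ones(61) / 61
        states = np.tile(np.array([[0], [0], [0], [5]]), 1)
        aln = CodonAlignment(taxa=["focal", "a", "b", "c"], states=states, pi=pi)
        fit = fit_branch_model(aln, ct, "focal", constrained=False,
                               n_starts=1, seed=0, maxiter=100)
        assert np.isfinite(fit.logL)  # converges with omega possibly at a bound


class TestLrt:
    def _fit(self, ll, constrained):
        return ModelFit(params=None, logL=ll, converged=True,
                        constrained=constrained)

    def test_equal_likelihoods(self):
        res = lrt(self._fit(-10.0, False), self._fit(-10.0, True))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_critical_value_maps_to_alpha(self):
        res = lrt(self._fit(-10.0 + 3.841 / 2, False), self._fit(-10.0, True))
        assert res.p == pytest.approx(sps.chi2.sf(3.841, 1))
        assert res.p == pytest.approx(0.05, abs=5e-4)

    def test_optimizer_fault_detected(self):
        with pytest.raises(ValueError, match="optimizer"):
            lrt(self._fit(-12.0, False), self._fit(-10.0, True))


class TestHochberg:
    def test_single_p_unchanged(self):
        assert hochberg_adjust([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert hochberg_adjust([0.01, 0.04]) == [0.02, 0.04]

    def test_all_equal(self):
        assert hochberg_adjust([0.05, 0.05, 0.05]) == [0.05, 0.05, 0.05]

    def test_adjusted_at_least_raw_and_order_preserved(self):
        p = [0.2, 0.01, 0.8, 0.04, 0.03]
        adj = hochberg_adjust(p)
        assert all(a >= r for a, r in zip(adj, p))
        assert all(a <= 1 for a in adj)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(size=rng.integers(2, 12))
            assert np.allclose(hochberg_adjust(p),
                               multipletests(p, method="simes-hochberg")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hochberg_adjust([0.5, 1.2])
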