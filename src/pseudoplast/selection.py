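"""Branch-specific dN/dS estimation under a GY94-style codon model.

The model: 61 sense-codon states; instantaneous rates are zero for
multi-nucleotide changes and proportional to κ·π_j for synonymous
transitions, π_j for synonymous transversions, ω_b·κ·π_j and ω_b·π_j for the
nonsynonymous counterparts on branch b.  Rows are normalized so a branch
length is the expected number of substitutions per codon on that branch.
Codon frequencies π come from F3x4 (position-specific nucleotide
frequencies, stop frequency redistributed).  Likelihoods are computed by
Felsenstein pruning with per-pattern rescaling; internal stop codons and
ambiguous codons are missing data and are marginalized.

The test of interest compares a free-ratio ("full") model, one ω per branch,
against a constrained model in which the focal branch shares ω with the
branch immediately ancestral to it; 2Δℓ is referred to χ²₁.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
from scipy import optimize, stats

from .codons import (CODON_INDEX, N_STATES, SENSE_CODONS, SINGLE_DIFF,
                     IS_TRANSITION, IS_NONSYN, STOP_CODONS)

GAP_CHARS = set("-?")
EdgeKey = frozenset


# ---------------------------------------------------------------------------
# Codon alignments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CodonAlignment:
    """Taxa × codon-state matrix over the 61 sense codons (-1 = missing)."""

    taxa: list[str]
    states: np.ndarray  # (n_taxa, n_codons) int64
    pi: np.ndarray      # 61-vector (F3x4)
    n_recoded_stops: int = 0

    @property
    def length(self) -> int:
        return self.states.shape[1]


def f3x4_frequencies(rows: list[str]) -> np.ndarray:
    """F3x4 codon frequencies from position-specific nucleotide counts."""
    counts = np.zeros((3, 4))
    order = {n: i for i, n in enumerate("TCAG")}
    for row in rows:
        for i in range(0, len(row) - 2, 3):
            for p in range(3):
                j = order.get(row[i + p])
                if j is not None:
                    counts[p, j] += 1
    counts += 0.1  # guard against unobserved nucleotides in short alignments
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array([freqs[0, order[c[0]]] * freqs[1, order[c[1]]] * freqs[2, order[c[2]]]
                   for c in SENSE_CODONS])
    return pi / pi.sum()  # stop-codon mass redistributed proportionally


def build_codon_alignment(sequences: dict[str, str], min_remaining: int = 200,
                          ambiguous_mask=None) -> CodonAlignment:
    """Build a codon alignment from codon-aware aligned DNA.

    Columns flagged in ``ambiguous_mask`` (boolean per nucleotide column) are
    removed; sequences with fewer than ``min_remaining`` unmasked non-gap bp
    are dropped; internal stop codons are recoded as missing states.
    """
    taxa = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (aln_len,) = lengths
    keep = np.ones(aln_len, dtype=bool)
    if ambiguous_mask is not None:
        mask = np.asarray(ambiguous_mask, dtype=bool)
        if mask.size != aln_len:
            raise ValueError("mask length mismatch")
        keep = ~mask
    rows, kept_taxa = [], []
    for t in taxa:
        row = "".join(ch for ch, k in zip(sequences[t].upper(), keep) if k)
        unmasked = sum(1 for ch in row if ch not in GAP_CHARS)
        if unmasked >= min_remaining:
            rows.append(row)
            kept_taxa.append(t)
    if len(kept_taxa) < 3:
        raise ValueError(f"only {len(kept_taxa)} sequences survive filtering; need >= 3")
    if len(rows[0]) % 3 != 0:
        raise ValueError("alignment length after masking is not a multiple of 3")
    n_codons = len(rows[0]) // 3
    states = np.full((len(rows), n_codons), -1, dtype=np.int64)
    n_stops = 0
    for i, row in enumerate(rows):
        for k in range(n_codons):
            codon = row[3 * k:3 * k + 3]
            if codon in STOP_CODONS:
                n_stops += 1  # recoded as missing
            else:
                states[i, k] = CODON_INDEX.get(codon, -1)
    pi = f3x4_frequencies(rows)
    return CodonAlignment(taxa=kept_taxa, states=states, pi=pi,
                          n_recoded_stops=n_stops)


# ---------------------------------------------------------------------------
# GY94 rate matrix
# ---------------------------------------------------------------------------

class GY94:
    """Rate-matrix factory for fixed π; eigendecompositions cached per (κ, ω)."""

    def __init__(self, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        pi = np.maximum(pi, 1e-10)
        self.pi = pi / pi.sum()
        self._sqrt = np.sqrt(self.pi)
        self._cache: dict[tuple[float, float], tuple] = {}

    def rate_matrix(self, kappa: float, omega: float) -> np.ndarray:
        R = np.where(SINGLE_DIFF,
                     np.where(IS_TRANSITION, kappa, 1.0)
                     * np.where(IS_NONSYN, omega, 1.0), 0.0)
        Q = R * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(self.pi * np.diag(Q)).sum()
        if scale <= 0:
            raise ValueError("degenerate rate matrix")
        return Q / scale

    def _eig(self, kappa: float, omega: float):
        key = (kappa, omega)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Q = self.rate_matrix(kappa, omega)
        S = (self._sqrt[:, None] * Q) / self._sqrt[None, :]
        lam, W = np.linalg.eigh((S + S.T) / 2)
        U = W / self._sqrt[:, None]
        Vt = W.T * self._sqrt[None, :]
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = (lam, U, Vt)
        return lam, U, Vt

    def transition_matrix(self, kappa: float, omega: float, t: float) -> np.ndarray:
        lam, U, Vt = self._eig(kappa, omega)
        P = (U * np.exp(lam * t)[None, :]) @ Vt
        return np.clip(P, 0.0, None)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def tree_from_newick(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


@dataclasses.dataclass
class CompiledTree:
    """Array form of a tree for pruning; edges keyed by canonical bipartition.

    An edge's key is the frozenset of tip labels on the side of the edge not
    containing the lexicographically smallest taxon, which is stable under
    rerooting.  For a bifurcating root the two root edges share one key and
    act as a single merged branch (the model is reversible), carrying one
    branch length and one ω.
    """

    taxa: list[str]
    children: list[list[int]]
    parent: list[int]
    edge_key: list[EdgeKey | None]
    tip_label: list[str | None]
    postorder: list[int]
    root: int
    init_length: dict[EdgeKey, float]
    merged_root_child: int | None  # child edge evaluated with t = 0

    @property
    def edge_keys(self) -> list[EdgeKey]:
        seen = []
        for i in self.postorder:
            k = self.edge_key[i]
            if k is not None and k not in seen and i != self.merged_root_child:
                seen.append(k)
        return sorted(seen, key=lambda k: sorted(k))


def compile_tree(tree: dendropy.Tree) -> CompiledTree:
    nodes = list(tree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    children = [[] for _ in range(n)]
    parent = [-1] * n
    tip_label = [None] * n
    for nd in nodes:
        i = idx[id(nd)]
        if nd.taxon is not None:
            tip_label[i] = nd.taxon.label
        for ch in nd.child_nodes():
            j = idx[id(ch)]
            children[i].append(j)
            parent[j] = i
    taxa = sorted(lb for lb in tip_label if lb is not None)
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon labels")
    ref = taxa[0]
    below = [set() for _ in range(n)]
    postorder = []

    def _post(i):
        for j in children[i]:
            _post(j)
            below[i] |= below[j]
        if tip_label[i] is not None:
            below[i].add(tip_label[i])
        postorder.append(i)

    root = idx[id(tree.seed_node)]
    _post(root)
    all_taxa = frozenset(taxa)
    edge_key: list[EdgeKey | None] = [None] * n
    for i in range(n):
        if i == root:
            continue
        fs = frozenset(below[i])
        edge_key[i] = fs if ref not in fs else all_taxa - fs
    merged_root_child = None
    root_children = children[root]
    if len(root_children) == 2:
        merged_root_child = root_children[1]  # its length folds into the sibling edge
    init_length: dict[EdgeKey, float] = {}
    for nd in nodes:
        i = idx[id(nd)]
        if i == root or edge_key[i] is None:
            continue
        el = nd.edge.length if nd.edge.length is not None else 0.05
        init_length[edge_key[i]] = init_length.get(edge_key[i], 0.0) + float(el)
    return CompiledTree(taxa=taxa, children=children, parent=parent,
                        edge_key=edge_key, tip_label=tip_label,
                        postorder=postorder, root=root,
                        init_length=init_length,
                        merged_root_child=merged_root_child)


def tip_edge_key(ct: CompiledTree, label: str) -> EdgeKey:
    for i, lb in enumerate(ct.tip_label):
        if lb == label and ct.edge_key[i] is not None:
            return ct.edge_key[i]
    raise KeyError(f"no tip branch for {label!r}")


def ancestral_edge_key(ct: CompiledTree, label: str) -> EdgeKey:
    """Key of the branch immediately ancestral to a tip's terminal branch."""
    for i, lb in enumerate(ct.tip_label):
        if lb == label:
            p = ct.parent[i]
            if p == -1 or ct.edge_key[p] is None or p == ct.root:
                raise ValueError(f"tip {label!r} has no ancestral branch")
            if ct.merged_root_child is not None and p == ct.merged_root_child:
                # merged with its sibling root edge; same key either way
                pass
            return ct.edge_key[p]
    raise KeyError(f"tip {label!r} not found")


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CodonModelParams:
    kappa: float
    pi: np.ndarray
    branch_lengths: dict[EdgeKey, float]
    omegas: dict[EdgeKey, float]


@dataclasses.dataclass
class ModelFit:
    params: CodonModelParams
    logL: float
    converged: bool
    constrained: bool
    n_evals: int = 0


def _pattern_compress(states: np.ndarray):
    patterns, counts = np.unique(states, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def _tip_partials(patterns: np.ndarray):
    """Per-taxon (61, n_patterns) tip likelihood matrices; missing = ones."""
    out = []
    for row in patterns:
        M = np.zeros((N_STATES, row.size))
        miss = row < 0
        M[:, miss] = 1.0
        obs = ~miss
        M[row[obs], np.nonzero(obs)[0]] = 1.0
        out.append(M)
    return out


class _Pruner:
    def __init__(self, alignment: CodonAlignment, ct: CompiledTree):
        missing = set(ct.taxa) ^ set(alignment.taxa)
        if missing:
            raise ValueError(f"tree/alignment taxa mismatch: {sorted(missing)}")
        order = [alignment.taxa.index(ct.tip_label[i]) if ct.tip_label[i] else -1
                 for i in range(len(ct.tip_label))]
        patterns, weights = _pattern_compress(alignment.states)
        tipmats = _tip_partials(patterns)
        self.ct = ct
        self.weights = weights
        self.n_pat = patterns.shape[1]
        self.tipmat = {i: tipmats[order[i]] for i in range(len(order))
                       if ct.tip_label[i] is not None}
        self.model = GY94(alignment.pi)
        self.pi = self.model.pi

    def loglik(self, kappa: float, t_by_key: dict, omega_by_key: dict) -> float:
        ct = self.ct
        partial = {}
        logscale = {}
        for i in ct.postorder:
            if ct.tip_label[i] is not None:
                partial[i] = self.tipmat[i]
                logscale[i] = np.zeros(self.n_pat)
            else:
                acc = np.ones((N_STATES, self.n_pat))
                ls = np.zeros(self.n_pat)
                for j in ct.children[i]:
                    key = ct.edge_key[j]
                    t = 0.0 if j == ct.merged_root_child else t_by_key[key]
                    P = self.model.transition_matrix(kappa, omega_by_key[key], t)
                    acc = acc * (P @ partial[j])
                    ls += logscale[j]
                m = acc.max(axis=0)
                m = np.where(m > 0, m, 1.0)
                partial[i] = acc / m
                logscale[i] = ls + np.log(m)
        root = ct.root
        site_l = self.pi @ partial[root]
        site_l = np.maximum(site_l, 1e-300)
        return float((self.weights * (np.log(site_l) + logscale[root])).sum())


def gy94_loglik(alignment: CodonAlignment, tree: dendropy.Tree | CompiledTree,
                params: CodonModelParams) -> float:
    """Log-likelihood of a codon alignment on a tree under GY94 parameters.

    ``params.branch_lengths`` / ``params.omegas`` may be keyed by canonical
    bipartition; a scalar ω (float) is broadcast to all branches, and missing
    branch lengths fall back to the tree's own edge lengths.
    """
    ct = tree if isinstance(tree, CompiledTree) else compile_tree(tree)
    pruner = _Pruner(alignment, ct)
    keys = ct.edge_keys
    omegas = params.omegas
    if np.isscalar(omegas):
        omegas = {k: float(omegas) for k in keys}
    t_by_key = dict(ct.init_length)
    if params.branch_lengths:
        t_by_key.update(params.branch_lengths)
    return pruner.loglik(params.kappa, t_by_key, omegas)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_BOUNDS = {"kappa": (1e-3, 100.0), "omega": (1e-6, 999.0), "t": (1e-8, 50.0)}


def fit_branch_model(alignment: CodonAlignment, tree: dendropy.Tree | CompiledTree,
                     focal_branch: str, constrained: bool,
                     n_starts: int = 3, seed: int = 0,
                     warm_start: ModelFit | None = None,
                     maxiter: int = 500) -> ModelFit:
    """Maximum-likelihood fit of the free-ratio (or focal-constrained) model.

    ``focal_branch`` is a tip label naming the focal terminal branch.  The
    full model gives every branch its own ω; the constrained model forces the
    focal branch to share ω with its immediately ancestral branch (df = 1).
    κ and all branch lengths are estimated; π is fixed at the alignment's
    F3x4 frequencies.  Optimization is quasi-Newton (L-BFGS-B) on
    log-transformed parameters with ``n_starts`` seeded starts; pass
    ``warm_start`` (e.g. the constrained fit when fitting the full model) to
    add its optimum as an extra start.
    """
    ct = tree if isinstance(tree, CompiledTree) else compile_tree(tree)
    pruner = _Pruner(alignment, ct)
    keys = ct.edge_keys
    focal = tip_edge_key(ct, focal_branch)
    ancestral = ancestral_edge_key(ct, focal_branch)
    omega_class = {k: (ancestral if (constrained and k == focal) else k) for k in keys}
    classes = sorted({omega_class[k] for k in keys}, key=lambda k: sorted(k))
    n_t, n_w = len(keys), len(classes)

    def unpack(x):
        kappa = np.exp(x[0])
        t_by_key = {k: np.exp(x[1 + i]) for i, k in enumerate(keys)}
        w_by_class = {c: np.exp(x[1 + n_t + i]) for i, c in enumerate(classes)}
        omega_by_key = {k: w_by_class[omega_class[k]] for k in keys}
        return kappa, t_by_key, omega_by_key

    evals = [0]

    def nll(x):
        evals[0] += 1
        kappa, t_by_key, omega_by_key = unpack(x)
        return -pruner.loglik(kappa, t_by_key, omega_by_key)

    bounds = ([tuple(np.log(_BOUNDS["kappa"]))]
              + [tuple(np.log(_BOUNDS["t"]))] * n_t
              + [tuple(np.log(_BOUNDS["omega"]))] * n_w)

    def base_start():
        t0 = [max(ct.init_length.get(k, 0.05), 1e-4) for k in keys]
        return np.log(np.array([2.0] + t0 + [0.2] * n_w))

    starts = []
    if warm_start is not None:
        p = warm_start.params
        x = [np.log(p.kappa)]
        x += [np.log(max(p.branch_lengths[k], 1e-8)) for k in keys]
        x += [np.log(max(p.omegas[c], 1e-6)) for c in classes]
        starts.append(np.array(x))
    if n_starts >= 1 or warm_start is None:
        starts.append(base_start())
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts + (warm_start is not None):
        starts.append(base_start() + rng.normal(0, 0.5, size=1 + n_t + n_w))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "maxfun": 20000})
        if best is None or res.fun < best.fun:
            best = res
    kappa, t_by_key, omega_by_key = unpack(best.x)
    params = CodonModelParams(kappa=kappa, pi=pruner.pi.copy(),
                              branch_lengths=t_by_key, omegas=omega_by_key)
    return ModelFit(params=params, logL=-float(best.fun),
                    converged=bool(best.success), constrained=constrained,
                    n_evals=evals[0])


# ---------------------------------------------------------------------------
# Likelihood-ratio test & multiple-testing correction
# ---------------------------------------------------------------------------

def fit_lrt_pair(alignment: CodonAlignment, tree, focal_branch: str,
                 n_starts: int = 1, seed: int = 0
                 ) -> tuple[ModelFit, ModelFit]:
    """Fit the constrained and full models with mutual warm starts.

    The full model is warm-started from the constrained optimum (it contains
    it, so Λ ≥ 0 structurally); the constrained model is then refit from the
    full optimum's projection and the better of the two constrained fits is
    kept — standard optimizer hygiene that keeps the LRT statistic from being
    inflated by an under-converged null fit.  Returns (full, constrained).
    """
    fit_c = fit_branch_model(alignment, tree, focal_branch, constrained=True,
                             n_starts=n_starts, seed=seed)
    fit_f = fit_branch_model(alignment, tree, focal_branch, constrained=False,
                             n_starts=n_starts, seed=seed, warm_start=fit_c)
    fit_c2 = fit_branch_model(alignment, tree, focal_branch, constrained=True,
                              n_starts=0, seed=seed, warm_start=fit_f)
    if fit_c2.logL > fit_c.logL:
        fit_c = fit_c2
    return fit_f, fit_c


@dataclasses.dataclass
class LRTResult:
    statistic: float      # 2(ℓ_full − ℓ_constrained), clamped at 0
    df: int
    p: float
    p_adjusted: float | None = None


def lrt(full: ModelFit, constrained: ModelFit, tol: float = 1e-3) -> LRTResult:
    """Likelihood-ratio test of the constrained (shared-ω) model, df = 1."""
    delta = 2.0 * (full.logL - constrained.logL)
    if delta < -tol:
        raise ValueError(
            f"constrained logL exceeds full logL by {-delta / 2:.6g}; optimizer fault")
    stat = max(0.0, delta)
    return LRTResult(statistic=stat, df=1, p=float(stats.chi2.sf(stat, df=1)))


def hochberg_adjust(pvals) -> list[float]:
    """Hochberg step-up adjusted p-values (original order preserved)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    factors = (m - np.arange(m)) * sorted_p  # (m - j + 1) * p_(j), 1-based j
    adj_sorted = np.minimum.accumulate(factors[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()
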