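"""Synthetic plastome panels with known evolutionary history and injected lesions.

The generator emulates the inputs of a comparative plastome-degradation
study: a panel of related circular genomes with canonical quadripartite
structure (LSC + IRb + SSC + IRa = revcomp(IRb)), protein-coding genes
evolved along a phylogeny under the same GY94 generator the likelihood code
uses, conserved tRNA/rRNA models, random intergenic spacers, and a focal
genome carrying injected degradation events recorded in a truth ledger.

All randomness flows from one seed through labelled child streams, so adding
a gene or taxon does not perturb other draws.
"""

from __future__ import annotations

import dataclasses
import zlib

import numpy as np

from .codons import (CODON_INDEX, SENSE_CODONS, STOP_CODONS, IS_NONSYN,
                     revcomp)
from .io import GeneModel, PlastomeRecord
from .selection import (CodonModelParams, CompiledTree, GY94, compile_tree,
                        tree_from_newick, tip_edge_key, ancestral_edge_key)

DEFAULT_GENES = [
    # (name, codons) — a scaled-down but structurally faithful plastid gene set
    ("psbA", 160), ("matK", 250), ("rpoB", 320), ("petA", 140), ("rbcL", 220),
    ("atpB", 230), ("rpl20", 120), ("clpP", 110), ("rps4", 100), ("ycf4", 90),
    ("cemA", 210), ("ccsA", 150), ("ndhB", 240), ("ndhK", 130), ("psaA", 300),
]
DEFAULT_SSC_GENES = [("ndhF", 260), ("ndhA", 180), ("ndhD", 170), ("rps15", 90)]
DEFAULT_TRNA = [("trnH-GUG", 75), ("trnK-UUU", 72), ("trnL-UAA", 80)]
DEFAULT_RRNA = [("rrn16", 800), ("rrn23", 1500)]
MINUS_STRAND_GENES = {"psbA", "clpP"}  # exercised strand handling

NUC = np.array(list("ACGT"))


def stream(seed: int, *labels) -> np.random.Generator:
    """Deterministic child RNG for a labelled purpose."""
    key = tuple(zlib.crc32(str(l).encode()) for l in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclasses.dataclass
class SyntheticConfig:
    seed: int
    n_taxa: int = 8
    tree: str | None = None                 # newick; generated if None
    genes: list = dataclasses.field(default_factory=lambda: list(DEFAULT_GENES))
    ssc_genes: list = dataclasses.field(default_factory=lambda: list(DEFAULT_SSC_GENES))
    trna_genes: list = dataclasses.field(default_factory=lambda: list(DEFAULT_TRNA))
    rrna_genes: list = dataclasses.field(default_factory=lambda: list(DEFAULT_RRNA))
    spacer_length_range: tuple = (100, 400)
    ir_length: int = 4000
    divergence: float = 0.03                # branch length, subs/codon
    kappa: float = 2.0
    omega_background: float = 0.2
    omega_focal: float = 0.03               # focal + ancestral branch
    gc_spacer: float = 0.37
    focal_taxon: str = "focal"
    focal_spacer_scale: float = 0.8         # focal intergenic erosion -> shorter genome
    flip_ssc: bool = False                  # emit the reversed SSC orientation


@dataclasses.dataclass
class SyntheticTruth:
    """Ledger of injected degradation events."""

    events: list = dataclasses.field(default_factory=list)

    def add(self, genome: str, gene: str, kind: str, position: int, **payload):
        self.events.append({"genome": genome, "gene": gene, "kind": kind,
                            "position": position, **payload})

    def genes_with(self, kind: str) -> set[str]:
        return {e["gene"] for e in self.events if e["kind"] == kind}


@dataclasses.dataclass
class SyntheticPanel:
    config: SyntheticConfig
    newick: str
    records: dict[str, PlastomeRecord]          # taxon -> annotated genome
    gene_alignments: dict[str, dict[str, str]]  # gene -> taxon -> CDS (gap-free)
    substitution_counts: dict                   # gene -> edge key -> (syn, nonsyn)

    @property
    def focal(self) -> PlastomeRecord:
        return self.records[self.config.focal_taxon]

    def panel_records(self) -> list[PlastomeRecord]:
        return [r for t, r in self.records.items() if t != self.config.focal_taxon]


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

def _sample_codons(pi: np.ndarray, n: int, rng) -> np.ndarray:
    return rng.choice(len(SENSE_CODONS), size=n, p=pi / pi.sum())


def _evolve_branch(states: np.ndarray, t: float, Q: np.ndarray, rng):
    """Exact stochastic simulation (jump chain) of one branch; returns
    (new_states, n_synonymous, n_nonsynonymous)."""
    cur = states.copy()
    n_syn = n_nonsyn = 0
    if t <= 0:
        return cur, 0, 0
    rates = -np.diag(Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(rates[:, None] > 0, Q / rates[:, None], 0.0)
    np.fill_diagonal(jump, 0.0)
    cum = np.cumsum(jump, axis=1)
    remaining = np.full(cur.size, t)
    active = np.nonzero(rates[cur] > 0)[0]
    while active.size:
        waits = rng.exponential(1.0, size=active.size) / rates[cur[active]]
        jumping = waits < remaining[active]
        remaining[active] -= waits
        movers = active[jumping]
        for site in movers:
            u = rng.random()
            new = int(np.searchsorted(cum[cur[site]], u, side="right"))
            new = min(new, len(SENSE_CODONS) - 1)
            if IS_NONSYN[cur[site], new]:
                n_nonsyn += 1
            else:
                n_syn += 1
            cur[site] = new
        active = movers[rates[cur[movers]] > 0]
    return cur, n_syn, n_nonsyn


def simulate_codon_evolution(tree, params: CodonModelParams, n_codons: int,
                             seed: int):
    """Simulate gap-free codon sequences down a tree under the GY94 generator.

    Root codons are drawn from π; per-branch substitution events are simulated
    with the branch's own ω (rate matrix identical to the likelihood code).
    Returns (sequences: taxon -> DNA, counts: edge key -> (n_syn, n_nonsyn)).
    """
    ct = tree if isinstance(tree, CompiledTree) else compile_tree(tree)
    model = GY94(params.pi)
    pi = model.pi
    rng = stream(seed, "root")
    root_states = _sample_codons(pi, n_codons, rng)
    omegas = params.omegas
    if np.isscalar(omegas):
        omegas = {k: float(omegas) for k in ct.edge_keys}
    t_by_key = dict(ct.init_length)
    if params.branch_lengths:
        t_by_key.update(params.branch_lengths)

    states = {ct.root: root_states}
    counts = {}
    order = [i for i in reversed(ct.postorder)]  # preorder
    for i in order:
        if i == ct.root:
            continue
        key = ct.edge_key[i]
        t = 0.0 if i == ct.merged_root_child else t_by_key[key]
        Q = model.rate_matrix(params.kappa, omegas[key])
        label = "|".join(sorted(key))
        branch_rng = stream(seed, "branch", label, int(i == ct.merged_root_child))
        new, ns, nn = _evolve_branch(states[ct.parent[i]], t, Q, branch_rng)
        states[i] = new
        if i != ct.merged_root_child:
            counts[key] = (ns, nn)
    seqs = {}
    for i, lb in enumerate(ct.tip_label):
        if lb is not None:
            seqs[lb] = "".join(SENSE_CODONS[s] for s in states[i])
    return seqs, counts


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_spacer(rng, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(NUC[rng.choice(4, size=length, p=p)])


def _random_gene_dna(rng, length_bp: int) -> str:
    return "".join(NUC[rng.integers(0, 4, size=length_bp)])


def default_tree(n_taxa: int, divergence: float, focal: str = "focal") -> str:
    """Pectinate tree with the focal tip nested one node deep (so an
    ancestral branch exists), unit branch lengths = divergence."""
    d = divergence
    labels = [f"panel_{i}" for i in range(1, n_taxa)]
    sub = f"({focal}:{d},{labels[0]}:{d}):{d}"
    for lb in labels[1:-1]:
        sub = f"({sub},{lb}:{d}):{d}"
    return f"({sub},{labels[-1]}:{d});"


def _stationary_pi(gc: float = 0.38) -> np.ndarray:
    """Codon frequencies from genome-wide nucleotide composition (F1x4-like)."""
    base = {"T": (1 - gc) / 2, "C": gc / 2, "A": (1 - gc) / 2, "G": gc / 2}
    pi = np.array([base[c[0]] * base[c[1]] * base[c[2]] for c in SENSE_CODONS])
    return pi / pi.sum()


def build_synthetic_plastome(config: SyntheticConfig) -> SyntheticPanel:
    """Generate an annotated panel of related plastomes plus gene alignments.

    Coding genes are ATG + evolved sense codons + TAA, evolved along the tree
    with background ω on all branches except the focal tip and its ancestral
    branch (ω_focal); tRNA/rRNA models are held identical across the panel;
    spacers are regenerated per genome with plastome-like GC.
    """
    cfg = config
    if not (cfg.genes or cfg.ssc_genes):
        raise ValueError("gene set must be non-empty")
    newick = cfg.tree or default_tree(cfg.n_taxa, cfg.divergence, cfg.focal_taxon)
    tree = tree_from_newick(newick)
    ct = compile_tree(tree)
    taxa = ct.taxa
    if cfg.focal_taxon not in taxa:
        raise ValueError(f"focal taxon {cfg.focal_taxon!r} not in tree")

    pi = _stationary_pi()
    focal_key = tip_edge_key(ct, cfg.focal_taxon)
    anc_key = ancestral_edge_key(ct, cfg.focal_taxon)
    omegas = {k: cfg.omega_background for k in ct.edge_keys}
    omegas[focal_key] = cfg.omega_focal
    omegas[anc_key] = cfg.omega_focal
    params = CodonModelParams(kappa=cfg.kappa, pi=pi, branch_lengths={},
                              omegas=omegas)

    gene_alignments: dict[str, dict[str, str]] = {}
    sub_counts = {}
    all_pcg = list(cfg.genes) + list(cfg.ssc_genes)
    for name, n_codons in all_pcg:
        seqs, counts = simulate_codon_evolution(
            ct, params, n_codons, seed=int(stream(cfg.seed, "gene", name).integers(2 ** 31)))
        gene_alignments[name] = {t: "ATG" + s + "TAA" for t, s in seqs.items()}
        sub_counts[name] = counts

    # conserved structural RNAs: identical across the panel
    rna_seqs = {}
    for name, length in list(cfg.trna_genes) + list(cfg.rrna_genes):
        rna_seqs[name] = _random_gene_dna(stream(cfg.seed, "rna", name), length)

    rrna_total = sum(l for _, l in cfg.rrna_genes)
    min_sp = 50
    if cfg.rrna_genes and rrna_total + (len(cfg.rrna_genes) + 1) * min_sp > cfg.ir_length:
        raise ValueError(
            f"rRNA genes ({rrna_total} bp) exceed IR capacity ({cfg.ir_length} bp)")

    records = {}
    for taxon in taxa:
        rng = stream(cfg.seed, "genome", taxon)

        def spacer(length=None):
            if length is None:
                length = int(rng.integers(*cfg.spacer_length_range))
                if taxon == cfg.focal_taxon:
                    # degraded plastomes erode intergenic DNA as well
                    length = int(length * cfg.focal_spacer_scale)
            return _random_spacer(rng, length, cfg.gc_spacer)

        seq_parts: list[str] = []
        features: list[GeneModel] = []
        pos = 0

        def emit(text: str):
            nonlocal pos
            seq_parts.append(text)
            pos += len(text)

        def emit_gene(name, dna, kind, strand):
            nonlocal pos
            genomic = dna if strand == "+" else revcomp(dna)
            features.append(GeneModel(name, kind, [(pos, pos + len(genomic))], strand))
            emit(genomic)

        # ---- LSC
        for name, _ in cfg.genes:
            emit(spacer())
            strand = "-" if name in MINUS_STRAND_GENES else "+"
            emit_gene(name, gene_alignments[name][taxon], "protein_coding", strand)
        for name, _ in cfg.trna_genes:
            emit(spacer())
            emit_gene(name, rna_seqs[name], "tRNA", "+")
        emit(spacer())

        # ---- IRb (content built once, then mirrored)
        irb_start = pos
        ir_features_rel = []
        ir_parts = []
        ir_pos = 0
        n_r = len(cfg.rrna_genes)
        slack = cfg.ir_length - rrna_total - (n_r + 1) * min_sp if n_r else cfg.ir_length
        gaps = [min_sp] * (n_r + 1) if n_r else []
        if n_r:
            extra = stream(cfg.seed, "irpad", taxon).multinomial(slack, [1 / (n_r + 1)] * (n_r + 1))
            gaps = [g + int(e) for g, e in zip(gaps, extra)]
            for (name, _), g in zip(cfg.rrna_genes, gaps[:-1]):
                ir_parts.append(_random_spacer(rng, g, cfg.gc_spacer))
                ir_pos += g
                ir_features_rel.append((name, ir_pos, ir_pos + len(rna_seqs[name])))
                ir_parts.append(rna_seqs[name])
                ir_pos += len(rna_seqs[name])
            ir_parts.append(_random_spacer(rng, gaps[-1], cfg.gc_spacer))
            ir_pos += gaps[-1]
        else:
            ir_parts.append(_random_spacer(rng, cfg.ir_length, cfg.gc_spacer))
            ir_pos = cfg.ir_length
        irb_seq = "".join(ir_parts)
        assert len(irb_seq) == cfg.ir_length
        for name, a, b in ir_features_rel:
            features.append(GeneModel(name, "rRNA", [(irb_start + a, irb_start + b)], "+"))
        emit(irb_seq)

        # ---- SSC
        ssc_start = pos
        for name, _ in cfg.ssc_genes:
            emit(spacer())
            emit_gene(name, gene_alignments[name][taxon], "protein_coding", "+")
        emit(spacer())
        ssc_end = pos

        # ---- IRa = revcomp(IRb); rRNA copies annotated on '-' strand
        ira_start = pos
        emit(revcomp(irb_seq))
        for name, a, b in ir_features_rel:
            g0 = ira_start + (cfg.ir_length - b)
            g1 = ira_start + (cfg.ir_length - a)
            features.append(GeneModel(name, "rRNA", [(g0, g1)], "-"))

        sequence = "".join(seq_parts)
        # guard the planted IR boundary: if the SSC's first and last bases are
        # complementary the maximal repeat would extend past the construction
        # by chance; both positions are spacer, so break the pairing
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if sequence[ssc_end - 1] == comp[sequence[ssc_start]]:
            sequence = (sequence[:ssc_end - 1]
                        + ("A" if sequence[ssc_start] != "T" else "C")
                        + sequence[ssc_end:])
        record = PlastomeRecord(id=taxon, sequence=sequence, features=features,
                                is_circular=True)
        record.meta["regions"] = {"lsc": (0, irb_start), "irb": (irb_start, ssc_start),
                                  "ssc": (ssc_start, ssc_end), "ira": (ira_start, pos)}
        if cfg.flip_ssc:
            flipped = (sequence[:ssc_start]
                       + revcomp(sequence[ssc_start:ssc_end]) + sequence[ssc_end:])
            new_feats = []
            for f in record.features:
                s, e = f.segments[0]
                if ssc_start <= s and e <= ssc_end:
                    new_feats.append(GeneModel(
                        f.gene_name, f.kind,
                        [(ssc_start + (ssc_end - e), ssc_start + (ssc_end - s))],
                        "+" if f.strand == "-" else "-", f.codon_start_offset))
                else:
                    new_feats.append(f)
            record = PlastomeRecord(id=taxon, sequence=flipped, features=new_feats,
                                    is_circular=True, meta=dict(record.meta))
        records[taxon] = record

    return SyntheticPanel(config=cfg, newick=newick, records=records,
                          gene_alignments=gene_alignments,
                          substitution_counts=sub_counts)


# ---------------------------------------------------------------------------
# Degradation injection
# ---------------------------------------------------------------------------

_STOP_MUTATIONS = None


def _one_sub_to_stop(codon: str):
    """(pos, base) turning `codon` into a stop by one substitution, or None."""
    for p in range(3):
        for b in "ACGT":
            if b != codon[p]:
                mutant = codon[:p] + b + codon[p + 1:]
                if mutant in STOP_CODONS:
                    return p, b
    return None


def _replace_gene(record: PlastomeRecord, gene: str, new_cds: str) -> PlastomeRecord:
    """Replace a gene's genomic segment with a new CDS, shifting downstream
    feature coordinates by the length difference (single-segment genes)."""
    model = record.gene(gene)
    (s, e), = model.segments
    genomic = new_cds if model.strand == "+" else revcomp(new_cds)
    delta = len(genomic) - (e - s)
    seq = record.sequence[:s] + genomic + record.sequence[e:]
    feats = []
    for f in record.features:
        (fs, fe), = f.segments
        if f.gene_name == gene and (fs, fe) == (s, e):
            feats.append(GeneModel(gene, f.kind, [(s, s + len(genomic))], f.strand,
                                   f.codon_start_offset))
        elif fs >= e:
            feats.append(GeneModel(f.gene_name, f.kind, [(fs + delta, fe + delta)],
                                   f.strand, f.codon_start_offset))
        else:
            feats.append(f)
    return PlastomeRecord(id=record.id, sequence=seq, features=feats,
                          is_circular=record.is_circular, meta=dict(record.meta))


def _downstream_window(record: PlastomeRecord, gene: str, length: int) -> str:
    """Strand-corrected sequence immediately downstream of a gene's stop."""
    model = record.gene(gene)
    (s, e), = model.segments
    L = record.length
    if model.strand == "+":
        return record.slice(e, (e + length) % L)
    return revcomp(record.slice((s - length) % L, s))


def _edit_downstream(record: PlastomeRecord, gene: str, new_window: str,
                     length: int) -> PlastomeRecord:
    model = record.gene(gene)
    (s, e), = model.segments
    if model.strand == "+":
        seq = record.sequence[:e] + new_window + record.sequence[e + length:]
    else:
        seq = record.sequence[:s - length] + revcomp(new_window) + record.sequence[s:]
    return PlastomeRecord(id=record.id, sequence=seq, features=record.features,
                          is_circular=record.is_circular, meta=dict(record.meta))


def inject_degradation(record: PlastomeRecord, truth_spec: list, seed: int
                       ) -> tuple[PlastomeRecord, SyntheticTruth]:
    """Apply degradation events to intact genes; returns mutated record + ledger.

    ``truth_spec`` is a list of ``(gene, kind, params)`` with kinds:

    - ``premature_stop``: one substitution creating an in-frame stop
      (``codon``: codon index, default mid-gene)
    - ``frameshift``: 1–2 bp indel (``indel_len`` ±1/±2: negative = deletion)
    - ``large_deletion``: in-frame-offset deletion of ``length`` bp
    - ``short_inversion``: in-place reverse complement of ``length`` bp
      (default 60)
    - ``lost_stop``: canonical stop mutated to a sense codon and the 30 bp
      downstream cleared of in-frame stops
    - ``termination_shift``: as ``lost_stop`` but a novel stop planted
      ``extension`` bp (default 90) downstream
    """
    from .io import extract_cds  # local import to avoid cycle at module load

    rng = stream(seed, "inject", record.id)
    truth = SyntheticTruth()
    rec = record
    for gene, kind, params in truth_spec:
        params = dict(params or {})
        cds = extract_cds(rec, gene)
        n_codons = len(cds) // 3
        if kind == "premature_stop":
            codon_i = params.get("codon")
            order = list(range(n_codons // 4, 3 * n_codons // 4))
            rng.shuffle(order)
            candidates = [codon_i] if codon_i is not None else order
            hit = None
            for ci in candidates:
                res = _one_sub_to_stop(cds[3 * ci:3 * ci + 3])
                if res:
                    hit = (ci, *res)
                    break
            if hit is None:
                raise ValueError(f"{gene}: no codon mutable to a stop by one substitution")
            ci, p, b = hit
            new = cds[:3 * ci + p] + b + cds[3 * ci + p + 1:]
            rec = _replace_gene(rec, gene, new)
            truth.add(rec.id, gene, "premature_stop", 3 * ci + p, codon=ci)
        elif kind == "frameshift":
            indel = int(params.get("indel_len", rng.choice([-2, -1, 1, 2])))
            pos = int(params.get("position", rng.integers(n_codons // 4, 3 * n_codons // 4)) * 3)
            if indel > 0:
                ins = "".join(NUC[rng.integers(0, 4, size=indel)])
                new = cds[:pos] + ins + cds[pos:]
            else:
                new = cds[:pos] + cds[pos - indel:]
            rec = _replace_gene(rec, gene, new)
            truth.add(rec.id, gene, "frameshift", pos, indel_len=indel)
        elif kind == "large_deletion":
            length = int(params.get("length", 150))
            if length >= len(cds) - 60:
                raise ValueError(f"{gene}: deletion {length} exceeds gene capacity")
            start = int(params.get("position",
                                   rng.integers(30, len(cds) - length - 30)))
            start -= start % 3  # in-frame so the deletion is the sole lesion
            new = cds[:start] + cds[start + length:]
            rec = _replace_gene(rec, gene, new)
            truth.add(rec.id, gene, "large_deletion", start, length=length)
        elif kind == "short_inversion":
            length = int(params.get("length", 60))
            start = int(params.get("position",
                                   rng.integers(30, len(cds) - length - 30)))
            seg = cds[start:start + length]
            new = cds[:start] + revcomp(seg) + cds[start + length:]
            rec = _replace_gene(rec, gene, new)
            truth.add(rec.id, gene, "short_inversion", start, length=length)
        elif kind in ("lost_stop", "termination_shift"):
            stop = cds[-3:]
            if stop not in STOP_CODONS:
                raise ValueError(f"{gene}: no canonical stop to destroy")
            new = cds[:-3] + "TGG"  # sense codon
            rec = _replace_gene(rec, gene, new)
            ext = int(params.get("extension", 90)) if kind == "termination_shift" else 0
            ext -= ext % 3  # the novel stop must sit on the focal codon grid
            horizon = max(ext + 3, 36)
            window = _downstream_window(rec, gene, horizon)
            w = list(window)
            for q in range(0, horizon - 2, 3):
                codon = "".join(w[q:q + 3])
                if kind == "termination_shift" and q == ext - 3:
                    w[q:q + 3] = list("TAA")
                elif codon in STOP_CODONS:
                    w[q] = "C"  # recode to a sense codon
            rec = _edit_downstream(rec, gene, "".join(w), horizon)
            truth.add(rec.id, gene, kind, len(cds) - 3,
                      extension=ext if kind == "termination_shift" else None)
        else:
            raise ValueError(f"unknown degradation kind {kind!r}")
    return rec, truth
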