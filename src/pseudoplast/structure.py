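"""Quadripartite plastome structure: IR detection, SSC orientation, summaries.

Land-plant plastomes are circular with two reverse-complementary inverted
repeat copies (IRa/IRb) separating a large and a small single-copy region
(LSC/SSC).  The IR is found by seeding on maximal exact matches between the
genome and its reverse complement and extending symmetrically under a
mismatch tolerance; ties are broken by the leftmost IRb start.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

from .codons import revcomp
from .io import GeneModel, PlastomeRecord

Interval = tuple[int, int]  # 0-based half-open; end <= start wraps the origin


def interval_length(iv: Interval, genome_length: int) -> int:
    start, end = iv
    return end - start if end > start else genome_length - start + end


def in_interval(pos: int, iv: Interval, genome_length: int) -> bool:
    start, end = iv
    if end > start:
        return start <= pos < end
    return pos >= start or pos < end


@dataclasses.dataclass
class QuadripartiteStructure:
    """Detected LSC / IRb / SSC / IRa partition of a circular plastome."""

    found: bool
    lsc: Interval | None = None
    ssc: Interval | None = None
    ira: Interval | None = None
    irb: Interval | None = None
    ir_length: int = 0
    lsc_length: int = 0
    ssc_length: int = 0
    mismatches: int = 0

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


class AmbiguousStructureError(ValueError):
    """Raised when multiple repeat pairs tie for the maximum length."""


def _seed_pairs(seq: str, k: int):
    """Maximal exact reverse-complement repeat pairs via k-mer anchoring.

    Yields (a_start, b_start, length) with seq[a:a+len] == revcomp(seq[b:b+len]).
    """
    L = len(seq)
    rc = revcomp(seq)
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(L - k + 1):
        index[rc[i:i + k]].append(i)
    covered: dict[int, int] = {}  # diagonal (a - b) -> furthest a reached
    out = []
    for a in range(L - k + 1):
        kmer = seq[a:a + k]
        hits = index.get(kmer)
        if not hits:
            continue
        for b in hits:
            diag = a - b
            if covered.get(diag, -1) >= a:
                continue
            # extend exact match both directions
            a1, b1 = a, b
            while a1 > 0 and b1 > 0 and seq[a1 - 1] == rc[b1 - 1]:
                a1 -= 1
                b1 -= 1
            a2, b2 = a + k, b + k
            while a2 < L and b2 < L and seq[a2] == rc[b2]:
                a2 += 1
                b2 += 1
            covered[diag] = a2
            # rc coords -> genome coords: rc[b1:b2] is revcomp of seq[L-b2:L-b1]
            g1, g2 = L - b2, L - b1
            out.append(((a1, a2), (g1, g2)))
    return out


def _disjoint(x: Interval, y: Interval) -> bool:
    return x[1] <= y[0] or y[1] <= x[0]


def _extend_mismatch(seq: str, A: Interval, B: Interval, max_mismatch_frac: float):
    """Symmetric outward extension allowing mismatches up to the tolerated fraction.

    A grows rightward while B grows leftward (and vice versa), keeping
    seq[A] == revcomp(seq[B]) up to mismatches; extensions never end on a
    mismatch and never make the copies overlap.
    """
    if max_mismatch_frac <= 0:
        return A, B, 0
    L = len(seq)
    a1, a2 = A
    b1, b2 = B
    mism = 0
    # each pending chunk (mismatches + following matches) is accepted only if
    # the chunk's own mismatch fraction is within tolerance, so a long exact
    # seed cannot bankroll absorption of random flanking sequence
    pend_m = pend_l = 0
    pa2, pb1 = a2, b1
    while pa2 < L and pb1 > 0 and pa2 <= pb1 - 1:  # grow A right / B left
        match = seq[pa2] == revcomp(seq[pb1 - 1])
        pa2 += 1
        pb1 -= 1
        pend_m += 0 if match else 1
        pend_l += 1
        if match and pend_m / pend_l <= max_mismatch_frac:
            a2, b1 = pa2, pb1
            mism += pend_m
            pend_m = pend_l = 0
    pend_m = pend_l = 0
    pa1, pb2 = a1, b2
    while pa1 > 0 and pb2 < L and _disjoint((pa1 - 1, a2), (b1, pb2 + 1)):
        match = seq[pa1 - 1] == revcomp(seq[pb2])
        pa1 -= 1
        pb2 += 1
        pend_m += 0 if match else 1
        pend_l += 1
        if match and pend_m / pend_l <= max_mismatch_frac:
            a1, b2 = pa1, pb2
            mism += pend_m
            pend_m = pend_l = 0
    return (a1, a2), (b1, b2), mism


def detect_inverted_repeat(sequence: str, min_len: int = 1000,
                           max_mismatch_frac: float = 0.01,
                           ) -> QuadripartiteStructure:
    """Locate the longest pair of disjoint reverse-complementary repeats ≥ min_len.

    Returns an absent-structure result (``found=False``) when no qualifying
    repeat pair exists.  Single-copy regions are labelled LSC (longer) and SSC
    (shorter); IRb is the copy adjacent to the downstream end of the LSC.
    """
    sequence = sequence.upper()
    L = len(sequence)
    if L <= 2 * min_len:
        raise ValueError(f"sequence length {L} must exceed 2*min_len={2 * min_len}")
    k = min(min_len, 21)
    candidates = []
    for A, B in _seed_pairs(sequence, k):
        first, second = (A, B) if A[0] <= B[0] else (B, A)
        if not _disjoint(first, second):
            continue  # palindromic self-match
        first, second, mism = _extend_mismatch(sequence, first, second, max_mismatch_frac)
        length = first[1] - first[0]
        if length >= min_len and length * 2 < L:
            candidates.append((length, first, second, mism))
    if not candidates:
        return QuadripartiteStructure(found=False)
    candidates.sort(key=lambda c: (-c[0], c[1][0]))
    best_len = candidates[0][0]
    # dedupe identical interval pairs before tie diagnostics
    top = {(c[1], c[2]) for c in candidates if c[0] == best_len}
    if len(top) > 1:
        raise AmbiguousStructureError(
            f"{len(top)} repeat pairs tie at length {best_len}: {sorted(top)}")
    _, first, second, mism = candidates[0]

    gap_inner: Interval = (first[1], second[0])
    gap_outer: Interval = (second[1], first[0])  # wraps the origin
    len_inner = interval_length(gap_inner, L)
    len_outer = interval_length(gap_outer, L)
    if len_inner >= len_outer:
        lsc, ssc = gap_inner, gap_outer
    else:
        lsc, ssc = gap_outer, gap_inner
    # IRb immediately follows the LSC
    irb, ira = (second, first) if lsc[1] % L == second[0] else (first, second)
    return QuadripartiteStructure(
        found=True, lsc=lsc, ssc=ssc, ira=ira, irb=irb,
        ir_length=first[1] - first[0],
        lsc_length=max(len_inner, len_outer),
        ssc_length=min(len_inner, len_outer),
        mismatches=mism,
    )


def standardize_ssc_orientation(record: PlastomeRecord,
                                structure: QuadripartiteStructure,
                                anchor_gene: str = "ndhF") -> PlastomeRecord:
    """Flip the SSC so the anchor gene lies on the '+' strand; idempotent.

    Plastome assemblies occur in both SSC orientations; comparative work needs
    one convention.  Only features fully inside the SSC are remapped.
    """
    if not structure.found:
        raise ValueError("no quadripartite structure to standardize")
    model = record.gene(anchor_gene)  # KeyError with diagnostic if absent
    L = record.length
    s0, s1 = structure.ssc
    if s1 <= s0:
        raise ValueError("origin-wrapping SSC not supported for standardization")
    span = model.span(L)
    if not (in_interval(span[0], structure.ssc, L)
            and in_interval((span[1] - 1) % L, structure.ssc, L)):
        raise ValueError(f"anchor gene {anchor_gene!r} is not inside the SSC "
                         f"{structure.ssc}; gene span {span}")
    if model.strand == "+":
        return record  # already standard
    new_seq = record.sequence[:s0] + revcomp(record.sequence[s0:s1]) + record.sequence[s1:]
    new_features = []
    for f in record.features:
        fs = f.span(L)
        inside = in_interval(fs[0], structure.ssc, L) and in_interval((fs[1] - 1) % L,
                                                                      structure.ssc, L)
        if not inside:
            new_features.append(f)
            continue
        segs = [(s0 + (s1 - e), s0 + (s1 - s)) for s, e in f.segments]
        strand = "+" if f.strand == "-" else "-"
        if strand == "-":
            segs = segs[::-1]
        new_features.append(GeneModel(f.gene_name, f.kind, segs, strand,
                                      f.codon_start_offset))
    return PlastomeRecord(id=record.id, sequence=new_seq, features=new_features,
                          is_circular=record.is_circular, meta=dict(record.meta))


def genome_summary(record: PlastomeRecord,
                   structure: QuadripartiteStructure | None = None) -> dict:
    """One summary row: lengths of the four regions plus gene counts by kind.

    Counts are of distinct gene names, excluding pseudogene annotations (IR
    duplicates therefore count once).
    """
    if structure is None:
        structure = detect_inverted_repeat(record.sequence)
    counts = {kind: len({f.gene_name for f in record.features if f.kind == kind})
              for kind in ("protein_coding", "tRNA", "rRNA", "pseudogene_annotation")}
    return {
        "id": record.id,
        "total_length": record.length,
        "ir_length": structure.ir_length,
        "lsc_length": structure.lsc_length,
        "ssc_length": structure.ssc_length,
        "n_protein_coding": counts["protein_coding"],
        "n_trna": counts["tRNA"],
        "n_rrna": counts["rRNA"],
        "n_pseudogene_annotations": counts["pseudogene_annotation"],
    }
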