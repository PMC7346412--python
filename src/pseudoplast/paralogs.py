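"""Coverage-based classification and degradation screening of paralog contigs.

Assembled paralog contigs of plastid genes (candidate NUPTs — nuclear
sequences of plastid origin) are classified by the ratio of their assembler
k-mer coverage to the organellar coverage: nuclear copies sit orders of
magnitude below the plastid/mitochondrion.  Each contig is then screened for
the same degradation events as the plastid copy, and premature stops are
labelled shared (same reference codon) or novel.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .codons import revcomp
from .scan import (DegradationEvent, PairwiseAlignment, ScanConfig,
                   align_gene_to_reference, detect_events)


class InsufficientOverlapError(ValueError):
    """Contig does not overlap the reference gene enough to be screened."""


@dataclasses.dataclass
class ParalogContig:
    id: str
    sequence: str
    kmer_coverage: float
    best_hit_gene: str | None = None
    classification: str | None = None

    def __post_init__(self):
        if self.kmer_coverage < 0:
            raise ValueError("coverage must be non-negative")


def classify_origin(contig: ParalogContig, organellar_coverage: float,
                    ratio_threshold: float = 0.1,
                    organellar_ratio: float = 0.5) -> str:
    """Classify a contig as nuclear / organellar / ambiguous by coverage ratio.

    nuclear if coverage/organellar < ratio_threshold (strict); organellar if
    ≥ organellar_ratio; ambiguous in between.  Scale-invariant by construction.
    """
    if organellar_coverage <= 0:
        raise ValueError("organellar coverage must be positive")
    r = contig.kmer_coverage / organellar_coverage
    if r < ratio_threshold:
        cls = "nuclear"
    elif r >= organellar_ratio:
        cls = "organellar"
    else:
        cls = "ambiguous"
    contig.classification = cls
    return cls


def _orient_and_align(contig_seq: str, reference_cds: str,
                      config: ScanConfig) -> PairwiseAlignment:
    """Align the contig (best strand) to the reference CDS, free end gaps on
    both sequences (contigs are typically partial)."""
    best = None
    for probe in (contig_seq, revcomp(contig_seq)):
        aln = align_gene_to_reference(probe, reference_cds, config,
                                      free_ref_end_gaps=True,
                                      free_focal_end_gaps=True)
        if best is None or aln.score > best.score:
            best = aln
    return best


def _aligned_overlap(aln: PairwiseAlignment) -> int:
    return sum(1 for r, f in zip(aln.ref, aln.focal) if r != "-" and f != "-")


def assign_best_hit(contig: ParalogContig, reference_cds_by_gene: dict[str, str],
                    config: ScanConfig | None = None) -> str | None:
    """Assign a contig to the reference gene with the best alignment score.

    Ties leave the contig unassigned (best_hit_gene None, to be excluded)."""
    config = config or ScanConfig()
    scores = {}
    for gene, cds in reference_cds_by_gene.items():
        scores[gene] = _orient_and_align(contig.sequence, cds, config).score
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        contig.best_hit_gene = None
        return None
    contig.best_hit_gene = ranked[0][0]
    return contig.best_hit_gene


def _ref_positions_of(aln: PairwiseAlignment, kind: str, events) -> set[int]:
    """Reference coordinates (bp) of premature-stop events in an alignment."""
    ref_pos_at = np.cumsum([1 if ch != "-" else 0 for ch in aln.ref])
    out = set()
    for e in events:
        if e.kind == kind:
            out.add(int(ref_pos_at[e.position]) - (1 if aln.ref[e.position] != "-" else 0))
    return out


def screen_paralog(contig: ParalogContig, reference_cds: str,
                   plastid_copy_events: list[DegradationEvent] | None = None,
                   plastid_alignment: PairwiseAlignment | None = None,
                   config: ScanConfig | None = None,
                   min_overlap: int = 100) -> list[DegradationEvent]:
    """Screen a paralog contig for degradation events against a reference CDS.

    Reuses the pseudogene event detector on the contig-vs-reference alignment
    (frame anchored to the reference at the first aligned column).  When the
    plastid copy's events and alignment are supplied, each premature stop is
    additionally labelled ``shared`` (same reference codon as a plastid-copy
    stop) or ``novel``.
    """
    config = config or ScanConfig()
    aln = _orient_and_align(contig.sequence, reference_cds, config)
    overlap = _aligned_overlap(aln)
    if overlap < min_overlap:
        raise InsufficientOverlapError(
            f"contig {contig.id}: only {overlap} bp aligned to reference "
            f"(minimum {min_overlap})")
    events = detect_events(aln, config, partial=True)
    if plastid_copy_events is not None and plastid_alignment is not None:
        plastid_codons = {p // 3 for p in _ref_positions_of(
            plastid_alignment, "premature_stop", plastid_copy_events)}
        ref_pos_at = np.cumsum([1 if ch != "-" else 0 for ch in aln.ref])
        for e in events:
            if e.kind != "premature_stop":
                continue
            rp = int(ref_pos_at[e.position]) - (1 if aln.ref[e.position] != "-" else 0)
            label = "shared" if rp // 3 in plastid_codons else "novel"
            e.detail = f"{e.detail};{label}"
    return events


def prep_gene_matrix(plastid_alignment: dict[str, str],
                     contigs: list[ParalogContig],
                     min_remaining: int = 200,
                     ambiguous_mask=None,
                     anchor_taxon: str | None = None,
                     config: ScanConfig | None = None) -> dict[str, str]:
    """Project contigs into a per-gene plastid alignment for tree building.

    Contigs are aligned to the (ungapped) anchor sequence and their bases
    placed at the corresponding alignment columns — i.e. trimmed to the
    chloroplast gene extent, with contig-specific insertions dropped.  Masked
    (ambiguously aligned) columns are then removed and sequences with fewer
    than ``min_remaining`` remaining bp are discarded.
    """
    import warnings

    config = config or ScanConfig()
    if not plastid_alignment:
        raise ValueError("empty plastid alignment")
    anchor_taxon = anchor_taxon or next(iter(plastid_alignment))
    anchor_row = plastid_alignment[anchor_taxon]
    n_cols = len(anchor_row)
    col_of = [i for i, ch in enumerate(anchor_row) if ch != "-"]
    anchor_seq = anchor_row.replace("-", "")

    rows = dict(plastid_alignment)
    for contig in contigs:
        aln = _orient_and_align(contig.sequence, anchor_seq, config)
        row = ["-"] * n_cols
        rp = 0
        for r, f in zip(aln.ref, aln.focal):
            if r != "-":
                if f != "-":
                    row[col_of[rp]] = f
                rp += 1
        rows[contig.id] = "".join(row)

    keep = np.ones(n_cols, dtype=bool)
    if ambiguous_mask is not None:
        keep = ~np.asarray(ambiguous_mask, dtype=bool)
    out = {}
    for name, row in rows.items():
        trimmed = "".join(ch for ch, k in zip(row, keep) if k)
        if sum(1 for ch in trimmed if ch not in "-?") >= min_remaining:
            out[name] = trimmed
    if not any(c.id in out for c in contigs) and contigs:
        warnings.warn("all contigs dropped from gene matrix")
    return out
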