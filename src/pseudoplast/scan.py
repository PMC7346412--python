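"""Criteria-based pseudogene detection against a panel of reference orthologs.

A focal gene copy is aligned to an intact reference ortholog (affine-gap
global alignment) and scanned for disabling lesions: premature stop codons,
frameshifting indels, loss of the canonical stop, large deletions, and short
inversions.  Supporting (non-primary) anomalies — novel terminations, length
anomalies, hydrophobicity outliers relative to the panel — are reported but
do not alone make a pseudogene call.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

import numpy as np
from Bio import Align
from scipy import stats

from .codons import STOP_CODONS, revcomp, translate
from .io import PlastomeRecord, GeneModel, extract_cds, protein_of

PRIMARY_EVENT_KINDS = frozenset(
    {"premature_stop", "frameshift", "lost_canonical_stop", "large_deletion"})
SUPPORTING_EVENT_KINDS = frozenset(
    {"short_inversion", "novel_termination", "hydrophobicity_outlier", "length_anomaly"})

# positive Kyte–Doolittle hydropathy
DEFAULT_HYDROPHOBIC = frozenset("ACFILMV")


@dataclasses.dataclass
class ScanConfig:
    """Thresholds for annotation lift and degradation-event calling."""

    large_deletion_threshold: int = 100
    min_identity_for_lift: float = 0.70
    hydrophobic_residues: frozenset = DEFAULT_HYDROPHOBIC
    ci_level: float = 0.95
    inversion_window: int = 200
    inversion_identity_gain: float = 0.25
    stop_search_window: int = 30         # bp after the reference stop column
    termination_margin: int = 200        # extra downstream sequence scanned
    match_score: float = 2.0
    mismatch_score: float = -3.0
    open_gap_score: float = -10.0
    extend_gap_score: float = -0.5
    excluded_genes: tuple = ("ycf15", "ycf1", "ycf2")  # known IR-boundary pseudogenes

    def __post_init__(self):
        if self.large_deletion_threshold <= 0 or self.inversion_window <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")


@dataclasses.dataclass
class DegradationEvent:
    kind: str
    position: int      # alignment column
    detail: str = ""


@dataclasses.dataclass
class GeneScan:
    events: list[DegradationEvent]
    verdict: str  # pseudogene | anomalous | intact
    identity: float | None = None
    protein_length: int | None = None
    hydrophobicity: "HydrophobicityProfile | None" = None


@dataclasses.dataclass
class HydrophobicityProfile:
    gene_name: str
    focal_fraction: float
    panel_fractions: list[float]
    ci: tuple[float, float] | None


@dataclasses.dataclass
class DegradationReport:
    focal_id: str
    per_gene: dict[str, GeneScan]
    missing: list[str] = dataclasses.field(default_factory=list)

    def flagged(self) -> list[str]:
        return sorted(g for g, s in self.per_gene.items() if s.verdict == "pseudogene")


# ---------------------------------------------------------------------------
# Pairwise alignment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PairwiseAlignment:
    ref: str    # gapped reference row
    focal: str  # gapped focal row
    score: float

    def identity(self) -> float:
        """Identities over reference length (ungapped)."""
        matches = sum(1 for r, f in zip(self.ref, self.focal) if r == f and r != "-")
        ref_len = sum(1 for r in self.ref if r != "-")
        return matches / ref_len if ref_len else 0.0


def _aligner(config: ScanConfig, free_ref_end_gaps: bool,
             free_focal_end_gaps: bool = False) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = config.match_score
    a.mismatch_score = config.mismatch_score
    a.open_gap_score = config.open_gap_score
    a.extend_gap_score = config.extend_gap_score
    if free_ref_end_gaps:
        # focal overhang beyond the reference ends is not penalized
        a.open_end_insertion_score = 0.0
        a.extend_end_insertion_score = 0.0
    if free_focal_end_gaps:
        a.open_end_deletion_score = 0.0
        a.extend_end_deletion_score = 0.0
    return a


def align_gene_to_reference(focal_region: str, reference_cds: str,
                            config: ScanConfig | None = None,
                            free_ref_end_gaps: bool = True,
                            free_focal_end_gaps: bool = False) -> PairwiseAlignment:
    """Affine-gap global alignment of a focal gene region against a reference CDS.

    Scoring defaults: match +2, mismatch −3, gap open −10, gap extend −0.5.
    Focal sequence extending past the reference ends is unpenalized by default
    so downstream termination shifts can be inspected.  Deterministic: the
    aligner's first optimal alignment is always taken.
    """
    if not focal_region or not reference_cds:
        raise ValueError("sequences must be non-empty")
    config = config or ScanConfig()
    a = _aligner(config, free_ref_end_gaps, free_focal_end_gaps)
    aln = a.align(reference_cds.upper(), focal_region.upper())[0]
    return PairwiseAlignment(ref=str(aln[0]), focal=str(aln[1]), score=aln.score)


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _gap_runs(row: str, start: int, stop: int):
    """(start_col, length) of maximal gap runs of `row` within [start, stop)."""
    runs = []
    i = start
    while i < stop:
        if row[i] == "-":
            j = i
            while j < stop and row[j] == "-":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def _detect_inversions(ref_aln: str, focal_aln: str, config: ScanConfig,
                       core: tuple[int, int]):
    """Short-inversion calls, returning (events, consumed_run_starts).

    The aligner renders an in-place inversion as a mosaic of mismatches and
    compensating indels.  We segment the core into "noisy blocks" — maximal
    runs of non-identical columns separated by < 15 clean matches — and call
    an inversion when the block's focal sequence, reverse-complemented,
    matches the reference far better than the direct comparison (identity
    gain ≥ ``inversion_identity_gain``).  Gap runs inside a called block are
    marked consumed so they are not double-reported as deletions/frameshifts.
    """
    events = []
    consumed: set[int] = set()
    c0, c1 = core
    noisy = [i for i in range(c0, c1)
             if ref_aln[i] == "-" or focal_aln[i] == "-" or ref_aln[i] != focal_aln[i]]
    blocks: list[list[int]] = []
    for col in noisy:
        if blocks and col - blocks[-1][-1] <= 15:
            blocks[-1].append(col)
        else:
            blocks.append([col])
    for bl in blocks:
        span = bl[-1] - bl[0] + 1
        if span < 12 or span > int(config.inversion_window * 1.5):
            continue
        ref_seg = ref_aln[bl[0]:bl[-1] + 1].replace("-", "")
        foc_seg = focal_aln[bl[0]:bl[-1] + 1].replace("-", "")
        m = min(len(ref_seg), len(foc_seg))
        if m < 12 or abs(len(ref_seg) - len(foc_seg)) > max(3, 0.2 * m):
            continue  # net length change: a deletion/insertion, not an inversion
        # direct and reverse-complement identities are computed the same way
        # (best ungapped identity over small coordinate shifts) so the gain is
        # a like-for-like comparison; the aligner's own rendering can offset
        # the inverted segment relative to the reference
        min_ov = max(20, m // 3)

        def best_shift_identity(a: str, b: str) -> float:
            best = 0.0
            for d in range(-min(100, m), min(100, m) + 1):
                if d >= 0:
                    pairs = zip(a[d:], b)
                    ov = min(len(a) - d, len(b))
                else:
                    pairs = zip(a, b[-d:])
                    ov = min(len(a), len(b) + d)
                if ov < min_ov:
                    continue
                best = max(best, sum(x == y for x, y in pairs) / ov)
            return best

        direct = best_shift_identity(ref_seg, foc_seg)
        flipped = best_shift_identity(ref_seg, revcomp(foc_seg))
        if flipped - direct >= config.inversion_identity_gain:
            events.append(DegradationEvent(
                "short_inversion", bl[0],
                f"span={span};identity_gain={flipped - direct:.2f}"))
            consumed.update(s for s, _ in _gap_runs(focal_aln, bl[0], bl[-1] + 1))
            consumed.update(s for s, _ in _gap_runs(ref_aln, bl[0], bl[-1] + 1))
    return events, consumed


def detect_events(alignment: PairwiseAlignment, config: ScanConfig | None = None,
                  partial: bool = False) -> list[DegradationEvent]:
    """Scan a focal-vs-reference alignment for degradation events.

    The reference row is expected to be an intact CDS including its stop
    codon.  With ``partial=True`` (paralog contigs) terminal gap runs on both
    rows are ignored and the focal reading frame is anchored to the reference
    frame at the first aligned column instead of the focal sequence start.
    """
    config = config or ScanConfig()
    ref_aln, focal_aln = alignment.ref, alignment.focal
    n = len(ref_aln)
    events: list[DegradationEvent] = []

    # core = columns between the first and last aligned (both non-gap) column,
    # extended per policy: full-gene scans keep focal-gap runs at the ref ends
    # (true 5'/3' deletions); overhanging focal tails are never lesions.
    ref_cols = [i for i in range(n) if ref_aln[i] != "-"]
    if not ref_cols:
        return events
    if partial:
        both = [i for i in range(n) if ref_aln[i] != "-" and focal_aln[i] != "-"]
        if not both:
            return events
        core = (both[0], both[-1] + 1)
    else:
        core = (ref_cols[0], ref_cols[-1] + 1)
    c0, c1 = core

    inv_events, consumed = _detect_inversions(ref_aln, focal_aln, config, core)
    events.extend(inv_events)

    # ------------------------------------------------------------------ gaps
    net = 0
    frameshift_reported = False
    runs = ([(s, l, "del") for s, l in _gap_runs(focal_aln, c0, c1)]
            + [(s, l, "ins") for s, l in _gap_runs(ref_aln, c0, c1)])
    runs.sort()
    for start, length, kind in runs:
        net += length if kind == "ins" else -length
        if start in consumed:
            continue  # gap run explained by an inversion: counts toward the
            # running frame balance but is not itself a lesion
        if kind == "del" and length >= config.large_deletion_threshold:
            events.append(DegradationEvent("large_deletion", start, f"length={length}"))
        if net % 3 != 0 and not frameshift_reported:
            events.append(DegradationEvent("frameshift", start,
                                           f"net={net};indel_len={length}"))
            frameshift_reported = True

    # ------------------------------------------------------- reading frame
    focal_seq = focal_aln.replace("-", "")
    fpos_at = np.cumsum([1 if ch != "-" else 0 for ch in focal_aln])  # chars ≤ col
    col_of_fpos = {}
    for col, ch in enumerate(focal_aln):
        if ch != "-":
            col_of_fpos[fpos_at[col] - 1] = col

    if partial:
        # anchor the focal codon grid to the reference frame at the first
        # aligned column: focal chars before c0, plus the offset to the next
        # in-frame reference codon start
        r_before = sum(1 for i in range(c0) if ref_aln[i] != "-")
        f_before = int(fpos_at[c0]) - 1  # both rows non-gap at c0
        frame0 = f_before + (3 - r_before % 3) % 3
    else:
        frame0 = 0

    stops = []
    for p in range(frame0, len(focal_seq) - 2, 3):
        if focal_seq[p:p + 3] in STOP_CODONS:
            stops.append(p)

    # reference stop codon column (start of the last ref codon)
    ref_len = len(ref_aln) - ref_aln.count("-")
    ref_has_stop = False
    ref_ungapped = ref_aln.replace("-", "")
    if ref_len >= 3 and ref_ungapped[-3:] in STOP_CODONS:
        ref_has_stop = True
        # column of reference position ref_len-3
        count = 0
        col_ref_stop = n - 1
        for col, ch in enumerate(ref_aln):
            if ch != "-":
                if count == ref_len - 3:
                    col_ref_stop = col
                    break
                count += 1

    if ref_has_stop:
        f0 = int(fpos_at[col_ref_stop]) - (1 if focal_aln[col_ref_stop] != "-" else 0)
        for p in stops:
            col = col_of_fpos.get(p)
            if col is not None and col < col_ref_stop and p < f0:
                events.append(DegradationEvent("premature_stop", col,
                                               f"focal_codon={p // 3}"))
        if not partial or c1 > col_ref_stop:
            near = [p for p in stops if f0 <= p <= f0 + config.stop_search_window]
            if not near:
                events.append(DegradationEvent("lost_canonical_stop", col_ref_stop,
                                               "no stop at/within "
                                               f"{config.stop_search_window} bp of reference stop"))
                downstream = [p for p in stops if p > f0 + config.stop_search_window]
                if downstream:
                    ext = downstream[0] - f0
                    events.append(DegradationEvent(
                        "novel_termination", col_ref_stop,
                        f"extension={ext} bp before novel stop"))
    return events


# ---------------------------------------------------------------------------
# Hydrophobicity
# ---------------------------------------------------------------------------

def hydrophobic_fraction(protein: str, residue_set=DEFAULT_HYDROPHOBIC) -> float:
    """Fraction of counted residues that are hydrophobic ('*' and 'X' excluded)."""
    counted = [r for r in protein.upper() if r not in "*X"]
    if not counted:
        raise ValueError("no countable residues")
    return sum(1 for r in counted if r in residue_set) / len(counted)


def hydrophobicity_ci(panel_fractions, ci_level: float = 0.95) -> tuple[float, float]:
    """Student-t confidence interval of the panel mean hydrophobic fraction."""
    x = np.asarray(list(panel_fractions), dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 panel values, got {x.size}")
    mean = x.mean()
    sd = x.std(ddof=1)
    tq = stats.t.ppf(1 - (1 - ci_level) / 2, df=x.size - 1)
    half = tq * sd / np.sqrt(x.size)
    return (mean - half, mean + half)


# ---------------------------------------------------------------------------
# Annotation lift
# ---------------------------------------------------------------------------

def _kmer_hits(seq: str, index: dict, k: int):
    hits = defaultdict(int)  # offset -> votes
    for q in range(0, len(seq) - k + 1, 3):
        for t in index.get(seq[q:q + k], ()):
            hits[t - q] += 1
    return hits


def annotate_by_homology(target: PlastomeRecord, reference: PlastomeRecord,
                         config: ScanConfig | None = None,
                         k: int = 15) -> PlastomeRecord:
    """Lift gene models from an annotated reference onto an unannotated target.

    Each reference gene is located by exact k-mer seeding (both strands)
    followed by affine-gap alignment of the reference CDS against the
    candidate window; models are transferred when best-hit identity is at
    least ``min_identity_for_lift`` (identity over reference length).
    Unlocatable genes are recorded in ``meta['missing_genes']``.
    """
    config = config or ScanConfig()
    tseq = target.sequence
    index = defaultdict(list)
    for i in range(len(tseq) - k + 1):
        index[tseq[i:i + k]].append(i)

    lifted: list[GeneModel] = []
    identities: dict[str, float] = {}
    missing: list[str] = []
    for model in reference.features:
        cds = extract_cds(reference, model.gene_name)
        if len(cds) < k:
            missing.append(model.gene_name)
            continue
        best = None  # (votes, strand, offset)
        for strand, probe in (("+", cds), ("-", revcomp(cds))):
            hits = _kmer_hits(probe, index, k)
            if hits:
                off, votes = max(hits.items(), key=lambda kv: (kv[1], -kv[0]))
                if best is None or votes > best[0]:
                    best = (votes, strand, off)
        if best is None or best[0] < 2:
            missing.append(model.gene_name)
            continue
        _, strand, off = best
        margin = 100
        w0 = max(0, off - margin)
        w1 = min(len(tseq), off + len(cds) + margin)
        window = tseq[w0:w1]
        probe = cds if strand == "+" else revcomp(cds)
        aln = align_gene_to_reference(window, probe, config, free_ref_end_gaps=True)
        ident = aln.identity()
        if ident < config.min_identity_for_lift:
            missing.append(model.gene_name)
            continue
        # window coordinates of the aligned reference extent
        ref_cols = [i for i, ch in enumerate(aln.ref) if ch != "-"]
        fpos = np.cumsum([1 if ch != "-" else 0 for ch in aln.focal])
        a0 = int(fpos[ref_cols[0]]) - (1 if aln.focal[ref_cols[0]] != "-" else 0)
        a1 = int(fpos[ref_cols[-1]])
        g0, g1 = w0 + a0, w0 + a1
        # `strand` is the target-genome strand of the sense sequence (the
        # probe was the strand-corrected CDS), so it is the lifted strand
        lifted.append(GeneModel(model.gene_name, model.kind, [(g0, g1)],
                                strand, model.codon_start_offset))
        identities[model.gene_name] = ident

    out = PlastomeRecord(id=target.id, sequence=target.sequence,
                         features=lifted, is_circular=target.is_circular,
                         meta=dict(target.meta))
    out.meta["lift_identity"] = identities
    out.meta["missing_genes"] = missing
    return out


# ---------------------------------------------------------------------------
# Genome-wide scan
# ---------------------------------------------------------------------------

def _focal_region(record: PlastomeRecord, model: GeneModel, margin: int) -> str:
    """Strand-corrected gene sequence extended `margin` bp downstream."""
    L = record.length
    s, e = model.span(L)
    if model.strand == "+":
        e2 = (e + margin) % L if record.is_circular else min(e + margin, L)
        return record.slice(s, e2)
    s2 = (s - margin) % L if record.is_circular else max(0, s - margin)
    return revcomp(record.slice(s2, e))


def scan_genome(focal: PlastomeRecord, panel: list[PlastomeRecord],
                config: ScanConfig | None = None,
                reference: PlastomeRecord | None = None) -> DegradationReport:
    """Scan every shared protein-coding gene of a focal genome against a panel.

    The first panel member (or ``reference``) supplies the intact reference
    CDS per gene; the remaining panel members provide ortholog protein
    lengths and hydrophobicity for the supporting criteria.  Genes known to
    be fragmented by IR boundaries (config.excluded_genes) are skipped.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    config = config or ScanConfig()
    reference = reference or panel[0]

    if not focal.features:
        focal = annotate_by_homology(focal, reference, config)

    per_gene: dict[str, GeneScan] = {}
    missing: list[str] = list(focal.meta.get("missing_genes", []))
    for gene in reference.gene_names("protein_coding"):
        if gene in config.excluded_genes:
            continue
        ref_cds = extract_cds(reference, gene)
        try:
            model = focal.gene(gene)
        except KeyError:
            if gene not in missing:
                missing.append(gene)
            continue
        region = _focal_region(focal, model, config.termination_margin)
        aln = align_gene_to_reference(region, ref_cds, config)
        events = detect_events(aln, config)

        # supporting panel-based criteria
        focal_protein = translate(region)
        focal_protein = focal_protein.split("*")[0] if "*" in focal_protein else focal_protein
        panel_lengths, panel_fracs = [], []
        for member in panel:
            if member.id == focal.id:
                continue
            try:
                prot = protein_of(member, gene)
            except KeyError:
                continue
            if prot:
                panel_lengths.append(len(prot))
                panel_fracs.append(hydrophobic_fraction(prot, config.hydrophobic_residues))
        if panel_lengths and not (min(panel_lengths) <= len(focal_protein) <= max(panel_lengths)):
            events.append(DegradationEvent(
                "length_anomaly", 0,
                f"protein_length={len(focal_protein)};"
                f"panel_range=[{min(panel_lengths)},{max(panel_lengths)}]"))
        profile = None
        if len(panel_fracs) >= 3 and focal_protein:
            ci = hydrophobicity_ci(panel_fracs, config.ci_level)
            frac = hydrophobic_fraction(focal_protein, config.hydrophobic_residues)
            profile = HydrophobicityProfile(gene, frac, panel_fracs, ci)
            if not ci[0] <= frac <= ci[1]:
                events.append(DegradationEvent(
                    "hydrophobicity_outlier", 0,
                    f"focal={frac:.3f};ci=[{ci[0]:.3f},{ci[1]:.3f}]"))

        verdict = "pseudogene" if any(e.kind in PRIMARY_EVENT_KINDS for e in events) \
            else ("anomalous" if events else "intact")
        per_gene[gene] = GeneScan(events=events, verdict=verdict,
                                  identity=focal.meta.get("lift_identity", {}).get(gene),
                                  protein_length=len(focal_protein),
                                  hydrophobicity=profile)
    return DegradationReport(focal_id=focal.id, per_gene=per_gene, missing=missing)
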