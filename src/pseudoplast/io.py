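"""Reading and writing annotated plastome records.

Internal coordinates are 0-based half-open on the forward strand; GenBank's
1-based inclusive locations are converted on read and restored on write.
Circular topology is modelled by allowing a gene segment to wrap the origin
(``end <= start`` means the segment runs ``[start, L) + [0, end)``); the
sequence is never doubled.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .codons import revcomp, translate

KINDS = ("protein_coding", "tRNA", "rRNA", "pseudogene_annotation")
_FEATURE_TYPE = {"protein_coding": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "pseudogene_annotation": "CDS"}


class GenBankParseError(ValueError):
    pass


@dataclasses.dataclass
class GeneModel:
    """A gene's location: ordered segments (transcription direction), strand, frame offset."""

    gene_name: str
    kind: str
    segments: list[tuple[int, int]]
    strand: str  # '+' or '-'
    codon_start_offset: int = 0

    def __post_init__(self):
        if not self.gene_name:
            raise ValueError("gene name must be non-empty")
        if self.kind not in KINDS:
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def spliced_length(self, genome_length: int) -> int:
        total = 0
        for start, end in self.segments:
            total += (end - start) if end > start else (genome_length - start + end)
        return total

    def span(self, genome_length: int) -> tuple[int, int]:
        """Genomic interval covering all segments (may wrap: end <= start)."""
        starts = [s for s, _ in self.segments]
        ends = [e for _, e in self.segments]
        if any(e <= s for s, e in self.segments):
            return (min(starts), max(ends))
        return (min(starts), max(ends))


@dataclasses.dataclass
class PlastomeRecord:
    """A circular annotated plastid genome."""

    id: str
    sequence: str
    features: list[GeneModel] = dataclasses.field(default_factory=list)
    is_circular: bool = True
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, gene_name: str) -> GeneModel:
        for f in self.features:
            if f.gene_name == gene_name:
                return f
        names = sorted({f.gene_name for f in self.features})
        raise KeyError(f"gene {gene_name!r} not found; available: {', '.join(names)}")

    def gene_names(self, kind: str | None = None) -> list[str]:
        return [f.gene_name for f in self.features if kind is None or f.kind == kind]

    def slice(self, start: int, end: int) -> str:
        """Forward-strand subsequence; end <= start wraps the origin (circular)."""
        if end > start:
            return self.sequence[start:end]
        if not self.is_circular:
            raise ValueError("origin-wrapping slice on a linear record")
        return self.sequence[start:] + self.sequence[:end]


def segment_slice(record: PlastomeRecord, segment: tuple[int, int]) -> str:
    return record.slice(*segment)


def extract_cds(record: PlastomeRecord, gene_name: str) -> str:
    """Spliced, strand-corrected coding sequence of a gene.

    Segments are concatenated in transcription order (reverse-complemented for
    '-' strand genes) and the codon_start offset is applied.
    """
    model = record.gene(gene_name)
    parts = []
    for seg in model.segments:
        raw = record.slice(*seg)
        parts.append(revcomp(raw) if model.strand == "-" else raw)
    return "".join(parts)[model.codon_start_offset:]


# ---------------------------------------------------------------------------
# GenBank I/O
# ---------------------------------------------------------------------------

def _location_to_segments(location, length: int, is_circular: bool):
    """Convert a Biopython location to internal segments + strand.

    Adjacent parts that meet at the origin of a circular record are merged
    into a single wrapping segment.
    """
    parts = list(location.parts)
    strand = "-" if location.strand == -1 else "+"
    raw = [(int(p.start), int(p.end)) for p in parts]
    # genomic (ascending) order for merging
    asc = sorted(raw, key=lambda se: se[0])
    merged = list(asc)
    if is_circular and len(asc) >= 2 and asc[-1][1] == length and asc[0][0] == 0:
        wrap = (asc[-1][0], asc[0][1])  # end <= start: wraps
        merged = asc[1:-1]
        merged.append(wrap)
        merged.sort(key=lambda se: se[0])
    if strand == "-":
        merged = merged[::-1]  # transcription direction
    return merged, strand


def _segments_to_location(model: GeneModel, length: int):
    genomic = list(model.segments)
    if model.strand == "-":
        genomic = genomic[::-1]
    parts = []
    for start, end in genomic:
        if end > start:
            parts.append(SimpleLocation(start, end, strand=1 if model.strand == "+" else -1))
        else:  # origin wrap splits into two parts
            s = 1 if model.strand == "+" else -1
            parts.append(SimpleLocation(start, length, strand=s))
            parts.append(SimpleLocation(0, end, strand=s))
    if model.strand == "-":
        parts = parts[::-1]
    return parts[0] if len(parts) == 1 else CompoundLocation(parts)


def read_genbank(path: str | Path) -> PlastomeRecord:
    """Read a single-record GenBank flat file into a PlastomeRecord."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "genbank"))
    if len(records) != 1:
        raise GenBankParseError(f"{path}: expected exactly one record, found {len(records)}")
    rec = records[0]
    is_circular = rec.annotations.get("topology", "linear") == "circular"
    length = len(rec.seq)
    features: list[GeneModel] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA"):
            continue
        quals = feat.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or [None])[0]
        if not name:
            raise GenBankParseError(f"{path}: {feat.type} feature without gene/locus_tag")
        try:
            segments, strand = _location_to_segments(feat.location, length, is_circular)
        except Exception as exc:  # pragma: no cover - defensive
            raise GenBankParseError(f"{path}: malformed location for {name}: {exc}") from exc
        if feat.type == "CDS":
            kind = "pseudogene_annotation" if "pseudo" in quals or "pseudogene" in quals \
                else "protein_coding"
        else:
            kind = feat.type
        offset = int(quals.get("codon_start", ["1"])[0]) - 1
        features.append(GeneModel(name, kind, segments, strand, offset))
    return PlastomeRecord(id=rec.id or rec.name, sequence=str(rec.seq),
                          features=features, is_circular=is_circular)


def write_genbank(record: PlastomeRecord, path: str | Path) -> Path:
    """Write a PlastomeRecord as a GenBank flat file (round-trip safe)."""
    path = Path(path)
    rec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.is_circular else "linear"
    rec.annotations["date"] = "01-JAN-2020"  # fixed for deterministic output
    for model in record.features:
        quals = {"gene": [model.gene_name]}
        if model.kind in ("protein_coding", "pseudogene_annotation"):
            quals["codon_start"] = [str(model.codon_start_offset + 1)]
            quals["transl_table"] = ["11"]
        if model.kind == "pseudogene_annotation":
            quals["pseudo"] = [""]
        rec.features.append(SeqFeature(_segments_to_location(model, record.length),
                                       type=_FEATURE_TYPE[model.kind], qualifiers=quals))
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "genbank")
    return path


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str] | Iterable[tuple[str, str]],
                path: str | Path, width: int = 70) -> Path:
    path = Path(path)
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Degradation report serialization (schema shared with pseudogene_scan)
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1


def write_report(report, out_prefix: str | Path) -> tuple[Path, Path]:
    """Serialize a DegradationReport to ``<prefix>.json`` and ``<prefix>.tsv``.

    The TSV carries one verdict row per gene plus one row per event, mirroring
    a per-gene evidence table (gene, verdict, event kind, position, detail).
    """
    import pandas as pd

    out_prefix = Path(out_prefix)
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "focal_id": report.focal_id,
        "genes": {
            gene: {
                "verdict": entry.verdict,
                "events": [dataclasses.asdict(e) for e in entry.events],
            }
            for gene, entry in sorted(report.per_gene.items())
        },
    }
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2) + "\n")

    rows = []
    for gene, entry in sorted(report.per_gene.items()):
        if not entry.events:
            rows.append({"gene": gene, "verdict": entry.verdict, "event": "",
                         "position": "", "detail": ""})
        for e in entry.events:
            rows.append({"gene": gene, "verdict": entry.verdict, "event": e.kind,
                         "position": e.position, "detail": e.detail})
    tsv_path = out_prefix.with_suffix(".tsv")
    pd.DataFrame(rows, columns=["gene", "verdict", "event", "position", "detail"]) \
        .to_csv(tsv_path, sep="\t", index=False)
    return json_path, tsv_path


def intact_protein_coding(record: PlastomeRecord) -> list[str]:
    """Names of protein-coding (non-pseudogene-annotated) genes."""
    return [f.gene_name for f in record.features if f.kind == "protein_coding"]


def protein_of(record: PlastomeRecord, gene_name: str) -> str:
    """Predicted protein of a gene, translated up to (not including) the stop."""
    aa = translate(extract_cds(record, gene_name))
    return aa.split("*")[0] if "*" in aa else aa
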