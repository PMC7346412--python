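"""End-to-end orchestration: structure → scan → paralogs → stats → selection.

``run_pipeline`` executes the full degradation analysis on a synthetic panel
(generated and lesioned by the synthetic-data module) or on user-supplied
annotated genomes, writing per-stage tables plus a manifest with input/output
checksums so a run can be verified and reproduced bit-for-bit from its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .paralogs import InsufficientOverlapError, ParalogContig, classify_origin, \
    prep_gene_matrix, screen_paralog
from .scan import (ScanConfig, align_gene_to_reference, detect_events,
                   scan_genome)
from .selection import (build_codon_alignment, compile_tree, fit_lrt_pair,
                        hochberg_adjust, lrt, tree_from_newick)
from .simulate import (SyntheticConfig, build_synthetic_plastome,
                       inject_degradation, stream)
from .stats import alignment_stats, one_tailed_t, plastid_read_fraction
from .structure import detect_inverted_repeat, genome_summary

# the canonical focal lesion set: five ndh genes plus ccsA and cemA, with the
# causal mechanisms distributed as in degraded semi-aquatic plastomes.
# Frameshifts sit in the 3' third of each gene so the in-frame portion stays
# long enough for the per-gene selection test (>= 200 bp rule).
DEFAULT_LESIONS = [
    ("ccsA", "frameshift", {"position": 120}),
    ("ndhA", "frameshift", {"position": 140}),
    ("ndhD", "frameshift", {"position": 125}),
    ("ndhD", "large_deletion", {"length": 150, "position": 60}),
    ("ndhF", "frameshift", {"position": 200}),
    ("ndhF", "large_deletion", {"length": 120, "position": 90}),
    ("ndhB", "premature_stop", {}),
    ("ndhK", "short_inversion", {}), ("ndhK", "premature_stop", {}),
    ("cemA", "large_deletion", {"length": 129}),
    ("cemA", "termination_shift", {"extension": 137}),
]


@dataclasses.dataclass
class RunConfig:
    out_dir: Path
    seed: int
    synthetic: SyntheticConfig | None = None
    lesions: list = dataclasses.field(default_factory=lambda: list(DEFAULT_LESIONS))
    focal_path: Path | None = None
    panel_paths: list = dataclasses.field(default_factory=list)
    scan: ScanConfig = dataclasses.field(default_factory=ScanConfig)
    selection_n_starts: int = 1
    read_fraction_focal: float = 3.4      # percent, synthetic mapped-read summaries
    read_fraction_panel_mean: float = 10.1
    read_fraction_panel_sd: float = 2.5


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _codon_clean_copy(focal_cds: str, ref_cds: str, config: ScanConfig) -> str:
    """Prepare a lesioned gene copy for codon-model fitting.

    Codon models assume in-frame, same-strand sequence.  Sequence downstream
    of an uncompensated frameshift no longer codes in the reference frame,
    and an inverted segment is wrong-strand sequence; both would masquerade
    as bursts of nonsynonymous change, so the frameshifted tail is truncated
    and inversion spans are recoded to N (missing) — the codon-aware
    analogue of removing ambiguously aligned regions.
    """
    import re

    import numpy as np

    aln = align_gene_to_reference(focal_cds, ref_cds, config)
    events = detect_events(aln, config)
    fpos = np.cumsum([ch != "-" for ch in aln.focal])

    def focal_at(col):
        return int(fpos[col]) - (1 if aln.focal[col] != "-" else 0)

    out = list(focal_cds)
    for e in events:
        if e.kind != "short_inversion":
            continue
        m = re.search(r"span=(\d+)", e.detail)
        span = int(m.group(1)) if m else config.inversion_window
        start = focal_at(e.position)
        for p in range(max(0, start - 2), min(len(out), start + span + 2)):
            out[p] = "N"
    cleaned = "".join(out)
    frameshifts = [e for e in events if e.kind == "frameshift"]
    if frameshifts:
        cut = focal_at(frameshifts[0].position)
        cut -= cut % 3
        if cut >= 60:
            cleaned = cleaned[:cut]
    return cleaned


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, (Path, frozenset)):
            return sorted(o) if isinstance(o, frozenset) else str(o)
        return str(o)
    payload = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns a results dict and writes reports + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    results: dict = {"seed": config.seed}
    stage = "setup"
    try:
        # ------------------------------------------------------------ inputs
        stage = "inputs"
        panel_obj = None
        if config.synthetic is not None:
            panel_obj = build_synthetic_plastome(config.synthetic)
            focal = panel_obj.focal
            if config.lesions:
                focal, truth = inject_degradation(focal, config.lesions,
                                                  seed=config.seed)
                truth_path = out / "truth.json"
                truth_path.write_text(json.dumps(truth.events, indent=2) + "\n")
                written.append(truth_path)
                results["truth"] = truth.events
            panel = panel_obj.panel_records()
            for rec in [focal] + panel:
                p = pio.write_genbank(rec, out / f"{rec.id}.gb")
                written.append(p)
        else:
            focal = pio.read_genbank(config.focal_path)
            panel = [pio.read_genbank(p) for p in config.panel_paths]
        reference = panel[0]

        # --------------------------------------------------------- structure
        stage = "structure"
        summaries = []
        for rec in [focal] + panel:
            structure = detect_inverted_repeat(rec.sequence)
            summaries.append(genome_summary(rec, structure))
        df = pd.DataFrame(summaries)
        p = out / "genome_summaries.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
        results["genome_summaries"] = summaries

        # -------------------------------------------------------------- scan
        stage = "scan"
        report = scan_genome(focal, [focal] + panel, config.scan,
                             reference=reference)
        jp, tp = pio.write_report(report, out / "degradation_report")
        written += [jp, tp]
        results["pseudogenes"] = report.flagged()
        results["report"] = report

        hydro_rows = [
            {"gene": g, "focal_fraction": s.hydrophobicity.focal_fraction,
             "ci_low": s.hydrophobicity.ci[0], "ci_high": s.hydrophobicity.ci[1]}
            for g, s in sorted(report.per_gene.items()) if s.hydrophobicity]
        p = out / "hydrophobicity.tsv"
        pd.DataFrame(hydro_rows).to_csv(p, sep="\t", index=False)
        written.append(p)

        # ---------------------------------------------------------- paralogs
        stage = "paralogs"
        paralog_rows = []
        if config.synthetic is not None and results.get("pseudogenes"):
            rng = stream(config.seed, "contigs")
            organellar_cov = float(rng.uniform(100, 2000))
            for gene in results["pseudogenes"]:
                cds = pio.extract_cds(focal, gene)
                contig = ParalogContig(id=f"contig_{gene}", sequence=cds,
                                       kmer_coverage=float(rng.uniform(1, 5)))
                cls = classify_origin(contig, organellar_cov)
                ref_cds = pio.extract_cds(reference, gene)
                try:
                    events = screen_paralog(contig, ref_cds, config=config.scan)
                    kinds = ";".join(sorted({e.kind for e in events}))
                except InsufficientOverlapError as exc:
                    kinds = f"skipped:{exc}"
                paralog_rows.append({"contig": contig.id, "gene": gene,
                                     "coverage": round(contig.kmer_coverage, 2),
                                     "organellar_coverage": round(organellar_cov, 1),
                                     "classification": cls, "events": kinds})
        p = out / "paralogs.tsv"
        pd.DataFrame(paralog_rows).to_csv(p, sep="\t", index=False)
        written.append(p)
        results["paralogs"] = paralog_rows

        # ------------------------------------------------------------- stats
        stage = "stats"
        stats_block = {}
        if panel_obj is not None:
            concat = {}
            for t in [focal.id] + [r.id for r in panel]:
                parts = []
                for gene, rows in sorted(panel_obj.gene_alignments.items()):
                    parts.append(rows[t])
                concat[t] = "".join(parts)
            astats = alignment_stats(concat)
            stats_block["alignment"] = dataclasses.asdict(astats)
            sizes = [r.length for r in panel]
            stats_block["genome_size_p"] = one_tailed_t(
                sizes, focal.length, "panel_mean_greater")
            rng = stream(config.seed, "readfrac")
            fracs = np.clip(rng.normal(config.read_fraction_panel_mean,
                                       config.read_fraction_panel_sd,
                                       size=len(panel)), 0.5, None)
            total = 1_000_000
            focal_counts = {"mapped_to_plastid":
                            int(round(config.read_fraction_focal / 100 * total)),
                            "total_reads": total}
            focal_frac = plastid_read_fraction(focal_counts)
            stats_block["read_fraction_focal"] = focal_frac
            stats_block["read_fraction_panel_mean"] = float(np.mean(fracs))
            stats_block["read_fraction_p"] = one_tailed_t(
                fracs, focal_frac, "panel_mean_greater")
        p = out / "comparative_stats.json"
        p.write_text(json.dumps(stats_block, indent=2, sort_keys=True) + "\n")
        written.append(p)
        results["stats"] = stats_block

        # --------------------------------------------------------- selection
        stage = "selection"
        sel_rows = []
        if panel_obj is not None and results.get("pseudogenes"):
            tree = tree_from_newick(panel_obj.newick)
            ct = compile_tree(tree)
            focal_taxon = config.synthetic.focal_taxon
            from .selection import ancestral_edge_key, tip_edge_key
            fkey, akey = tip_edge_key(ct, focal_taxon), ancestral_edge_key(ct, focal_taxon)
            for gene in results["pseudogenes"]:
                rows = {t: s[:-3] for t, s in panel_obj.gene_alignments[gene].items()
                        if t != focal_taxon}
                focal_cds = _codon_clean_copy(pio.extract_cds(focal, gene),
                                              pio.extract_cds(reference, gene),
                                              config.scan)
                contig = ParalogContig(id=focal_taxon, sequence=focal_cds,
                                       kmer_coverage=0.0)
                matrix = prep_gene_matrix(rows, [contig], min_remaining=200,
                                          config=config.scan)
                aln = build_codon_alignment(matrix, min_remaining=200)
                fit_f, fit_c = fit_lrt_pair(aln, ct, focal_taxon,
                                            n_starts=config.selection_n_starts,
                                            seed=config.seed)
                res = lrt(fit_f, fit_c)
                sel_rows.append({"gene": gene,
                                 "omega_focal": fit_f.params.omegas[fkey],
                                 "omega_ancestral": fit_f.params.omegas[akey],
                                 "lnL_full": fit_f.logL,
                                 "lnL_constrained": fit_c.logL,
                                 "LRT": res.statistic, "p": res.p})
            adj = hochberg_adjust([r["p"] for r in sel_rows])
            for r, a in zip(sel_rows, adj):
                r["p_hochberg"] = a
        p = out / "selection.tsv"
        pd.DataFrame(sel_rows).to_csv(p, sep="\t", index=False,
                                      float_format="%.6g")
        written.append(p)
        results["selection"] = sel_rows

        # ---------------------------------------------------------- manifest
        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "outputs": {pth.name: _sha256(pth) for pth in sorted(written)},
        }
        if config.focal_path:
            manifest["inputs"] = {str(pp): _sha256(Path(pp))
                                  for pp in [config.focal_path] + list(config.panel_paths)}
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        results["manifest"] = manifest
        return results
    except Exception as exc:
        for pth in written:
            try:
                pth.unlink()
            except OSError:
                pass
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def verify_manifest(out_dir: Path) -> bool:
    """Re-checksum every manifest-listed output; True iff all match."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return all(_sha256(out / name) == digest
               for name, digest in manifest["outputs"].items())
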