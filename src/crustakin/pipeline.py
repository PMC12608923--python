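"""Orchestrates curate -> tree QC -> motifs -> classify -> identsim -> report.

Each stage writes a flat TSV artifact plus one JSON run summary; output
ordering is sorted by sequence id throughout, so re-running with identical
inputs and configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .classify import NameRegistry, ReferencePanel, assign_decapod_name, classify_record
from .core_io import (
    DomainAnnotation, SequenceRecord, read_domain_table, read_fasta,
    read_hit_table, read_newick, write_tsv,
)
from .curation import (
    FilterConfig, filter_crustome_hits, filter_domain_completeness,
    filter_reference_hits, flag_long_branches, flag_taxon_inconsistency,
)
from .identsim import AlignParams, SimilarityScheme, identsim_matrix
from .motifs import STANDARD_PATTERNS, motif_report

logger = logging.getLogger("crustakin")


@dataclass
class PipelineConfig:
    fasta: str
    domains: str | None = None
    hits: str | None = None
    tree: str | None = None
    taxa: str | None = None
    panel: str | None = None
    mode: str = "crustome"                 # reference | crustome
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    align_params: AlignParams = field(default_factory=AlignParams)
    scheme: SimilarityScheme = field(default_factory=SimilarityScheme)
    denominator: str = "alignment"
    tree_k: float = 5.0
    tree_m: int = 5
    min_complete_domains: int = 0          # extra completeness gate (R/PKC: 2)
    run_identsim: bool = False             # all-pairs matrix is O(n^2)
    outdir: str = "crustakin_out"
    seed: int = 0

    def validate(self) -> None:
        for label, path in (("fasta", self.fasta), ("domains", self.domains),
                            ("hits", self.hits), ("tree", self.tree),
                            ("taxa", self.taxa), ("panel", self.panel)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label} path does not exist: {path}")
        if self.mode not in ("reference", "crustome"):
            raise ValueError("mode must be 'reference' or 'crustome'")


@dataclass
class RunSummary:
    counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "counts": self.counts,
             "stage_seconds": self.stage_seconds, "skipped": self.skipped,
             "config": self.config_echo},
            indent=2, sort_keys=True)


def read_taxa_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id, phylum) with optional header row."""
    taxa: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or (i == 0 and fields[0] in ("id", "seq_id", "tip")):
                continue
            taxa[fields[0]] = fields[1]
    return taxa


def tally_by_taxon(
    classifications: Sequence, taxon_map: Mapping[str, str],
) -> dict[str, dict[str, int]]:
    """Phylum x family contingency table with row/column totals.

    Ids missing from the taxon map are counted under 'unknown' with a
    logged warning. ``classifications`` is a sequence of
    ClassificationResult (or anything with .seq_id and .family).
    """
    table: dict[str, dict[str, int]] = {}
    for result in classifications:
        phylum = taxon_map.get(result.seq_id)
        if phylum is None:
            logger.warning("no taxon for %s; counted as unknown", result.seq_id)
            phylum = "unknown"
        row = table.setdefault(phylum, {})
        row[result.family] = row.get(result.family, 0) + 1
    families = sorted({f for row in table.values() for f in row})
    for row in table.values():
        row["total"] = sum(row.get(f, 0) for f in families)
    totals = {f: sum(row.get(f, 0) for row in table.values())
              for f in families}
    totals["total"] = sum(totals.values())
    table["total"] = totals
    return table


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> RunSummary:
    """Execute the configured stages in order, writing per-stage TSVs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(config_echo={
        "mode": config.mode, "denominator": config.denominator,
        "tree_k": config.tree_k, "tree_m": config.tree_m,
        "seed": config.seed,
    })

    def stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s started", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                summary.stage_seconds[name] = round(
                    time.perf_counter() - self_inner.t0, 3)
                if exc is not None:
                    raise StageFailure(name, exc) from exc
        return _Timer()

    with stage("load"):
        records = sorted(read_fasta(config.fasta), key=lambda r: r.id)
        by_id = {r.id: r for r in records}
        domains = (read_domain_table(config.domains, records)
                   if config.domains else [])
        summary.counts["input"] = len(records)

    with stage("curate"):
        kept_ids = {r.id for r in records}
        rejected_rows = []
        if config.hits:
            hits = read_hit_table(config.hits)
            if config.mode == "reference":
                report = filter_reference_hits(hits, domains,
                                               config.filter_config)
            else:
                report = filter_crustome_hits(hits, config.filter_config)
            kept_ids &= set(report.kept) | (kept_ids - report.all_ids())
            for seq_id, reason, detail in report.rejected:
                if seq_id in by_id:
                    kept_ids.discard(seq_id)
                    rejected_rows.append((seq_id, reason, detail))
                    logger.info("rejected %s: %s (%s)", seq_id, reason, detail)
        if config.min_complete_domains > 0:
            sub = [r for r in records if r.id in kept_ids]
            report = filter_domain_completeness(
                sub, domains, config.min_complete_domains)
            for seq_id, reason, detail in report.rejected:
                kept_ids.discard(seq_id)
                rejected_rows.append((seq_id, reason, detail))
                logger.info("rejected %s: %s (%s)", seq_id, reason, detail)
        write_tsv(sorted(rejected_rows), outdir / "qc_rejected.tsv",
                  header=("seq_id", "reason", "detail"))
        summary.counts["kept"] = len(kept_ids)
        summary.counts["rejected"] = len(rejected_rows)

    if config.tree and config.taxa:
        with stage("tree_qc"):
            tree = read_newick(config.tree)
            taxa = read_taxa_table(config.taxa)
            long_flags = flag_long_branches(tree, k=config.tree_k)
            taxon_flags = flag_taxon_inconsistency(tree, taxa, m=config.tree_m)
            write_tsv(
                [(t, f"{l:.6f}", f"{thr:.6f}") for t, l, thr in long_flags],
                outdir / "tree_long_branches.tsv",
                header=("tip", "length", "threshold"))
            write_tsv(
                [(t, own, ",".join(nb)) for t, own, nb in taxon_flags],
                outdir / "tree_taxon_flags.tsv",
                header=("tip", "phylum", "neighbor_phyla"))
            summary.counts["long_branch_flags"] = len(long_flags)
            summary.counts["taxon_flags"] = len(taxon_flags)
    else:
        summary.skipped.append("tree_qc")
        logger.warning("tree/taxa not supplied; tree QC skipped")

    kept = [r for r in records if r.id in kept_ids]

    with stage("motifs"):
        rows = []
        for rec in kept:
            rep = motif_report(rec, domains)
            rows.append([rec.id]
                        + [rep[p] if rep[p] is not None else "-"
                           for p in STANDARD_PATTERNS]
                        + ["yes" if rep["G2"] else "no"])
        write_tsv(rows, outdir / "motif_report.tsv",
                  header=("seq_id", *STANDARD_PATTERNS, "G2"))

    with stage("classify"):
        panel = None
        if config.panel:
            panel_records = read_fasta(config.panel, source="reference")
            exemplars = [(r, r.species) for r in panel_records]
            panel = ReferencePanel(exemplars)
        registry = NameRegistry()
        results = []
        class_counts: dict[str, int] = {}
        for rec in kept:
            anns = [a for a in domains if a.seq_id == rec.id]
            if not anns:
                continue
            result = classify_record(rec, anns, panel, config.align_params,
                                     config.scheme)
            if result.family != "unknown":
                assign_decapod_name(result, rec.species, registry)
            results.append(result)
            key = (f"{result.family}/{result.subtype}" if result.subtype
                   else result.family)
            class_counts[key] = class_counts.get(key, 0) + 1
        write_tsv(
            [(r.seq_id, r.family, r.subtype, r.decapod_name or "-",
              r.confidence,
              ";".join(f"{c}={o}" for c, o in r.evidence))
             for r in results],
            outdir / "classifications.tsv",
            header=("seq_id", "family", "subtype", "decapod_name",
                    "confidence", "evidence"))
        summary.counts["classified"] = dict(sorted(class_counts.items()))
        taxon_map = {r.id: r.phylum for r in kept}
        tally = tally_by_taxon(results, taxon_map)
        with open(outdir / "taxon_tally.json", "w", encoding="utf-8") as fh:
            json.dump(tally, fh, indent=2, sort_keys=True)

    if config.run_identsim and len(kept) >= 2:
        with stage("identsim"):
            matrix = identsim_matrix(kept, config.align_params,
                                     config.scheme, config.denominator)
            write_tsv(matrix.to_table(), outdir / "identsim_matrix.tsv")
    elif config.run_identsim:
        summary.skipped.append("identsim")

    with open(outdir / "run_summary.json", "w", encoding="utf-8") as fh:
        fh.write(summary.to_json() + "\n")
    return summary
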