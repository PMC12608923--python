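"""Dataset construction and refinement filters.

Two stages of homolog curation are modelled:

* reference curation — BLASTp hits against characterized (mostly chordate)
  reference proteins are kept only with E-value <= 1e-70, percent identity
  strictly above 60, and at least one complete conserved domain;
* transcriptome (CrusTome) curation — hits are kept with E-value <= 1e-120,
  with no identity or domain condition at that stage.

Regulatory-subunit and PKC candidates are additionally required to carry at
least two complete conserved domains, which removes other cAMP-binding
proteins and kinases that share a single domain.

Contamination screening operates on an inferred tree: terminal branches far
longer than the rest of the tree (putative artifacts or contaminants) and
tips whose nearest neighbours by patristic distance are dominated by a
foreign phylum (e.g. an arthropod-labelled sequence sitting inside a
nematode neighbourhood) are flagged for manual follow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .core_io import DomainAnnotation, HomologyHit, SequenceRecord

REASON_CODES = ("evalue", "identity", "domain_count", "long_branch",
                "taxon_inconsistent")


@dataclass
class FilterConfig:
    """Thresholds for the two curation stages."""

    reference_max_evalue: float = 1e-70
    reference_min_identity: float = 60.0
    reference_min_domains: int = 1
    crustome_max_evalue: float = 1e-120
    min_complete_domains_r_pkc: int = 2

    def __post_init__(self) -> None:
        if self.reference_max_evalue <= 0 or self.crustome_max_evalue <= 0:
            raise ValueError("evalue thresholds must be > 0")
        if not 0 <= self.reference_min_identity <= 100:
            raise ValueError("identity threshold must lie in [0, 100]")


@dataclass
class QCReport:
    """Kept ids plus rejected (id, reason-code, detail) triples.

    Kept and rejected ids partition the input set exactly.
    """

    kept: list[str] = field(default_factory=list)
    rejected: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def rejected_ids(self) -> list[str]:
        return [r[0] for r in self.rejected]

    def all_ids(self) -> set[str]:
        return set(self.kept) | set(self.rejected_ids)


def _best_hits(hits: Sequence[HomologyHit]) -> dict[str, tuple[float, float]]:
    """Per subject: (min evalue, max percent identity) over all its hits."""
    best: dict[str, tuple[float, float]] = {}
    for h in hits:
        ev, ident = best.get(h.subject_id, (math.inf, -math.inf))
        best[h.subject_id] = (min(ev, h.evalue), max(ident, h.percent_identity))
    return best


def _complete_domain_counts(
    domains: Sequence[DomainAnnotation],
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for d in domains:
        if d.complete:
            counts[d.seq_id] = counts.get(d.seq_id, 0) + 1
    return counts


def filter_reference_hits(
    hits: Sequence[HomologyHit],
    domains: Sequence[DomainAnnotation],
    cfg: FilterConfig | None = None,
) -> QCReport:
    """Reference-stage filter: E-value, identity, and domain completeness.

    A subject is kept iff its best (minimum) E-value is <= the threshold,
    its best (maximum) percent identity is strictly above the identity
    threshold, and it carries at least ``reference_min_domains`` complete
    conserved-domain annotations. Subjects with hits but no annotations are
    rejected with reason ``domain_count``.
    """
    cfg = cfg or FilterConfig()
    best = _best_hits(hits)
    counts = _complete_domain_counts(domains)
    report = QCReport()
    for subject in sorted(best):
        evalue, identity = best[subject]
        if evalue > cfg.reference_max_evalue:
            report.rejected.append(
                (subject, "evalue",
                 f"best evalue {evalue:g} > {cfg.reference_max_evalue:g}"))
        elif identity <= cfg.reference_min_identity:
            report.rejected.append(
                (subject, "identity",
                 f"best identity {identity:g} not above "
                 f"{cfg.reference_min_identity:g}"))
        elif counts.get(subject, 0) < cfg.reference_min_domains:
            detail = ("no annotations" if subject not in counts else
                      f"{counts[subject]} complete domain(s) < "
                      f"{cfg.reference_min_domains}")
            report.rejected.append((subject, "domain_count", detail))
        else:
            report.kept.append(subject)
    return report


def filter_crustome_hits(
    hits: Sequence[HomologyHit],
    cfg: FilterConfig | None = None,
) -> QCReport:
    """Transcriptome-stage filter: best E-value <= threshold (inclusive)."""
    cfg = cfg or FilterConfig()
    best = _best_hits(hits)
    report = QCReport()
    for subject in sorted(best):
        evalue, _ = best[subject]
        if evalue <= cfg.crustome_max_evalue:
            report.kept.append(subject)
        else:
            report.rejected.append(
                (subject, "evalue",
                 f"best evalue {evalue:g} > {cfg.crustome_max_evalue:g}"))
    return report


def filter_domain_completeness(
    records: Sequence[SequenceRecord],
    domains: Sequence[DomainAnnotation],
    min_domains: int,
) -> QCReport:
    """Keep records with >= min_domains complete conserved domains.

    Applied with min_domains=2 to regulatory-subunit and PKC candidates to
    exclude unrelated proteins that share a single conserved domain.
    """
    if min_domains < 0:
        raise ValueError("min_domains must be >= 0")
    counts = _complete_domain_counts(domains)
    report = QCReport()
    for rec in sorted(records, key=lambda r: r.id):
        n = counts.get(rec.id, 0)
        if n >= min_domains:
            report.kept.append(rec.id)
        else:
            report.rejected.append(
                (rec.id, "domain_count",
                 f"{n} complete domain(s) < {min_domains}"))
    return report


# ---------------------------------------------------------------------------
# Tree-based contamination screening

def _terminal_lengths(tree: dendropy.Tree) -> dict[str, float]:
    return {
        leaf.taxon.label: (leaf.edge.length or 0.0)
        for leaf in tree.leaf_node_iter()
    }


def flag_long_branches(
    tree: dendropy.Tree, k: float = 5.0, min_tips: int = 10,
) -> list[tuple[str, float, float]]:
    """Flag tips whose terminal branch is an extreme length outlier.

    A tip is flagged only when its terminal branch length exceeds BOTH
    ``k`` x median(terminal lengths) and the Tukey upper fence
    (Q3 + 1.5 IQR); the conjunction avoids flagging in trees whose branches
    are uniformly long. Returns (tip_id, length, threshold) sorted by
    length descending.
    """
    lengths = _terminal_lengths(tree)
    if len(lengths) < min_tips:
        raise ValueError(
            f"tree has {len(lengths)} tips < min_tips={min_tips}; "
            "too few terminal branches to estimate a null spread — review "
            "manually"
        )
    values = np.array(list(lengths.values()))
    median = float(np.median(values))
    q1, q3 = (float(q) for q in np.percentile(values, [25, 75]))
    fence = q3 + 1.5 * (q3 - q1)
    threshold = max(k * median, fence)
    flags = [
        (tip, length, threshold)
        for tip, length in lengths.items()
        if length > k * median and length > fence
    ]
    flags.sort(key=lambda t: (-t[1], t[0]))
    return flags


def patristic_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and the symmetric matrix of tip-to-tip path lengths."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return labels, mat


def flag_taxon_inconsistency(
    tree: dendropy.Tree,
    taxon_map: Mapping[str, str],
    m: int = 5,
) -> list[tuple[str, str, list[str]]]:
    """Flag tips whose m nearest tips (patristic) mostly have a foreign phylum.

    A tip is flagged when fewer than 2 of its ``m`` nearest other tips share
    its phylum. Distance ties are broken by tip-id lexicographic order. With
    m=1 at most one neighbour can match, so every tip is flagged — a
    documented degenerate setting; m >= 3 is recommended.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    labels, mat = patristic_matrix(tree)
    for tip in labels:
        if tip not in taxon_map:
            raise KeyError(f"tip {tip!r} missing from taxon map")
    flags: list[tuple[str, str, list[str]]] = []
    for i, tip in enumerate(labels):
        order = sorted(
            (j for j in range(len(labels)) if j != i),
            key=lambda j: (mat[i, j], labels[j]),
        )
        neighbours = [labels[j] for j in order[:m]]
        neighbour_phyla = [taxon_map[t] for t in neighbours]
        if sum(p == taxon_map[tip] for p in neighbour_phyla) < 2:
            flags.append((tip, taxon_map[tip], neighbour_phyla))
    return flags


# ---------------------------------------------------------------------------
# Alignment-trimming plumbing

def trim_gap_columns(alignment, max_gap_frac: float = 0.9):
    """Drop alignment columns whose gap fraction exceeds ``max_gap_frac``.

    Plain gap-fraction trimmer provided as plumbing for post-alignment
    cleanup; returns a new Alignment with the surviving columns.
    """
    from .core_io import Alignment

    if not 0 <= max_gap_frac <= 1:
        raise ValueError("max_gap_frac must lie in [0, 1]")
    if not alignment.rows:
        return Alignment(ids=[], rows=[])
    nrow = len(alignment.rows)
    keep = [
        c for c in range(alignment.n_columns)
        if sum(row[c] == "-" for row in alignment.rows) / nrow <= max_gap_frac
    ]
    return Alignment(
        ids=list(alignment.ids),
        rows=["".join(row[c] for c in keep) for row in alignment.rows],
    )
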