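"""Family, subtype, and decapod-name assignment for PKA/PKC sequences.

Family calling is rule-based on domain architecture:

* PKA-R   — two or more cAMP-binding domains (the docking domain is
  optional; truncated subunits lacking one are recorded in the evidence);
* PKN     — at least one HR1 repeat plus a kinase domain;
* aPKC    — PB1 + a single C1 + kinase;
* cPKC    — C1 + C2 + kinase with C1 preceding C2;
* nPKC    — C2 preceding C1 + kinase (delta-like vs epsilon-like resolved
  against a reference panel by grouped similarity);
* PKA-C   — a kinase domain with no regulatory domains, supported by
  N-terminal evidence (the MGN start, the MATL motif, the FxxxW anchor, or
  a glycine-rich N-terminus).

Subtype calling layers the N-terminal motif evidence on top, and decapod
names are issued per species in order of characterization (cPKC_D1,
nPKC_D1δ, PKA-C_GLY2, PKN_D3, ...). Chordate isozyme names (Cα/Cβ, RIα,
PKCδ, ...) are never assigned to non-chordate inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .core_io import DomainAnnotation, SequenceRecord
from .identsim import AlignParams, SimilarityScheme, global_align, ident_sim
from .motifs import (
    classify_ai_site, compile_motif, find_motif, is_gly_rich_nterm,
    linker_region, motif_report, nterm_region,
)

FAMILIES = ("PKA-C", "PKA-R", "cPKC", "nPKC-delta-like", "nPKC-epsilon-like",
            "aPKC", "PKN", "unknown")

_MGN_ANY = compile_motif("MGNxxxx[K/R]", anchored=True)
_MGN_INV = compile_motif("MGNxxxxK", anchored=True)
_MATL = compile_motif("MATL[M/T/A]A[F/T]")
_FXXXW = compile_motif("FxxxW")

REGULATORY_DOMAINS = ("cAMP_binding", "DD", "C1", "C2", "PB1", "HR1", "PH")


@dataclass
class ClassificationResult:
    seq_id: str
    family: str = "unknown"
    subtype: str = ""
    decapod_name: str | None = None
    evidence: list[tuple[str, str]] = field(default_factory=list)
    confidence: str = "architecture_only"

    def note(self, check: str, outcome: str) -> None:
        self.evidence.append((check, outcome))


@dataclass
class ReferencePanel:
    """Labelled exemplar sequences used for similarity-based resolution."""

    exemplars: list[tuple[SequenceRecord, str]]

    def __post_init__(self) -> None:
        if not self.exemplars:
            raise ValueError("reference panel is empty")

    @property
    def labels(self) -> set[str]:
        return {label for _, label in self.exemplars}


def _check_overlaps(anns: Sequence[DomainAnnotation]) -> None:
    """Reject annotation sets with heavily overlapping conflicting domains."""
    for i, a in enumerate(anns):
        for b in anns[i + 1:]:
            if a.domain_name == b.domain_name:
                continue
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi < lo:
                continue
            overlap = hi - lo + 1
            if overlap > 0.5 * min(a.length, b.length):
                raise ValueError(
                    f"{a.seq_id}: contradictory annotations "
                    f"{a.domain_name}@{a.start}-{a.end} vs "
                    f"{b.domain_name}@{b.start}-{b.end} share >50% span")


def _pka_c_evidence(
    record: SequenceRecord, anns: Sequence[DomainAnnotation],
) -> list[tuple[str, str]]:
    """N-terminal evidence supporting a PKA catalytic-subunit call."""
    evidence: list[tuple[str, str]] = []
    if find_motif(record, _MGN_ANY):
        evidence.append(("MGNxxxx[K/R]", "present at 1"))
    start, end, empty = nterm_region(record, anns)
    if not empty:
        if find_motif(record, _MATL, region=(start, end)):
            evidence.append(("MATL[M/T/A]A[F/T]", "present in N-terminal region"))
        if find_motif(record, _FXXXW, region=(start, end)):
            evidence.append(("FxxxW", "present in N-terminal region"))
        if is_gly_rich_nterm(record, anns):
            evidence.append(("gly-rich N-terminus", "present"))
    return evidence


def classify_family(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation],
) -> ClassificationResult:
    """Apply the architecture rule table to one annotated sequence."""
    anns = sorted(
        (a for a in annotations if a.seq_id == record.id),
        key=lambda a: (a.start, a.end, a.domain_name),
    )
    if not anns:
        raise ValueError(f"{record.id}: no domain annotations")
    _check_overlaps(anns)
    names = [a.domain_name for a in anns]
    counts = {n: names.count(n) for n in set(names)}
    result = ClassificationResult(seq_id=record.id)

    def first_start(domain: str) -> int:
        return min(a.start for a in anns if a.domain_name == domain)

    has_kinase = counts.get("kinase", 0) >= 1
    if counts.get("cAMP_binding", 0) >= 2:
        result.family = "PKA-R"
        result.note("architecture", f"{counts['cAMP_binding']} cAMP_binding domains")
        if counts.get("DD", 0) == 0:
            result.note("DD", "no identifiable dimerization domain")
    elif counts.get("HR1", 0) >= 1 and has_kinase:
        result.family = "PKN"
        result.note("architecture", f"{counts['HR1']} HR1 repeat(s) + kinase")
    elif counts.get("PB1", 0) >= 1 and counts.get("C1", 0) == 1 and has_kinase:
        result.family = "aPKC"
        result.note("architecture", "PB1 + single C1 + kinase")
    elif counts.get("C1", 0) >= 1 and counts.get("C2", 0) >= 1 and has_kinase:
        if first_start("C1") < first_start("C2"):
            result.family = "cPKC"
            result.note("architecture", "C1 preceding C2 + kinase")
        else:
            result.family = "nPKC"  # delta-like vs epsilon-like via panel
            result.note("architecture", "C2 preceding C1 + kinase")
    elif has_kinase and not any(counts.get(d, 0) for d in REGULATORY_DOMAINS):
        evidence = _pka_c_evidence(record, anns)
        if evidence:
            result.family = "PKA-C"
            result.note("architecture", "kinase only")
            result.evidence.extend(evidence)
        else:
            result.note("architecture",
                        "kinase only, no N-terminal PKA evidence")
    else:
        result.note("architecture", "no rule matched: " + ",".join(names))
    return result


def classify_pka_c_isoform(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation],
    report: Mapping[str, object] | None = None,
    gly_status: bool | None = None,
) -> str:
    """Subtype a PKA catalytic subunit: C_GLY > C_D1 > C_1 > other-arthropod.

    A glycine tract is the rarest, most specific signal, so it takes
    priority when several checks fire.
    """
    report = report if report is not None else motif_report(record, annotations)
    if gly_status is None:
        gly_status = is_gly_rich_nterm(record, annotations)
    if gly_status:
        return "C_GLY"
    if report.get("MATL[M/T/A]A[F/T]") is not None:
        return "C_D1"
    if (report.get("MGNxxxxK") is not None
            or report.get("MGNxxxx[K/R]") is not None):
        return "C_1"
    return "other-arthropod"


def classify_pka_r(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation],
    result: ClassificationResult | None = None,
    gly_status: bool | None = None,
) -> str:
    """Subtype a regulatory subunit from its autoinhibitory-site motif.

    RI (pseudosubstrate RRx[A/G]) vs RII (phosphorylatable RRxS); RII with
    a glycine-rich N-terminus becomes RII_GLY; both motifs present yields
    'R-unresolved' with both positions recorded in the evidence.
    """
    linker = linker_region(record, annotations)
    ai = classify_ai_site(record, linker)
    if gly_status is None:
        gly_status = is_gly_rich_nterm(record, annotations)
    if result is not None:
        if linker is None:
            result.note("AI-site", "no linker delimited; whole-sequence scan")
        result.note("AI-site", ai)
    if ai == "ambiguous":
        if result is not None:
            ri = find_motif(record, "RRx[A/G]", region=linker)
            rii = find_motif(record, "RRxS", region=linker)
            result.note("RRx[A/G]", f"at {ri[0].start}")
            result.note("RRxS", f"at {rii[0].start}")
        return "R-unresolved"
    if ai == "RII":
        return "RII_GLY" if gly_status else "RII"
    if ai == "RI":
        return "RI"
    return "R-unresolved"


def nearest_reference(
    record: SequenceRecord,
    panel: ReferencePanel,
    params: AlignParams | None = None,
    scheme: SimilarityScheme | None = None,
) -> tuple[str, float, float]:
    """Label of the panel exemplar with maximal grouped similarity.

    Ties broken by maximal identity, then lexicographic exemplar id; a tie
    that reaches the id tie-break is still deterministic.
    """
    best: tuple[float, float, str, str] | None = None
    for exemplar, label in panel.exemplars:
        aln = global_align(record, exemplar, params)
        ident, sim = ident_sim(aln, scheme)
        key = (-sim, -ident, exemplar.id)
        if best is None or key < best[:3]:
            best = (*key, label)
    assert best is not None
    return best[3], -best[1], -best[0]


@dataclass
class NameRegistry:
    """Tracks decapod names already issued per (species, class) pair."""

    issued: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def next_ordinal(self, species: str, class_key: str) -> int:
        return 1 + len(self.issued.get((species, class_key), []))

    def register(self, species: str, class_key: str, name: str) -> None:
        names = self.issued.setdefault((species, class_key), [])
        if name in names:
            raise ValueError(
                f"duplicate decapod name {name!r} for species {species!r}")
        names.append(name)


def assign_decapod_name(
    result: ClassificationResult,
    species: str,
    registry: NameRegistry,
) -> str:
    """Issue the next decapod name for this family/subtype within a species.

    Ordinals count previously registered isoforms of the same class for the
    species, so names are deterministic given input order (an order-of-
    characterization convention, not a biological claim).
    """
    family, subtype = result.family, result.subtype
    if family == "unknown":
        raise ValueError(f"{result.seq_id}: cannot name an unknown family")
    if family == "PKA-C":
        key = f"PKA-C/{subtype or 'other'}"
        n = registry.next_ordinal(species, key)
        if subtype == "C_GLY":
            name = f"PKA-C_GLY{n}"
        elif subtype == "C_D1":
            name = f"PKA-C_D{n}"
        elif subtype == "C_1":
            name = "PKA-C_1" if n == 1 else f"PKA-C_1.{n}"
        else:
            name = f"PKA-C_A{n}"
    elif family == "PKA-R":
        key = f"PKA-R/{subtype}"
        n = registry.next_ordinal(species, key)
        if subtype == "RII_GLY":
            name = "PKA-RII_GLY" if n == 1 else f"PKA-RII_GLY{n}"
        elif subtype == "RII":
            name = f"PKA-RII_D{n}"
        elif subtype.startswith("RI"):
            name = "PKA-RI_1" if n == 1 else f"PKA-RI_D{n - 1}"
        else:
            name = f"PKA-R_U{n}"
    elif family == "cPKC":
        n = registry.next_ordinal(species, "cPKC")
        key, name = "cPKC", f"cPKC_D{n}"
    elif family == "nPKC":
        # unresolved novel PKC (no reference panel): greek suffix omitted
        n = registry.next_ordinal(species, "nPKC")
        key, name = "nPKC", f"nPKC_D{n}"
    elif family == "nPKC-delta-like":
        n = registry.next_ordinal(species, "nPKC-delta")
        key, name = "nPKC-delta", f"nPKC_D{n}δ"
    elif family == "nPKC-epsilon-like":
        n = registry.next_ordinal(species, "nPKC-epsilon")
        key, name = "nPKC-epsilon", f"nPKC_D{n}ε"
    elif family == "aPKC":
        n = registry.next_ordinal(species, "aPKC")
        key, name = "aPKC", f"aPKC_D{n}"
    elif family == "PKN":
        n = registry.next_ordinal(species, "PKN")
        key, name = "PKN", f"PKN_D{n}"
    else:
        raise ValueError(f"unhandled family {family!r}")
    registry.register(species, key, name)
    result.decapod_name = name
    return name


def classify_record(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation],
    panel: ReferencePanel | None = None,
    params: AlignParams | None = None,
    scheme: SimilarityScheme | None = None,
) -> ClassificationResult:
    """Full per-sequence classification: family, then subtype.

    nPKC delta-like vs epsilon-like is resolved against the panel when one
    is supplied; without a panel the family stays the generic 'nPKC' with
    architecture-only confidence.
    """
    result = classify_family(record, annotations)
    if result.family == "PKA-C":
        gly = is_gly_rich_nterm(record, annotations)
        result.subtype = classify_pka_c_isoform(
            record, annotations, gly_status=gly)
        result.confidence = "architecture+motif"
        result.note("subtype", result.subtype)
    elif result.family == "PKA-R":
        result.subtype = classify_pka_r(record, annotations, result)
        result.confidence = "architecture+motif"
    elif result.family == "nPKC":
        if panel is not None:
            npkc = [(rec, lab) for rec, lab in panel.exemplars
                    if lab in ("nPKC-delta-like", "nPKC-epsilon-like")]
            if npkc:
                label, ident, sim = nearest_reference(
                    record, ReferencePanel(npkc), params, scheme)
                result.family = label
                result.confidence = "nearest_reference_only"
                result.note("nearest_reference",
                            f"{label} ({ident:.1f}/{sim:.1f})")
    return result
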