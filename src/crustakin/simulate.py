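"""Synthetic PKA/PKC datasets with planted ground truth.

The generator emulates the structure the analysis assumes so every stage is
testable offline:

* class-specific N-terminal signatures (the MGN start of ancestral
  catalytic subunits, the decapod MATL motif, the FxxxW anchor, the RI/RII
  autoinhibitory motifs, glycine-rich tracts);
* subfamily-specific domain architectures at roughly the proportions seen
  in full-length sequences (catalytic subunit ~350 aa with a C-terminal
  kinase domain; PKN ~900 aa with three N-terminal HR1 repeats; ...);
* a catalytic core that is identical across PKA-C isoforms of one species
  (the isoforms differ only N-terminally), mutated between species;
* point-mutation divergence between taxa, with planted motif literals and
  domain-boundary neighbourhoods excluded from mutation so the truth table
  stays exact;
* homology-hit tables with planted keep/reject E-value bands; and
* trees carrying planted long-branch and mislabeled-taxon contaminants.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Sequence

import dendropy

from .core_io import DomainAnnotation, HomologyHit, SequenceRecord, parse_newick
from .motifs import compile_motif, find_motif

# rough metazoan proteome residue frequencies; used for filler and for
# substitution proposals
_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_WEIGHTS = [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
               1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]

_TEMPLATE_SEED = 20251030  # class templates are fixed, independent of SimSpec

DEFAULT_CLASSES = (
    "PKA-C_1", "PKA-C_GLY", "PKA-C_D1", "PKA-RI", "PKA-RII_GLY",
    "cPKC", "nPKC-delta-like", "nPKC-epsilon-like", "aPKC", "PKN",
)

FAMILY_OF_CLASS = {
    "PKA-C_1": "PKA-C", "PKA-C_GLY": "PKA-C", "PKA-C_D1": "PKA-C",
    "PKA-RI": "PKA-R", "PKA-RII_GLY": "PKA-R",
    "cPKC": "cPKC", "nPKC-delta-like": "nPKC-delta-like",
    "nPKC-epsilon-like": "nPKC-epsilon-like", "aPKC": "aPKC", "PKN": "PKN",
}

SUBTYPE_OF_CLASS = {
    "PKA-C_1": "C_1", "PKA-C_GLY": "C_GLY", "PKA-C_D1": "C_D1",
    "PKA-RI": "RI", "PKA-RII_GLY": "RII_GLY",
}

_FORBIDDEN_CHECKS = {
    # patterns that must NOT occur in a finished template (anchored start
    # motifs are checked at position 1 only by nature of anchoring)
    "PKA-C_1": ("MATL[M/T/A]A[F/T]",),
    "PKA-C_GLY": ("MATL[M/T/A]A[F/T]",),
    "PKA-C_D1": (),
    "PKA-RI": ("RRxS",),
    "PKA-RII_GLY": ("RRx[A/G]",),
}


@dataclass
class ClassTemplate:
    """A finished class template with planted features and protections."""

    label: str
    residues: str
    domains: list[tuple[str, int, int]]          # (name, start, end) 1-based
    planted_motifs: dict[str, tuple[int, int]]   # pattern -> (start, end)
    protected_sub: set[int]                      # 0-based, no substitutions
    protected_indel: set[int]                    # 0-based, no indels
    gly_span: tuple[int, int] | None = None      # 1-based inclusive
    core_start: int | None = None                # 0-based start of shared core


@dataclass
class SimSpec:
    """Study conditions for one synthetic dataset."""

    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_species: int = 20
    seqs_per_class: int = 1
    mu: float = 0.05
    indel_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 0.3:
            raise ValueError(
                f"substitution rate mu={self.mu} outside [0, 0.3]; planted "
                "motifs cannot be preserved at higher rates — lower mu")
        if not 0 <= self.indel_rate <= 0.05:
            raise ValueError("indel_rate outside [0, 0.05]")
        unknown = set(self.classes) - set(DEFAULT_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")


@dataclass
class TruthRecord:
    seq_id: str
    class_label: str
    family: str
    subtype: str
    species: str
    planted_motifs: dict[str, tuple[int, int]]
    gly_span: tuple[int, int] | None


def _draw(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_AA, weights=_AA_WEIGHTS, k=n))


def _filler_avoiding(rng: random.Random, n: int, forbidden: Sequence[str],
                     context: str = "", max_tries: int = 200) -> str:
    """Random filler such that context+filler contains none of the patterns."""
    compiled = [compile_motif(p) for p in forbidden]
    for _ in range(max_tries):
        cand = _draw(rng, n)
        probe = SequenceRecord(id="probe", residues=(context + cand) or "A")
        if not any(find_motif(probe, m) for m in compiled):
            return cand
    raise RuntimeError("could not draw filler avoiding forbidden motifs")


def _gly_tract(rng: random.Random, n: int, frac: float = 0.76) -> str:
    out = []
    for _ in range(n):
        out.append("G" if rng.random() < frac else rng.choice("SAN"))
    return "".join(out)


def _span_positions(start: int, end: int) -> set[int]:
    """0-based positions of a 1-based inclusive span."""
    return set(range(start - 1, end))


def _literal_positions(pattern: str, start: int) -> set[int]:
    """0-based positions of non-wildcard motif positions planted at start."""
    motif = compile_motif(pattern)
    out = set()
    for offset, allowed in enumerate(motif.compiled):
        if len(allowed) < 20:
            out.add(start - 1 + offset)
    return out


def _boundary_zone(domains: Sequence[tuple[str, int, int]]) -> set[int]:
    zone: set[int] = set()
    for _, start, end in domains:
        zone |= set(range(max(0, start - 4), start + 3))
        zone |= set(range(max(0, end - 4), end + 3))
    return zone


def _assemble(label: str, nterm: str, core: str,
              core_domains: list[tuple[str, int, int]],
              planted: dict[str, tuple[int, int]],
              gly_span: tuple[int, int] | None,
              shared_core: bool) -> ClassTemplate:
    """Glue an N-terminal part onto a core whose domains are core-relative."""
    offset = len(nterm)
    residues = nterm + core
    domains = [(name, s + offset, e + offset) for name, s, e in core_domains]
    protected_sub: set[int] = set()
    for pattern, (s, _e) in planted.items():
        protected_sub |= _literal_positions(pattern, s)
    protected_indel = set(protected_sub)
    for pattern, (s, e) in planted.items():
        protected_indel |= _span_positions(s, e)
    if gly_span:
        protected_sub |= _span_positions(*gly_span)
        protected_indel |= _span_positions(*gly_span)
    protected_indel |= _boundary_zone(domains)
    return ClassTemplate(
        label=label, residues=residues, domains=domains,
        planted_motifs=dict(planted), protected_sub=protected_sub,
        protected_indel=protected_indel, gly_span=gly_span,
        core_start=offset if shared_core else None,
    )


def _pka_c_core(rng: random.Random) -> tuple[str, list[tuple[str, int, int]]]:
    """Shared catalytic core of all PKA-C classes: one kinase domain."""
    core = _draw(rng, 240)
    return core, [("kinase", 6, 235)]


def build_templates() -> dict[str, ClassTemplate]:
    """The fixed class templates (deterministic, independent of SimSpec)."""
    rng = random.Random(_TEMPLATE_SEED)
    templates: dict[str, ClassTemplate] = {}
    pka_c_core, pka_c_doms = _pka_c_core(rng)

    # --- PKA-C_1: MGNxxxxK start, FxxxW anchor, short N-terminus
    nterm = ("MGNAAATK"
             + _filler_avoiding(rng, 6, _FORBIDDEN_CHECKS["PKA-C_1"])
             + "FAQLW"
             + _filler_avoiding(rng, 41, _FORBIDDEN_CHECKS["PKA-C_1"]))
    templates["PKA-C_1"] = _assemble(
        "PKA-C_1", nterm, pka_c_core, pka_c_doms,
        planted={"MGNxxxxK": (1, 8), "MGNxxxx[K/R]": (1, 8),
                 "FxxxW": (15, 19)},
        gly_span=None, shared_core=True)

    # --- PKA-C_GLY: elongated glycine-rich N-terminus, FxxxW retained
    tract = _gly_tract(rng, 40)
    nterm = ("MS" + tract
             + _filler_avoiding(rng, 8, _FORBIDDEN_CHECKS["PKA-C_GLY"])
             + "FNELW"
             + _filler_avoiding(rng, 35, _FORBIDDEN_CHECKS["PKA-C_GLY"]))
    templates["PKA-C_GLY"] = _assemble(
        "PKA-C_GLY", nterm, pka_c_core, pka_c_doms,
        planted={"FxxxW": (51, 55)},
        gly_span=(3, 42), shared_core=True)

    # --- PKA-C_D1: MATL[M/T/A]A[F/T] at reference-like position, FxxxW
    nterm = ("MSE" + _filler_avoiding(rng, 26, ())
             + "MATLMAF"
             + _filler_avoiding(rng, 6, ())
             + "FKDLW"
             + _filler_avoiding(rng, 23, ()))
    templates["PKA-C_D1"] = _assemble(
        "PKA-C_D1", nterm, pka_c_core, pka_c_doms,
        planted={"MATL[M/T/A]A[F/T]": (30, 36), "FxxxW": (43, 47)},
        gly_span=None, shared_core=True)
    # the D1 N-terminus must not itself start with the ancestral MGN motif
    assert not templates["PKA-C_D1"].residues.startswith("MGN")

    # --- PKA-RI: D/D + pseudosubstrate RRx[A/G] + two cAMP-binding domains
    dd = "M" + _filler_avoiding(rng, 44, _FORBIDDEN_CHECKS["PKA-RI"])
    linker = (_filler_avoiding(rng, 50, _FORBIDDEN_CHECKS["PKA-RI"], dd)
              + "RRNA"
              + _filler_avoiding(rng, 20, _FORBIDDEN_CHECKS["PKA-RI"]))
    core = _filler_avoiding(rng, 260, _FORBIDDEN_CHECKS["PKA-RI"])
    residues_nterm = dd + linker
    templates["PKA-RI"] = _assemble(
        "PKA-RI", residues_nterm, core,
        [("cAMP_binding", 6, 115), ("cAMP_binding", 136, 250)],
        planted={"RRx[A/G]": (96, 99)},
        gly_span=None, shared_core=False)
    templates["PKA-RI"].domains.insert(0, ("DD", 1, 45))
    templates["PKA-RI"].protected_indel |= _boundary_zone([("DD", 1, 45)])

    # --- PKA-RII_GLY: glycine-rich N-terminus, D/D, RRxS substrate site
    tract = _gly_tract(rng, 32)
    pre = "MA" + tract + _filler_avoiding(rng, 6, _FORBIDDEN_CHECKS["PKA-RII_GLY"])
    dd = _filler_avoiding(rng, 45, _FORBIDDEN_CHECKS["PKA-RII_GLY"], pre)
    linker = (_filler_avoiding(rng, 40, _FORBIDDEN_CHECKS["PKA-RII_GLY"])
              + "RRVS"
              + _filler_avoiding(rng, 20, _FORBIDDEN_CHECKS["PKA-RII_GLY"]))
    nterm = pre + dd + linker
    core = _filler_avoiding(rng, 260, _FORBIDDEN_CHECKS["PKA-RII_GLY"])
    templates["PKA-RII_GLY"] = _assemble(
        "PKA-RII_GLY", nterm, core,
        [("cAMP_binding", 6, 115), ("cAMP_binding", 136, 250)],
        planted={"RRxS": (126, 129)},
        gly_span=(3, 34), shared_core=False)
    dd_span = ("DD", 41, 85)
    templates["PKA-RII_GLY"].domains.insert(0, dd_span)
    templates["PKA-RII_GLY"].protected_indel |= _boundary_zone([dd_span])

    # --- PKC subfamilies (architectures per full-length schematics)
    def pkc(label: str, length: int,
            domains: list[tuple[str, int, int]]) -> ClassTemplate:
        residues = "M" + _draw(rng, length - 1)
        tpl = _assemble(label, "", residues, domains, planted={},
                        gly_span=None, shared_core=False)
        return tpl

    templates["cPKC"] = pkc("cPKC", 650, [
        ("C1", 40, 90), ("C2", 120, 210), ("kinase", 350, 600)])
    templates["nPKC-delta-like"] = pkc("nPKC-delta-like", 700, [
        ("C2", 30, 130), ("C1", 180, 240), ("kinase", 350, 600)])
    templates["nPKC-epsilon-like"] = pkc("nPKC-epsilon-like", 700, [
        ("C2", 30, 130), ("C1", 180, 240), ("kinase", 350, 600)])
    templates["aPKC"] = pkc("aPKC", 550, [
        ("PB1", 20, 100), ("C1", 130, 180), ("kinase", 250, 500)])
    templates["PKN"] = pkc("PKN", 900, [
        ("HR1", 10, 80), ("HR1", 100, 170), ("HR1", 190, 260),
        ("C2", 300, 400), ("kinase", 600, 850)])
    return templates


# ---------------------------------------------------------------------------
# Mutation machinery

def _substitute(residues: list[str], protected: set[int], mu: float,
                rng: random.Random) -> None:
    for i in range(len(residues)):
        if i in protected:
            continue
        if rng.random() < mu:
            original = residues[i]
            choices = [a for a in _AA if a != original]
            weights = [_AA_WEIGHTS[_AA.index(a)] for a in choices]
            residues[i] = rng.choices(choices, weights=weights, k=1)[0]


def _apply_indels(
    residues: list[str],
    domains: list[list],
    planted: dict[str, list[int]],
    protected_indel: set[int],
    rate: float,
    rng: random.Random,
) -> None:
    """Single-residue indels outside protected zones, right to left.

    Domain coordinates and planted motif positions are shifted consistently.
    """
    events = []
    for i in range(len(residues)):
        if i in protected_indel:
            continue
        r = rng.random()
        if r < rate / 2:
            events.append((i, "ins"))
        elif r < rate:
            events.append((i, "del"))
    for pos, kind in sorted(events, reverse=True):
        if kind == "ins":
            residues.insert(pos, _draw(rng, 1))
            shift = 1
        else:
            del residues[pos]
            shift = -1
        pos1 = pos + 1  # 1-based coordinate of the edited site
        for dom in domains:
            if dom[1] > pos1:
                dom[1] += shift
            if dom[2] >= pos1:
                dom[2] += shift
        for span in planted.values():
            if span[0] > pos1:
                span[0] += shift
                span[1] += shift


def _mutate_template(
    tpl: ClassTemplate,
    mu: float,
    indel_rate: float,
    rng: random.Random,
    frozen_core: str | None = None,
) -> tuple[str, list[tuple[str, int, int]], dict[str, tuple[int, int]],
           tuple[int, int] | None]:
    """One mutated copy: residues, shifted domains, planted spans, gly span.

    When ``frozen_core`` is given, the template's shared-core region is
    replaced by it verbatim (no further mutation there): isoforms of one
    species keep an identical catalytic core.
    """
    residues = list(tpl.residues)
    protected_sub = set(tpl.protected_sub)
    protected_indel = set(tpl.protected_indel)
    if tpl.core_start is not None and frozen_core is not None:
        residues[tpl.core_start:] = list(frozen_core)
        core_zone = set(range(tpl.core_start, len(residues)))
        protected_sub |= core_zone
        protected_indel |= core_zone
    _substitute(residues, protected_sub, mu, rng)
    domains = [list(d) for d in tpl.domains]
    planted = {p: list(span) for p, span in tpl.planted_motifs.items()}
    if tpl.gly_span is not None:
        planted["__gly__"] = list(tpl.gly_span)
    if indel_rate > 0:
        _apply_indels(residues, domains, planted, protected_indel,
                      indel_rate, rng)
    gly_span = None
    if "__gly__" in planted:
        s = planted.pop("__gly__")
        gly_span = (s[0], s[1])
    return ("".join(residues),
            [(d[0], d[1], d[2]) for d in domains],
            {p: (s[0], s[1]) for p, s in planted.items()},
            gly_span)


# ---------------------------------------------------------------------------
# Dataset generation

def generate_dataset(
    spec: SimSpec,
) -> tuple[list[SequenceRecord], list[DomainAnnotation], dict[str, TruthRecord]]:
    """Sequences, domain table, and truth table for one SimSpec.

    Within a species, all PKA-C class sequences share one identical
    catalytic core (mutated once per species from the core template); the
    classes differ only in their N-terminal region.
    """
    templates = build_templates()
    rng = random.Random(spec.seed)
    records: list[SequenceRecord] = []
    annotations: list[DomainAnnotation] = []
    truth: dict[str, TruthRecord] = {}
    pka_c_tpl = templates["PKA-C_1"]
    for s in range(1, spec.n_species + 1):
        species = f"Synthspecies_{s:02d}"
        # per-species shared PKA-C catalytic core
        core_template = pka_c_tpl.residues[pka_c_tpl.core_start:]
        core = list(core_template)
        _substitute(core, set(), spec.mu, rng)
        species_core = "".join(core)
        for label in spec.classes:
            tpl = templates[label]
            for i in range(1, spec.seqs_per_class + 1):
                seq_id = f"{species}_{label}_{i}"
                frozen = species_core if tpl.core_start is not None else None
                residues, domains, planted, gly_span = _mutate_template(
                    tpl, spec.mu, spec.indel_rate, rng, frozen_core=frozen)
                rec = SequenceRecord(
                    id=seq_id, residues=residues, species=species,
                    phylum="Arthropoda", source="synthetic")
                records.append(rec)
                for name, start, end in domains:
                    annotations.append(DomainAnnotation(
                        seq_id=seq_id, domain_name=name, start=start,
                        end=end, complete=True, evalue=1e-80))
                truth[seq_id] = TruthRecord(
                    seq_id=seq_id, class_label=label,
                    family=FAMILY_OF_CLASS[label],
                    subtype=SUBTYPE_OF_CLASS.get(label, ""),
                    species=species, planted_motifs=planted,
                    gly_span=gly_span)
    return records, annotations, truth


def reference_panel_records() -> list[tuple[SequenceRecord, str]]:
    """The unmutated class templates as labelled synthetic exemplars."""
    templates = build_templates()
    out = []
    for label, tpl in templates.items():
        rec = SequenceRecord(
            id=f"exemplar_{label}", residues=tpl.residues,
            species="exemplar", phylum="unknown", source="reference")
        out.append((rec, FAMILY_OF_CLASS[label]))
    return out


# ---------------------------------------------------------------------------
# Hit tables

def _log_uniform(rng: random.Random, lo_exp: float, hi_exp: float) -> float:
    return 10.0 ** rng.uniform(lo_exp, hi_exp)


def generate_hit_table(
    records: Sequence[SequenceRecord],
    truth: dict[str, TruthRecord],
    decoy_count: int = 0,
    seed: int = 0,
    keep_fraction: float = 0.7,
    mu: float = 0.05,
) -> tuple[list[HomologyHit], dict[str, bool]]:
    """Hit table with planted keep/reject E-value bands.

    Keep-flagged subjects draw E-values log-uniform in [1e-180, 1e-121]
    (inside the transcriptome-stage threshold of 1e-120); reject-flagged in
    [1e-119, 1e-60]; decoys at 1e-50 and above. Identity tracks 100(1-mu)
    with mild noise. Returns (hits, planted keep-flags).
    """
    rng = random.Random(seed)
    hits: list[HomologyHit] = []
    flags: dict[str, bool] = {}
    for rec in records:
        keep = rng.random() < keep_fraction
        flags[rec.id] = keep
        if keep:
            evalue = _log_uniform(rng, -180, -121)
        else:
            evalue = _log_uniform(rng, -119, -60)
        identity = min(100.0, max(0.0,
                       100.0 * (1 - mu) + rng.gauss(0, 1.5)))
        hits.append(HomologyHit(
            query_id=f"query_{truth[rec.id].family}" if rec.id in truth
            else "query", subject_id=rec.id,
            percent_identity=round(identity, 1), evalue=evalue,
            bitscore=round(-math.log10(evalue) * 2, 1)
            if evalue > 0 else 2000.0,
            alignment_length=len(rec)))
    for d in range(1, decoy_count + 1):
        subject = f"decoy_{d}"
        flags[subject] = False
        evalue = _log_uniform(rng, -50, -5)
        hits.append(HomologyHit(
            query_id="query", subject_id=subject,
            percent_identity=round(rng.uniform(20, 45), 1), evalue=evalue,
            bitscore=round(-math.log10(evalue) * 2, 1),
            alignment_length=200))
    return hits, flags


# ---------------------------------------------------------------------------
# Contaminated trees

def _random_coalescent_newick(labels: Sequence[str],
                              rng: random.Random) -> str:
    """Topology by sequential random coalescence; edge lengths Gamma(3, 1/3).

    Gamma-distributed lengths give realistic spread with a light enough
    tail that un-contaminated terminal branches are never order-of-
    magnitude outliers; contamination is planted explicitly on top.
    """
    def edge_len() -> float:
        return rng.gammavariate(3.0, 1.0 / 3.0)

    nodes = [f"{lab}:{edge_len():.6f}" for lab in labels]
    while len(nodes) > 1:
        i, j = rng.sample(range(len(nodes)), 2)
        a, b = nodes[i], nodes[j]
        merged = f"({a},{b}):{edge_len():.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return nodes[0].rsplit(":", 1)[0] + ";"


def generate_contaminated_tree(
    n_tips: int = 40,
    n_long: int = 0,
    n_mislabeled: int = 0,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[str, str], dict[str, dict[str, bool]]]:
    """Two-phylum tree with planted long branches and mislabeled tips.

    Tips split evenly into an Arthropoda clade and a Nematoda clade.
    ``n_long`` random tips get terminal branches inflated 10x-100x;
    ``n_mislabeled`` tips keep their position but are recorded in the taxon
    map under the foreign phylum. Returns (tree, taxon map, planted flags).
    """
    if n_long + n_mislabeled >= n_tips / 2:
        raise ValueError("too many contaminants for tree size")
    rng = random.Random(seed)
    half = n_tips // 2
    arth = [f"arth_{i:02d}" for i in range(1, half + 1)]
    nema = [f"nema_{i:02d}" for i in range(1, n_tips - half + 1)]
    newick = (
        "(" + _random_coalescent_newick(arth, rng)[:-1] + ":0.500000,"
        + _random_coalescent_newick(nema, rng)[:-1] + ":0.500000);"
    )
    tree = parse_newick(newick)
    taxon_map = {t: "Arthropoda" for t in arth}
    taxon_map.update({t: "Nematoda" for t in nema})
    all_tips = arth + nema
    chosen = rng.sample(all_tips, n_long + n_mislabeled)
    long_tips, mislabeled = set(chosen[:n_long]), set(chosen[n_long:])
    terminal = sorted(leaf.edge.length for leaf in tree.leaf_node_iter())
    typical = terminal[len(terminal) // 2]
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in long_tips:
            # inflate relative to the typical terminal branch so planted
            # contaminants are genuinely 10x-100x outliers
            leaf.edge.length = (max(leaf.edge.length, typical)
                                * rng.uniform(10, 100))
    for tip in mislabeled:
        taxon_map[tip] = ("Nematoda" if taxon_map[tip] == "Arthropoda"
                          else "Arthropoda")
    flags = {
        tip: {"long_branch": tip in long_tips,
              "mislabeled": tip in mislabeled}
        for tip in all_tips
    }
    return tree, taxon_map, flags
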