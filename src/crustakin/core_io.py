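"""Shared domain types and readers/writers for the pipeline's file formats.

Formats handled here: FASTA (with an optional ``key=value; key=value``
metadata dialect in the header description), 12-column BLAST tabular hit
tables, 6-column conserved-domain annotation tables, and newick trees
(delegated to dendropy). All coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

# 20 canonical residues; X is tolerated in sequences but never matches a
# motif literal and never counts as identical/similar.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_RESIDUES = CANONICAL_RESIDUES | {"X"}

PHYLA = (
    "Annelida", "Arthropoda", "Chordata", "Cnidaria", "Echinodermata",
    "Mollusca", "Nematoda", "Platyhelminthes", "Porifera", "Tardigrada",
)

DOMAIN_VOCABULARY = (
    "kinase", "cAMP_binding", "DD", "C1", "C2", "PB1", "HR1", "PH",
)

#: domains that delimit the N-terminal region of a kinase sequence
CORE_DOMAINS = ("kinase", "cAMP_binding")


class FormatError(ValueError):
    """Malformed input file; parsers reject rather than truncate."""


@dataclass
class SequenceRecord:
    """One protein sequence with its taxonomic annotation."""

    id: str
    residues: str
    species: str = "unknown"
    phylum: str = "unknown"
    source: str = "synthetic"  # reference | crustome | synthetic

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, ch in enumerate(self.residues, start=1):
            if ch not in ALLOWED_RESIDUES:
                raise FormatError(
                    f"{self.id}: non-amino-acid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HomologyHit:
    """One row of a BLAST-style tabular homology search."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    alignment_length: int

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"negative evalue for {self.subject_id}")
        if not 0 <= self.percent_identity <= 100:
            raise ValueError(
                f"percent identity {self.percent_identity} out of [0, 100]"
            )
        if self.alignment_length <= 0:
            raise ValueError("alignment_length must be positive")


@dataclass(frozen=True)
class DomainAnnotation:
    """One conserved-domain hit on a sequence (1-based inclusive span)."""

    seq_id: str
    domain_name: str
    start: int
    end: int
    complete: bool
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.domain_name not in DOMAIN_VOCABULARY:
            raise FormatError(
                f"unknown domain name {self.domain_name!r}; expected one of "
                + ", ".join(DOMAIN_VOCABULARY)
            )
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"{self.seq_id}/{self.domain_name}: invalid span "
                f"{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Alignment:
    """Rows of gapped sequences of equal column count, keyed by id."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows:
            ncol = len(self.rows[0])
            if any(len(r) != ncol for r in self.rows):
                raise ValueError("alignment rows differ in column count")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise KeyError(f"row id {row_id!r} not in alignment") from None


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA header into (id, species, phylum).

    Metadata dialect: everything after the first whitespace is parsed as
    ``key=value; key=value`` pairs; unrecognized keys are ignored.
    """
    parts = header.split(None, 1)
    seq_id = parts[0]
    species = phylum = "unknown"
    if len(parts) == 2:
        for chunk in parts[1].split(";"):
            if "=" not in chunk:
                continue
            key, value = chunk.split("=", 1)
            key, value = key.strip().lower(), value.strip()
            if key == "species" and value:
                species = value
            elif key == "phylum" and value:
                phylum = value
    return seq_id, species, phylum


def read_fasta(path: str | Path, source: str = "synthetic") -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    Wrapped sequence lines are concatenated and uppercased; duplicate ids
    and non-amino-acid characters raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        seq_id, species, phylum = _parse_header(header)
        if seq_id in seen:
            raise FormatError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        records.append(
            SequenceRecord(
                id=seq_id, residues="".join(chunks),
                species=species, phylum=phylum, source=source,
            )
        )

    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError("sequence data before first FASTA header")
                chunks.append(line)
        _flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as wrapped FASTA, carrying species/phylum metadata."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id} species={rec.species}; phylum={rec.phylum}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tabular formats

_HIT_COLUMNS = 12


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column BLAST tabular file (outfmt-6 dialect).

    Columns: query, subject, pident, length, mismatch, gapopen, qstart,
    qend, sstart, send, evalue, bitscore. Comment lines (#) are skipped.
    """
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _HIT_COLUMNS:
                raise FormatError(
                    f"line {lineno}: expected {_HIT_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hits.append(
                    HomologyHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HomologyHit], path: str | Path) -> None:
    """Write hits back out in the 12-column dialect (unused fields zeroed)."""
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join([
                    h.query_id, h.subject_id, f"{h.percent_identity:g}",
                    str(h.alignment_length), "0", "0", "0", "0", "0", "0",
                    f"{h.evalue:g}", f"{h.bitscore:g}",
                ]) + "\n"
            )


_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no"}


def read_domain_table(path: str | Path,
                      records: Sequence[SequenceRecord] | None = None,
                      ) -> list[DomainAnnotation]:
    """Read a 6-column domain table (seq_id, name, start, end, complete, evalue).

    When ``records`` is supplied, every annotation span is validated against
    the length of its sequence. A header row starting with ``seq_id`` is
    skipped.
    """
    lengths = {r.id: len(r) for r in records} if records is not None else None
    annotations: list[DomainAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0] == "seq_id":
                continue
            if len(fields) != 6:
                raise FormatError(
                    f"line {lineno}: expected 6 tab-separated columns, "
                    f"found {len(fields)}"
                )
            flag = fields[4].strip().lower()
            if flag in _TRUE:
                complete = True
            elif flag in _FALSE:
                complete = False
            else:
                raise FormatError(f"line {lineno}: bad boolean {fields[4]!r}")
            try:
                ann = DomainAnnotation(
                    seq_id=fields[0], domain_name=fields[1],
                    start=int(fields[2]), end=int(fields[3]),
                    complete=complete, evalue=float(fields[5]),
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
            if lengths is not None:
                if ann.seq_id not in lengths:
                    raise FormatError(
                        f"line {lineno}: unknown sequence {ann.seq_id!r}"
                    )
                if ann.end > lengths[ann.seq_id]:
                    raise FormatError(
                        f"line {lineno}: {ann.seq_id} annotation end {ann.end} "
                        f"beyond sequence length {lengths[ann.seq_id]}"
                    )
            annotations.append(ann)
    return annotations


def write_domain_table(annotations: Iterable[DomainAnnotation],
                       path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id\tdomain_name\tstart\tend\tcomplete\tevalue\n")
        for a in annotations:
            fh.write(
                f"{a.seq_id}\t{a.domain_name}\t{a.start}\t{a.end}\t"
                f"{'true' if a.complete else 'false'}\t{a.evalue:g}\n"
            )


def write_tsv(rows: Iterable[Sequence], path: str | Path,
              header: Sequence[str] | None = None) -> None:
    """Write rows as UTF-8 TSV with an optional header row."""
    with open(path, "w", encoding="utf-8") as fh:
        if header is not None:
            fh.write("\t".join(str(c) for c in header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced parenthesis at character offset {offset}"
                )
    if depth != 0:
        raise FormatError(
            f"unbalanced parentheses: {depth} unclosed '(' at end of input"
        )


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a newick tree; missing branch lengths become 0 with a flag.

    The returned dendropy Tree carries ``missing_lengths`` (bool) as an
    attribute when any edge lacked a length.
    """
    text = Path(path).read_text(encoding="utf-8")
    return parse_newick(text)


def parse_newick(text: str) -> dendropy.Tree:
    _check_parentheses(text)
    tree = dendropy.Tree.get(
        data=text, schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    missing = False
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing = True
        elif edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    tree.missing_lengths = missing
    tip_ids = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(tip_ids) != len(set(tip_ids)):
        raise FormatError("duplicate tip labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            tree.as_string(
                schema="newick", suppress_rooting=True,
                unquoted_underscores=True,
            )
        )


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]
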