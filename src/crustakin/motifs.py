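"""Degenerate motif grammar, N-terminal scanning, consensus, and glycine tracts.

The motif grammar matches the notation used for kinase N-terminal signatures:
uppercase residue literals, ``x`` for any of the 20 canonical residues, and
bracketed alternations like ``[K/R]``. The stock patterns cover the PKA
catalytic-subunit starts (``MGNxxxx[K/R]`` in chordates, ``MGNxxxxK`` in
invertebrates), the hydrophobic anchor ``FxxxW``, the decapod-specific
``MATL[M/T/A]A[F/T]``, the AKAP-binding ``IxI``/``VxV`` motifs of the
regulatory-subunit docking domain, and the autoinhibitory-site motifs
``RRx[A/G]`` (RI pseudosubstrate) and ``RRxS`` (RII phosphorylatable
substrate).

``X`` (unknown residue) in a sequence never satisfies any motif position,
including the ``x`` wildcard.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .core_io import (
    Alignment, CANONICAL_RESIDUES, CORE_DOMAINS, DomainAnnotation,
    SequenceRecord,
)

_WILDCARD = frozenset(CANONICAL_RESIDUES)

#: the stock motif checks reported by :func:`motif_report`
STANDARD_PATTERNS = (
    "MGNxxxx[K/R]", "MGNxxxxK", "FxxxW", "MATL[M/T/A]A[F/T]",
    "IxI", "VxV", "RRx[A/G]", "RRxS",
)
_ANCHORED = {"MGNxxxx[K/R]", "MGNxxxxK"}


class MotifSyntaxError(ValueError):
    """Malformed motif pattern; the message carries the character offset."""


@dataclass(frozen=True)
class DegenerateMotif:
    pattern: str
    compiled: tuple[frozenset[str], ...]
    anchored: bool = False

    def __len__(self) -> int:
        return len(self.compiled)


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    pattern: str
    start: int  # 1-based
    end: int    # 1-based inclusive
    matched: str


@dataclass(frozen=True)
class GlyRegion:
    seq_id: str
    start: int
    end: int
    gly_fraction: float
    window: int


def compile_motif(pattern: str, anchored: bool = False) -> DegenerateMotif:
    """Compile a degenerate pattern into per-position residue sets.

    Grammar: uppercase canonical residue literals; ``x`` = any canonical
    residue; ``[A/B]`` or ``[A/B/C]`` = alternation. Errors report the
    0-based character offset of the offending token.
    """
    if not pattern:
        raise MotifSyntaxError("empty pattern")
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "x":
            positions.append(_WILDCARD)
            i += 1
        elif ch == "[":
            close = pattern.find("]", i)
            if close < 0:
                raise MotifSyntaxError(
                    f"unbalanced '[' at offset {i} in {pattern!r}")
            body = pattern[i + 1:close]
            alts = body.split("/")
            if not body or any(not a for a in alts):
                raise MotifSyntaxError(
                    f"empty alternation at offset {i} in {pattern!r}")
            for a in alts:
                if len(a) != 1 or a not in CANONICAL_RESIDUES:
                    raise MotifSyntaxError(
                        f"bad alternation member {a!r} at offset {i} "
                        f"in {pattern!r}")
            positions.append(frozenset(alts))
            i = close + 1
        elif ch in CANONICAL_RESIDUES:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise MotifSyntaxError(
                f"unexpected character {ch!r} at offset {i} in {pattern!r}")
    return DegenerateMotif(pattern=pattern, compiled=tuple(positions),
                           anchored=anchored)


def _matches_at(residues: str, motif: DegenerateMotif, start0: int) -> bool:
    for offset, allowed in enumerate(motif.compiled):
        if residues[start0 + offset] not in allowed:
            return False
    return True


def find_motif(
    record: SequenceRecord,
    motif: DegenerateMotif | str,
    region: tuple[int, int] | None = None,
) -> list[MotifHit]:
    """All match positions of a motif, left to right (1-based inclusive).

    Anchored motifs are only tried at position 1. ``region`` restricts the
    search to a 1-based inclusive span (matches must lie entirely within).
    """
    if isinstance(motif, str):
        motif = compile_motif(motif)
    residues = record.residues
    lo, hi = 1, len(residues)
    if region is not None:
        lo, hi = region
        if not (1 <= lo <= hi <= len(residues)):
            raise ValueError(
                f"region {region} outside sequence bounds 1-{len(residues)}")
    span = len(motif)
    hits: list[MotifHit] = []
    starts = [1] if motif.anchored else range(lo, hi - span + 2)
    for start in starts:
        if start < lo or start + span - 1 > hi:
            continue
        if _matches_at(residues, motif, start - 1):
            hits.append(MotifHit(
                seq_id=record.id, pattern=motif.pattern,
                start=start, end=start + span - 1,
                matched=residues[start - 1:start + span - 1],
            ))
    return hits


# ---------------------------------------------------------------------------
# N-terminal region and glycine tracts

def nterm_region(
    record: SequenceRecord, annotations: Sequence[DomainAnnotation],
) -> tuple[int, int, bool]:
    """(start=1, end, empty_flag): sequence upstream of the first core domain.

    The core domains are the kinase domain (catalytic subunits, PKCs) and
    the cAMP-binding domain (regulatory subunits). The region is empty
    (flagged) when a core domain starts at residue 1.
    """
    starts = [a.start for a in annotations
              if a.seq_id == record.id and a.domain_name in CORE_DOMAINS]
    if not starts:
        raise ValueError(
            f"{record.id}: no kinase/cAMP_binding annotation — supply domain "
            "annotations to delimit the N-terminal region")
    end = min(starts) - 1
    return (1, end, end < 1)


def glycine_rich_regions(
    record: SequenceRecord,
    window: int = 25,
    min_frac: float = 0.4,
    search_span: tuple[int, int] | None = None,
) -> tuple[list[GlyRegion], bool]:
    """Sliding-window glycine-tract scan; returns (regions, short_span_flag).

    Every window start whose glycine fraction is >= ``min_frac`` is reported;
    overlapping qualifying windows are merged into maximal regions whose
    ``gly_fraction`` is the best single-window fraction inside the region.
    A search span shorter than the window yields no regions and a warning
    flag.
    """
    if window < 5:
        raise ValueError("window must be >= 5")
    lo, hi = search_span if search_span else (1, len(record.residues))
    seq = record.residues
    if hi - lo + 1 < window:
        return [], True
    qualifying: list[tuple[int, float]] = []
    gly = [1 if c == "G" else 0 for c in seq]
    running = sum(gly[lo - 1:lo - 1 + window])
    for start in range(lo, hi - window + 2):
        if start > lo:
            running += gly[start + window - 2] - gly[start - 2]
        frac = running / window
        if frac >= min_frac:
            qualifying.append((start, frac))
    regions: list[GlyRegion] = []
    for start, frac in qualifying:
        if regions and start <= regions[-1].end:
            prev = regions[-1]
            regions[-1] = GlyRegion(
                seq_id=record.id, start=prev.start,
                end=max(prev.end, start + window - 1),
                gly_fraction=max(prev.gly_fraction, frac), window=window)
        else:
            regions.append(GlyRegion(
                seq_id=record.id, start=start, end=start + window - 1,
                gly_fraction=frac, window=window))
    return regions, False


def is_gly_rich_nterm(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation],
    window: int = 25,
    min_frac: float = 0.4,
) -> bool:
    """True iff a glycine-rich tract lies in the N-terminal region."""
    start, end, empty = nterm_region(record, annotations)
    if empty:
        return False
    regions, _ = glycine_rich_regions(
        record, window=window, min_frac=min_frac, search_span=(start, end))
    return bool(regions)


# ---------------------------------------------------------------------------
# Autoinhibitory-site typing (regulatory subunits)

_RI_MOTIF = compile_motif("RRx[A/G]")
_RII_MOTIF = compile_motif("RRxS")


def linker_region(
    record: SequenceRecord, annotations: Sequence[DomainAnnotation],
) -> tuple[int, int] | None:
    """Span between the docking domain (or start) and the first cAMP domain.

    Returns None when no cAMP-binding annotation exists (caller falls back
    to a whole-sequence scan).
    """
    anns = [a for a in annotations if a.seq_id == record.id]
    camp_starts = [a.start for a in anns if a.domain_name == "cAMP_binding"]
    if not camp_starts:
        return None
    dd_ends = [a.end for a in anns if a.domain_name == "DD"]
    start = max(dd_ends) + 1 if dd_ends else 1
    end = min(camp_starts) - 1
    if start > end:
        return None
    return (start, end)


def classify_ai_site(
    record: SequenceRecord,
    linker: tuple[int, int] | None = None,
) -> str:
    """Type the autoinhibitory site: 'RI', 'RII', 'ambiguous', or 'none'.

    RI when only the pseudosubstrate RRx[A/G] matches, RII when only the
    phosphorylatable RRxS matches, ambiguous when both do (RRxG and RRxS
    can co-occur at different positions), none otherwise. ``linker``
    restricts the scan; None scans the whole sequence.
    """
    ri = find_motif(record, _RI_MOTIF, region=linker)
    rii = find_motif(record, _RII_MOTIF, region=linker)
    if ri and rii:
        return "ambiguous"
    if ri:
        return "RI"
    if rii:
        return "RII"
    return "none"


# ---------------------------------------------------------------------------
# Consensus derivation

def consensus(
    alignment: Alignment,
    single_threshold: float = 0.7,
    pair_threshold: float = 0.7,
) -> str:
    """Frequency-based consensus of an alignment, one token per column.

    Per column, over non-gap entries: the residue when its frequency is
    >= ``single_threshold``; else ``[A/B]`` (alphabetical) when the two most
    frequent residues jointly reach ``pair_threshold`` and each reaches 0.2;
    else ``x``. Columns with gap fraction > 0.5 emit ``-``. Frequency ties
    are broken alphabetically.
    """
    if not alignment.rows:
        raise ValueError("empty alignment")
    for name, t in (("single_threshold", single_threshold),
                    ("pair_threshold", pair_threshold)):
        if not 0.5 < t <= 1:
            raise ValueError(f"{name} must lie in (0.5, 1]")
    tokens: list[str] = []
    nrow = len(alignment.rows)
    for c in range(alignment.n_columns):
        column = [row[c] for row in alignment.rows]
        gaps = column.count("-")
        if gaps / nrow > 0.5:
            tokens.append("-")
            continue
        residues = [ch for ch in column if ch != "-"]
        counts = Counter(residues)
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        n = len(residues)
        top, top_n = ranked[0]
        if top_n / n >= single_threshold:
            tokens.append(top)
        elif len(ranked) >= 2:
            second, second_n = ranked[1]
            if ((top_n + second_n) / n >= pair_threshold
                    and top_n / n >= 0.2 and second_n / n >= 0.2):
                a, b = sorted((top, second))
                tokens.append(f"[{a}/{b}]")
            else:
                tokens.append("x")
        else:
            tokens.append("x")
    return "".join(tokens)


# ---------------------------------------------------------------------------
# Per-sequence motif report

def motif_report(
    record: SequenceRecord,
    annotations: Sequence[DomainAnnotation] = (),
) -> dict[str, object]:
    """Presence/position table of the stock motif checks for one sequence.

    Anchored checks (the MGN starts) run at position 1; FxxxW and the MATL
    motif are restricted to the N-terminal region when core-domain
    annotations are available; the AI-site motifs are restricted to the
    linker when cAMP-binding annotations exist. Also reports the G2
    myristoylation site (glycine at position 2).
    """
    region = None
    try:
        start, end, empty = nterm_region(record, annotations)
        if not empty:
            region = (start, end)
    except ValueError:
        region = None
    linker = linker_region(record, annotations)

    report: dict[str, object] = {"seq_id": record.id}
    for pattern in STANDARD_PATTERNS:
        motif = compile_motif(pattern, anchored=pattern in _ANCHORED)
        if pattern in ("RRx[A/G]", "RRxS"):
            search = linker
        elif pattern in ("MATL[M/T/A]A[F/T]", "FxxxW"):
            search = region
        else:
            search = None
        hits = find_motif(record, motif, region=search)
        report[pattern] = hits[0].start if hits else None
    report["G2"] = len(record.residues) >= 2 and record.residues[1] == "G"
    return report
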