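"""Global pairwise alignment and grouped identity/similarity statistics.

Percent identity counts alignment columns with equal residues; percent
similarity additionally counts columns whose residues fall in the same
physicochemical group. The group scheme is GAVLI, FYW, CM, ST, KRH, DENQ,
and P — small/aliphatic, aromatic, sulfur-containing, hydroxyl, basic,
acidic/amide, and proline on its own. ``X`` belongs to no group and is
never identical, even to itself.

Alignment is global Needleman-Wunsch with affine gap penalties over
BLOSUM62 (Bio.Align.PairwiseAligner); a gap run of length L costs
``gap_open + (L - 1) * gap_extend``. Terminal gaps are penalized by
default, matching the full-length alignments the pairwise statistics are
defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import Alignment, CANONICAL_RESIDUES, SequenceRecord

DEFAULT_GROUPS = ("GAVLI", "FYW", "CM", "ST", "KRH", "DENQ", "P")


@dataclass(frozen=True)
class SimilarityScheme:
    """Disjoint residue groups whose union is the 20 canonical residues."""

    groups: tuple[str, ...] = DEFAULT_GROUPS

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if seen & set(g):
                raise ValueError(f"groups are not disjoint at {g!r}")
            seen |= set(g)
        if seen != set(CANONICAL_RESIDUES):
            raise ValueError("groups must cover exactly the 20 canonical residues")

    def group_of(self, residue: str) -> str | None:
        for g in self.groups:
            if residue in g:
                return g
        return None

    def similar(self, a: str, b: str) -> bool:
        """Same-group test; gaps and X are similar to nothing."""
        if a == "-" or b == "-" or a == "X" or b == "X":
            return False
        ga = self.group_of(a)
        return ga is not None and ga == self.group_of(b)


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    penalize_terminal_gaps: bool = True

    def __post_init__(self) -> None:
        if not self.gap_open >= self.gap_extend > 0:
            raise ValueError("require gap_open >= gap_extend > 0")


@dataclass
class PairwiseAlignment:
    """Two gapped rows of equal length plus the alignment score."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("aligned rows differ in length")
        for a, b in zip(self.row_a, self.row_b):
            if a == "-" and b == "-":
                raise ValueError("gap-in-both column")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    # Biopython convention: opening a gap costs open_gap_score, each further
    # residue extend_gap_score => run of L costs open + (L-1) * extend.
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    if not params.penalize_terminal_gaps:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def global_align(
    a: SequenceRecord, b: SequenceRecord,
    params: AlignParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two records under affine-gap scoring.

    Deterministic: among co-optimal alignments the aligner's canonical
    first traceback is returned.
    """
    params = params or AlignParams()
    if set(a.residues) <= {"X"} or set(b.residues) <= {"X"}:
        raise ValueError("sequence consists only of unknown residues (X); "
                         "unalignable")
    aligner = _make_aligner(params)
    result = aligner.align(a.residues, b.residues)
    best = result[0]
    row_a, row_b = str(best[0]), str(best[1])
    return PairwiseAlignment(
        id_a=a.id, id_b=b.id, row_a=row_a, row_b=row_b,
        score=float(best.score),
    )


def ident_sim(
    aln: PairwiseAlignment,
    scheme: SimilarityScheme | None = None,
    denominator: str = "alignment",
) -> tuple[float, float]:
    """(percent identity, percent similarity) of a pairwise alignment.

    denominator='alignment' divides by the total column count (gap columns
    count and are neither identical nor similar); 'shorter' divides by the
    length of the shorter ungapped sequence. Full precision is returned;
    round only at the reporting layer.
    """
    scheme = scheme or SimilarityScheme()
    identical = similar = 0
    for ra, rb in zip(aln.row_a, aln.row_b):
        if ra == "-" or rb == "-":
            continue
        if ra == rb and ra != "X":
            identical += 1
            similar += 1
        elif scheme.similar(ra, rb):
            similar += 1
    if denominator == "alignment":
        d = aln.n_columns
    elif denominator == "shorter":
        d = min(len(aln.row_a.replace("-", "")),
                len(aln.row_b.replace("-", "")))
    else:
        raise ValueError("denominator must be 'alignment' or 'shorter'")
    return 100.0 * identical / d, 100.0 * similar / d


@dataclass
class IdentSimMatrix:
    ids: list[str]
    identity: np.ndarray
    similarity: np.ndarray
    shading: np.ndarray  # min-max rank in [0, 1] per matrix, off-diagonal

    def to_table(self) -> list[list[str]]:
        """Paper-style layout: identity above the diagonal, similarity below."""
        n = len(self.ids)
        table = [[""] * (n + 1) for _ in range(n + 1)]
        table[0][1:] = self.ids
        for i in range(n):
            table[i + 1][0] = self.ids[i]
            for j in range(n):
                if i == j:
                    table[i + 1][j + 1] = "100"
                elif i < j:
                    table[i + 1][j + 1] = f"{self.identity[i, j]:.1f}"
                else:
                    table[i + 1][j + 1] = f"{self.similarity[i, j]:.1f}"
        return table


def _minmax_shading(mat: np.ndarray) -> np.ndarray:
    n = mat.shape[0]
    off = mat[~np.eye(n, dtype=bool)]
    lo, hi = float(off.min()), float(off.max())
    shading = np.ones_like(mat)
    if hi > lo:
        shading = (mat - lo) / (hi - lo)
    np.fill_diagonal(shading, 1.0)
    return shading


def identsim_matrix(
    records: list[SequenceRecord],
    params: AlignParams | None = None,
    scheme: SimilarityScheme | None = None,
    denominator: str = "alignment",
) -> IdentSimMatrix:
    """All-pairs identity/similarity matrices with min-max shading ranks."""
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    n = len(records)
    identity = np.full((n, n), 100.0)
    similarity = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], params)
            ident, sim = ident_sim(aln, scheme, denominator)
            identity[i, j] = identity[j, i] = ident
            similarity[i, j] = similarity[j, i] = sim
    return IdentSimMatrix(
        ids=ids, identity=identity, similarity=similarity,
        shading=_minmax_shading(identity),
    )


# ---------------------------------------------------------------------------
# MSA conservation profile

PROFILE_BINS = (">80", ">60", ">40", "<=40")


def msa_identity_profile(
    alignment: Alignment,
    reference_row: str,
    window: int = 1,
) -> list[tuple[float | None, str | None]]:
    """Per-column (percent match to reference, bin) along an MSA.

    The percent is the fraction of non-reference rows whose residue equals
    the reference residue in that column, optionally smoothed with a
    centred sliding-window mean. Bins are strict: >80, >60, >40, <=40.
    Columns where the reference carries a gap are undefined (None, None).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ref = alignment.row(reference_row)
    others = [row for rid, row in zip(alignment.ids, alignment.rows)
              if rid != reference_row]
    if not others:
        raise ValueError("alignment has no rows besides the reference")
    raw: list[float | None] = []
    for c in range(alignment.n_columns):
        if ref[c] == "-":
            raw.append(None)
            continue
        matches = sum(row[c] == ref[c] for row in others)
        raw.append(100.0 * matches / len(others))
    if window > 1:
        half = window // 2
        smoothed: list[float | None] = []
        for c, value in enumerate(raw):
            if value is None:
                smoothed.append(None)
                continue
            span = [v for v in raw[max(0, c - half):c + half + 1]
                    if v is not None]
            smoothed.append(sum(span) / len(span))
        raw = smoothed
    profile: list[tuple[float | None, str | None]] = []
    for value in raw:
        if value is None:
            profile.append((None, None))
        elif value > 80:
            profile.append((value, ">80"))
        elif value > 60:
            profile.append((value, ">60"))
        elif value > 40:
            profile.append((value, ">40"))
        else:
            profile.append((value, "<=40"))
    return profile
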