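# Methods

`crustakin` implements the sequence-analysis layer used to characterize
crustacean (especially decapod) PKA and PKC proteins: homolog curation,
tree-based contamination screening, N-terminal motif and consensus
analysis, glycine-rich isoform detection, grouped identity/similarity
statistics, and domain-architecture classification with a decapod isoform
nomenclature. This note records the models and procedures, the parameters
that matter, and the design choices made where the design was genuinely
open.

## Curation model

Homolog candidates arrive as BLAST-style tabular hits plus conserved-domain
annotations. Two stages are modelled, reflecting a reference-guided search
followed by a transcriptome-database search:

- **Reference stage** — a subject is kept iff its best (minimum) E-value is
  ≤ `reference_max_evalue` (default 1e-70), its best (maximum) percent
  identity is **strictly above** `reference_min_identity` (default 60; the
  criterion is worded "above", so a boundary hit at exactly 60 is
  rejected), and it has at least `reference_min_domains` (default 1)
  complete conserved-domain annotations.
- **Transcriptome stage** — keep iff best E-value ≤ `crustome_max_evalue`
  (default 1e-120), inclusive; no identity or domain condition at this
  stage.
- **Domain completeness** — regulatory-subunit and PKC candidates must
  carry ≥ 2 complete conserved domains; this removes other cAMP-binding
  proteins and kinases that share a single domain.

All filters are applied per subject using its best hit across queries
(multiple query searches are concatenated in practice). Every filter
partitions its input exactly into kept and rejected-with-reason; filters
are idempotent on their own kept sets and monotone in their thresholds.

## Tree-based contamination screening

The published refinement step removes sequences "identified by long branch
lengths or abnormal grouping" — a manual-review criterion with no printed
numbers. Two screens formalize it:

- **Long branches.** A tip is flagged only when its terminal branch length
  exceeds *both* `k` × median(terminal lengths) (default k = 5) *and* the
  Tukey upper fence Q3 + 1.5·IQR. The conjunction avoids flagging trees
  whose branches are uniformly long. Trees with fewer than `min_tips`
  (default 10) tips are refused — the null spread is not estimable.
- **Taxon inconsistency.** For each tip, the `m` (default 5) nearest other
  tips by patristic distance are collected (ties broken by tip id); the tip
  is flagged when fewer than 2 of them share its phylum. Nearest-neighbour
  analysis is used instead of clade membership because trees at this stage
  are effectively unrooted and "clade" is ill-defined without a root. With
  m = 1 at most one neighbour can match, so every tip is flagged; m ≥ 3 is
  the sensible range.

The published workflow re-BLASTs flagged sequences against NCBI to confirm
parasite contamination (nematodes, trematodes, mites). That external
round-trip needs network access and is out of scope; the screens produce a
report for manual follow-up instead.

## Motif grammar and N-terminal analysis

Degenerate patterns use the field's notation: residue literals, `x` for
any canonical residue, `[A/B]` alternations. The stock checks are the
catalytic-subunit starts `MGNxxxx[K/R]` (chordate) and `MGNxxxxK`
(invertebrate, anchored at residue 1), the hydrophobic anchor `FxxxW`, the
decapod-specific `MATL[M/T/A]A[F/T]`, the AKAP-binding `IxI`/`VxV` checks
of RII docking domains, the autoinhibitory-site motifs `RRx[A/G]` (RI
pseudosubstrate) and `RRxS` (RII phosphorylatable substrate), and the G2
myristoylation glycine. `X` (unknown residue) never satisfies any motif
position, including `x`: ambiguous data should not silently pass motif
checks.

The N-terminal region of a sequence runs from residue 1 to one before the
first core domain (kinase or cAMP-binding). The autoinhibitory-site scan is
restricted to the linker between the docking domain (or the sequence start)
and the first cAMP-binding domain when annotations exist — this avoids
spurious `RRxS` hits inside cAMP-binding domains — and falls back to a
whole-sequence scan otherwise. A sequence whose linker carries both
`RRx[A/G]` and `RRxS` is typed *ambiguous* rather than forced into RI/RII.

**Glycine-rich detection.** The published description is qualitative
("long stretches of glycine residues"), so the criterion here is a sliding
window: a region is glycine-rich when some window of `window` residues
(default 25) has G fraction ≥ `min_frac` (default 0.4). Both knobs are
exposed; the defaults are calibrated so the GLY-class synthetic exemplars
(40-residue tracts at ~76 % glycine, the magnitude seen in the published
alignments) are detected while ordinary N-termini (~7 % background glycine)
are not. Overlapping qualifying windows merge into maximal regions.

**Consensus.** Per alignment column over non-gap entries: emit the residue
when its frequency ≥ `single_threshold` (default 0.7); else `[A/B]`
(alphabetical order) when the two most frequent residues jointly reach
`pair_threshold` (default 0.7) and each reaches 0.2; else `x`; a column
with gap fraction > 0.5 emits `-`. The published consensus strings came
from a plotting script whose thresholds are not stated; these defaults
reproduce the expected strings on clean alignments (e.g. an even K/R split
yields `[K/R]`) and are exposed as parameters.

## Grouped identity/similarity

Pairs are aligned globally (Needleman–Wunsch, affine gaps, BLOSUM62; gap
run of length L costs `gap_open + (L−1)·gap_extend`, defaults 10/0.5,
terminal gaps penalized). The published study aligned pairs with a
structure-informed iterative aligner; re-implementing it is out of scope,
so printed values are reproduced within a tolerance (±2 percentage points
in the acceptance check) rather than bit-exactly, and all alignment
parameters are exposed for calibration.

Identity is the percentage of alignment columns with equal residues;
similarity additionally counts columns whose residues share a group:
**GAVLI, FYW, CM, ST, KRH, DENQ, P**. The denominator is the full
alignment column count by default (gap columns count and are neither
identical nor similar); a `shorter`-sequence denominator is available
because the convention behind the published tables is not stated. `X`
matches nothing, not even itself. Values are kept at full precision
internally and rounded to one decimal only at the reporting layer.

The per-column MSA conservation profile reports, for each column where the
reference row is ungapped, the percentage of *non-reference* rows matching
the reference residue (the reference trivially matches itself), binned
strictly: >80, >60, >40, ≤40.

## Architecture classification and nomenclature

Families are called by a rule table over domain annotations, in order:
PKA-R (≥ 2 cAMP-binding; docking domain optional, its absence recorded),
PKN (≥ 1 HR1 + kinase), aPKC (PB1 + single C1 + kinase), cPKC (C1 before
C2 + kinase), novel PKC (C2 before C1 + kinase), PKA-C (kinase only, with
N-terminal evidence: an anchored MGN start, the MATL motif, FxxxW in the
N-terminal region, or a glycine-rich N-terminus — the GLY isoforms lack
the MGN start but keep FxxxW). Anything else is `unknown`. Annotation sets
with conflicting domains overlapping more than half their span are
rejected as contradictory.

Subtypes: PKA-C isoforms are typed C_GLY > C_D1 > C_1 when several signals
fire — a glycine tract is the rarest, most specific feature, so it takes
priority (the order is a package choice; the published isoform types are
disjoint observations). PKA-R subunits are typed by the autoinhibitory
motif; RII with a glycine-rich N-terminus becomes RII_GLY. Novel-PKC
delta-like vs epsilon-like cannot be told apart by architecture (both are
C2-before-C1) and is resolved by nearest reference exemplar under grouped
similarity (ties: identity, then exemplar id), mirroring how the published
classification leaned on similarity tables; such calls carry
`nearest_reference_only` confidence.

Decapod names are issued per species in order of characterization:
cPKC_D1, nPKC_D1δ, nPKC_D1ε, aPKC_D1, PKN_D1–Dn, PKA-C_1, PKA-C_GLY1/2,
PKA-C_D1, PKA-RI_1/RI_D1, PKA-RII_GLY, PKA-RII_D1. The ordinal is a naming
convention (registration order), not a biological claim. Chordate isozyme
names (Cα/Cβ, RIα, PKCδ, …) are never assigned to non-chordate inputs:
non-chordate sequences do not segregate into those isozyme clades.

## Synthetic data generator

The generator emulates the structure the analysis assumes, with planted
ground truth, so every stage runs offline:

- Fixed class templates (independent of the simulation seed) carry the
  class N-terminal signature, a subfamily-appropriate domain layout at
  realistic proportions (PKA-C ≈ 300–330 aa with a C-terminal kinase
  domain; regulatory subunits ≈ 380–410 aa with D/D + linker + two
  cAMP-binding domains; PKN 900 aa with three HR1 repeats), and, for GLY
  classes, a 40/32-residue tract at ~76 % glycine.
- Within one species all PKA-C classes share an identical catalytic core
  (mutated once per species); isoforms differ only N-terminally — matching
  the observation that decapod PKA-C isoforms are 100 % identical from the
  catalytic domain to the C-terminus within a species.
- Point substitutions at per-residue rate μ (default 0.05, capped at 0.3)
  are drawn from residue-frequency-weighted proposals excluding the
  original residue; planted motif *literals* are immune (wildcard positions
  may mutate — the motif still matches). Single-residue indels (default
  rate 0.005) never fall inside planted motifs, glycine tracts, or within
  3 residues of a domain boundary; domain coordinates and planted spans
  are shifted consistently, so the truth table stays exact.
- Hit tables plant keep/reject E-value bands around the transcriptome
  threshold (log-uniform in [1e-180, 1e-121] vs [1e-119, 1e-60]) and
  decoys at ≥ 1e-50, so filter recovery is checkable exactly.
- Contaminated trees: two clean phylum clades (sequential random
  coalescence topology), branch lengths iid Gamma(shape 3, scale 1/3).
  Gamma rather than exponential lengths is deliberate: exponential
  terminal branches have a heavy enough tail that natural 5×-median
  outliers appear in ordinary 40-tip trees, which would make a planted
  long branch indistinguishable from the null. Planted long branches are
  set to max(own length, median terminal) × U(10, 100); mislabeled tips
  keep their position but are recorded under the foreign phylum.

What the generator does **not** emulate: empirical substitution models
(no LG/WAG), rate heterogeneity, alignment uncertainty, fragmentary
transcripts, or realistic phylogenetic signal. Passing recovery tests on
this generator therefore demonstrates the correctness of the decision
rules under their stated assumptions — not performance on raw
transcriptome data, where incomplete sequences and annotation errors
dominate.

## Problem sizes and numerical choices

Recovery checks run at the study conditions: μ = 0.05, 20 sequences per
class across the ten classes, three replicate simulations; tree QC on
40-tip trees with 2 long-branch and 1 mislabeled contaminant, three
replicates. Alignment-oracle equivalence is checked exhaustively against a
brute-force enumeration of all global alignments for pairs of length ≤ 6
over a 4-letter alphabet; the motif engine against a regex oracle on
sequences ≤ 50 aa. Co-optimal alignments resolve to the aligner's
canonical first traceback; consensus frequency ties break alphabetically;
nearest-reference ties break by identity then exemplar id. Degenerate
inputs (empty alignments, all-X sequences, windows longer than their
search span, trees too small for outlier statistics) are refused or
flagged rather than silently handled.

## Known limitations

- The published pairwise identity/similarity tables can only be recomputed
  from the named accession sequences; `scripts/fetch_reference_sequences.py`
  downloads them (network required) into `data/table2_sequences.fasta`,
  after which the corresponding acceptance test compares the computable
  cells within ±2 percentage points. Without that file the test fails with
  an explanatory message.
- Homology search, multiple alignment, and tree inference are consumed,
  never performed; the gap-fraction column trimmer is plain plumbing, not
  a reimplementation of informed trimming.
- RI_1 vs RI_D1 and RII_GLY vs RII_D1 have no printed motif rule; they are
  resolved by nearest reference when a panel is supplied and otherwise
  default to registration order.
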