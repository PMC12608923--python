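# crustakin

Sequence characterization of crustacean PKA and PKC protein kinases.

Invertebrate PKA (cAMP-dependent protein kinase) and PKC (protein kinase C)
sequences are poorly characterized: database annotation pipelines propagate
chordate isozyme names (Cα/Cβ, RIα/RIIβ, PKCδ/ε/ι …) onto non-chordate
proteins that do not actually fall into those isozyme clades. `crustakin`
implements the bioinformatic workflow for doing this properly in decapod
crustaceans and other non-model taxa:

- **curation** — E-value/identity/domain-completeness filters for
  reference hits (E ≤ 1e-70, identity > 60 %, ≥ 1 complete domain) and
  transcriptome hits (E ≤ 1e-120), plus ≥ 2-complete-domain gating for
  regulatory subunits and PKCs;
- **tree QC** — flagging of contaminant tips by terminal-branch-length
  outliers (length > k·median **and** > Q3 + 1.5·IQR) and by
  taxon-inconsistent patristic neighbourhoods (an "arthropod" tip whose
  nearest neighbours are all nematodes);
- **motifs** — a degenerate-pattern engine (`MGNxxxx[K/R]`, `MGNxxxxK`,
  `FxxxW`, `MATL[M/T/A]A[F/T]`, `RRx[A/G]`, `RRxS`, `IxI`/`VxV`, G2),
  N-terminal region and glycine-rich tract detection, and frequency-based
  alignment consensus;
- **identsim** — global Needleman–Wunsch alignment (affine gaps, BLOSUM62)
  and the grouped identity/similarity statistic with the groups
  GAVLI, FYW, CM, ST, KRH, DENQ, P; all-pairs matrices in the published
  layout (identity above the diagonal, similarity below) and binned MSA
  conservation profiles;
- **classify** — domain-architecture rules for PKA-C, PKA-R (RI/RII via
  the autoinhibitory motif), conventional/novel/atypical PKC and PKN, with
  decapod isoform names (PKA-C_1, PKA-C_GLY1/2, PKA-C_D1, PKA-RII_GLY,
  cPKC_D1, nPKC_D1δ/ε, aPKC_D1, PKN_D1–3) issued per species in order of
  characterization;
- **simulate** — a synthetic-data generator with planted motifs, shared
  per-species catalytic cores, glycine tracts, E-value bands, and
  contaminated trees, so the entire pipeline is testable with no
  downloads.

## Worked example

The grouped similarity statistic on a 7-residue pair (A~G and A~I fall in
the GAVLI group):

```python
>>> from crustakin import SequenceRecord, global_align, ident_sim
>>> aln = global_align(SequenceRecord(id="a", residues="MGNAAAK"),
...                    SequenceRecord(id="b", residues="MGNAGIK"))
>>> ident, sim = ident_sim(aln)
>>> round(ident, 1), round(sim, 1)
(71.4, 100.0)
```

5 of 7 columns are identical (71.4 %), and the two mismatches are
within-group substitutions, so similarity is 100 %.

A complete simulated run from the shell:

```sh
crustakin simulate --seed 3 --outdir sim/
crustakin classify --fasta sim/seqs.fasta --domains sim/domains.tsv \
    --out sim/classes.tsv
head -3 sim/classes.tsv
```

```
seq_id	family	subtype	decapod_name	confidence	evidence
Synthspecies_01_PKA-C_1_1	PKA-C	C_1	PKA-C_1	architecture+motif	architecture=kinase only;MGNxxxx[K/R]=present at 1;FxxxW=present in N-terminal region;subtype=C_1
Synthspecies_01_PKA-C_D1_1	PKA-C	C_D1	PKA-C_D1	architecture+motif	architecture=kinase only;MATL[M/T/A]A[F/T]=present in N-terminal region;FxxxW=present in N-terminal region;subtype=C_D1
```

Each row carries the family call, the N-terminal subtype, the issued
decapod name, and the evidence trail (which motifs fired and where). The
other subcommands — `curate`, `treeqc`, `motifs`, `identsim`, `profile`,
`run` — follow the same pattern; `crustakin run --config cfg.json`
executes the whole pipeline and writes per-stage TSVs plus a JSON run
summary.

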