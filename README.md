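# mitoblocks

Comparative structural analysis of organellar genomes: locally collinear
block (LCB) decomposition, large-repeat detection, repeat-mediated inversion
scenarios, and comparative RNA-editing prediction — the tool chain needed to
characterise a rearranged plant mitochondrial genome against a collinear
reference.

Plant mitochondrial genomes, and liverwort mitogenomes in particular, are
usually structurally conserved: gene order is essentially frozen across deep
phylogenetic splits. When an exception turns up, the questions are always
the same. How many collinear blocks do the rearranged and reference genomes
share, and in what signed order? Are there large, near-identical repeat
pairs sitting at the block junctions? And can a short series of
homologous-recombination events between inverted repeat copies explain the
observed order? `mitoblocks` answers each question with a tested,
deterministic implementation, and ships a synthetic-genome generator so the
whole pipeline is verifiable against planted ground truth without any
sequence downloads.

## The model

**Blocks and signed permutations.** A pairwise comparison decomposes the two
genomes into LCBs *A, B, C, …* (maximal regions with conserved order and
orientation). The observed genome's structure is the signed permutation π
read off the block order, e.g. the canonical rearranged case

> A, D, B(inverted), C(inverted), E  ⟷  π = (1, 4, −2, −3, 5).

An inversion ρ(i,j) reverses π_i…π_j and flips the signs. The minimal
number of inversions from the identity to π is found by breadth-first
search (exact for the n ≤ 10 block counts that occur in organelle work).

**Repeat-mediated recombination.** Two copies of a repeat in *inverted*
relative orientation can pair and recombine, inverting the intervening
segment; copies in direct orientation excise it instead, so they never
mediate an inversion. The constrained scenario search therefore allows
ρ(i,j) only when some repeat pair currently has one copy at the junction
left of block i and the other at the junction right of block j, in inverted
orientation — and re-tracks every repeat's junction position and relative
orientation after each event. All minimal scenarios are reported.

**Repeats.** A repeat pair is a maximal gapless diagonal window (direct or
inverted) containing no run of ≥3 consecutive mismatches, trimmed to
terminal matches, at ≥ min_len (default 100 bp) and ≥ min_identity
(default 90%). Exact 21-mers seed detection; a brute-force all-diagonal
scan provides an exact oracle in the tests.

**RNA editing.** Organellar transcripts are edited C→U and U→C. Query CDS
are translated and aligned against reference proteins; where the query
residue differs from the reference consensus and a single C↔U substitution
at one codon position restores it, a site is called and classified
(missense, start gain ACG→AUG, stop gain CAA/CGA→UAA/UGA, ORF-restoring
removal of internal stops). Summaries report counts, percent C→U, and
sites per CDS bp.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
conditions (a ~162.6 kb circular mitogenome pair related by two
repeat-mediated inversions, carrying ten planted repeat pairs):

```text
$ python analysis/01_simulate.py
seed 42: two 162,574 bp circular genomes, 70 genes each
planted 10 repeat pairs (107–566 bp); applied 2 inversions; expected block order (1, 4, -2, -3, 5)

$ python analysis/02_repeat_census.py
10 repeat pairs ≥100 bp (107–566 bp), 3.5% of the genome
two longest (the junction pairs): 566 bp at 97.7%, 435 bp at 95.9%
planted truth recovered exactly: True

$ python analysis/03_collinear_blocks.py
83 anchors -> 5 collinear blocks, 2 inverted
observed block order: (1, 4, -2, -3, 5) (truth: (1, 4, -2, -3, 5))
repeat pairs sitting on block junctions: ['P1', 'P2']
all junctions intergenic: True

$ python analysis/04_recombination_scenarios.py
unconstrained inversion distance (1, 2, 3, 4, 5) -> (1, 4, -2, -3, 5): 2
1 minimal repeat-mediated scenario(s):
  invert blocks 3–4 via R1 ; invert blocks 2–3 via R2
  orders visited: (1, 2, 3, 4, 5) -> (1, 2, -4, -3, 5) -> (1, 4, -2, -3, 5)
pipeline (from sequence alone): permutation (1, 4, -2, -3, 5), 1 scenario(s)
```

Reading this: the detector finds exactly the ten planted pairs, with the
two largest (566 bp at 97.7% identity, 435 bp at 95.9%) sitting on block
junctions; five blocks reconstruct the signed order (1, 4, −2, −3, 5); and
the constrained search proves that exactly one minimal two-event
recombination history — first through the large junction pair, then through
the second — produces the observed structure. `analysis/05_editing_summaries.py`
prints the editing statistics for the two organelles (60.1% / 39.9% C→U vs
U→C in the plastome, 76.6% C→U in the mitogenome, a 1.6× editing-site
density ratio) from the published site counts and CDS totals.

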