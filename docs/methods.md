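# Methods

## Data model and coordinates

Genomes are circular DNA strings with typed features (CDS, tRNA, rRNA,
intron, exon, pseudogene, spacer). All internal coordinates are 0-based
half-open; GFF3's 1-based closed convention exists only at the file
boundary, and the round trip is lossless. A feature crossing the origin is
kept in one piece with `end > length` (wrap notation) rather than split;
`rotate` renormalises after moving the origin. Ambiguity codes are retained
in sequences but excluded from GC content and treated as mismatches in
every comparison — they can never seed or extend a match.

## Repeat detection

The repeat model is deliberately gapless: a repeat pair is a maximal window
along one diagonal (direct) or antidiagonal (inverted) of the genome's
self-comparison that contains no run of three or more consecutive
mismatches, trimmed so both ends are matches, and passing the length and
identity thresholds (defaults 100 bp and 0.90; the cross-genome survey uses
400 bp and 0.90). The three-mismatch stop makes the window a purely local,
seed-independent object: wherever an exact k-mer (default k = 21) lands
inside it, extension reaches the same boundaries. That yields three
properties the tests rely on:

- a brute-force all-diagonal scan is an *exact* oracle, not an
  approximation (`brute_force_repeat_pairs`, checked on ≤1 kb genomes for
  both orientations);
- detection is invariant under rotation and covariant under
  reverse-complement;
- planted pairs are recovered with their exact length and identity.

We chose the run-bounded window over the alternative "extend while running
identity stays above the threshold" rule because the latter depends on
which seed starts the extension and can creep past a repeat's true boundary
on chance flank matches, making exact planted recovery impossible to
guarantee. The cost is that a qualifying sub-window inside a longer,
lower-identity window is not reported separately; for junction-repeat
analysis, where repeats are discrete planted or biological units, this is
the behaviour wanted. Percent identities are reported rounded half-up to
one decimal; full precision is kept internally. Copies overlapping by ≥50%
of the pair length, self-matches and palindromic centres are discarded; a
window that would wrap the entire circle (perfect tandem-array degeneracy)
is skipped — tandem repeats are out of scope. Complexity is O(genome +
seed-pair extensions); a 162 kb genome takes well under a second.

## Collinear blocks

Anchors are maximal exact matches unique in both genomes on either strand,
built by intersecting unique k-mer sets (k = `min_anchor_len`, default
25 bp) and merging runs along diagonals; circular sequences are indexed
with wrap padding. Uniqueness is load-bearing: sequence inside a
near-identical repeat copy is not unique, so anchors stop at repeat edges
and block boundaries fall exactly at the junction repeats. Greedy chaining
joins strand-consistent, B-monotone anchors with both gaps ≤ `max_gap`
(default 5000 bp); chains spanning < `min_block` (default 1000 bp) are
dropped, and surviving adjacent compatible chains re-merged, which removes
the tiny spurious chains that mismatch-containing k-mers inside repeat
copies occasionally produce. Block boundaries sit at the outermost anchor
endpoints. `max_gap` must stay below the smallest block displacement in the
data; the defaults suit ~160 kb genomes with kilobase spacers, and the test
on 40 kb genomes scales it down accordingly.

An exact match can run a few bases past a rearrangement breakpoint by
chance (probability 1/4 per base), so adjacent block intervals may overlap
by single-digit amounts; `blocks_to_permutation` tolerates ≤ 50 bp and
raises beyond that, which in practice only a chaining bug produces.

The block order is linear with the origin as a fixed linearisation point —
appropriate when, as here, the first and last blocks are unrearranged and
the origin lies inside conserved sequence. Circular rotation equivalence of
permutations is intentionally not implemented.

## Inversion model and scenario search

Block orders are signed permutations; ρ(i,j) reverses the segment and flips
its signs. `inversion_distance_bfs` searches all inversions exhaustively
(n ≤ 10 guard; the biological case is n = 5) and reports failure beyond
`max_depth` explicitly rather than truncating.

The recombination-constrained search allows an event only when a repeat
pair in *inverted* relative orientation flanks the segment (one copy at
each bounding junction). After an event, placements are re-tracked:
junctions strictly inside the span reflect (k → i−1+j−k); the two boundary
junctions are the breakpoints themselves and stay put; a pair's relative
orientation flips iff exactly one copy lies strictly inside. Keeping the
boundary junctions fixed is the physically correct reading of a crossover
inside the repeat copies — verified in the generator, where sequence-level
recombination leaves a copy in place at each breakpoint. All minimal-length
scenarios are returned (sorted by event segments), since a single observed
genome cannot distinguish between equally short histories.

The pipeline observes placements on the extant (rearranged) genome, so it
searches backward from the observed permutation to the identity and
reverses the event list; inversions are involutions, so the reversed
scenario replays exactly and is validated on construction.

## Synthetic study conditions

The generator emulates a liverwort-scale mitogenome: 162,574 bp circular,
70 non-overlapping genes of mean 900 bp (≈39% coding) in jittered even
slots, i.i.d. background at GC 0.447. `make_two_inversion_case` partitions
it into five gene regions via four junction spacers, plants an inverted
566 bp pair with 13 mismatches flanking regions C–D, a direct 435 bp pair
with 18 mismatches on the A–B and C–D junctions, and eight decoy pairs
(107–389 bp, ≥90% identity, mixed orientation) in region-internal spacers
— ten pairs in all. Recombination through the first pair inverts C–D
(order A, B, −D, −C, E) and re-orients the inner copy of the second pair,
whose recombination then produces the final order A, D, −B, −C, E =
(1, 4, −2, −3, 5). Crossovers sit at copy midpoints (left half from one
copy, right half from the other), which keeps both copies detectable and
both identities exact after the events.

Three generator guarantees make downstream recovery exact rather than
approximate, all fixed by construction: planted mismatch columns are ≥3
apart (no run ever reaches the detector's stop threshold) and leave a ≥24 bp
clean stretch in each half (a seedable 21-mer survives the midpoint
crossover's column shuffling); after all events the three alignment columns
beyond each copy end are hardened to mismatches, so extension stops at the
planted boundary; and the construction self-validates these invariants on
the final genome, re-planting from derived subseeds if violated. RNG
streams are domain-separated per stage (`[seed, stage]` seed sequences) so
the same user seed never yields correlated background and repeat sequences.

What the generator does *not* emulate: codon structure in genes, mutational
divergence between the two genomes outside the planted differences, indels,
tandem repeats, nested or overlapping rearrangements, and chimeric
substoichiometric forms. Passing tests therefore demonstrate correctness of
the block/repeat/scenario machinery under clean rearrangement signal, not
robustness to deep sequence divergence — for diverged genome pairs the
`--gene-anchors`-style annotation-based comparison is the right tool and is
out of scope here.

## RNA-editing prediction

Queries are translated (standard code, table 1 — plant organelles use it;
configurable) and aligned as proteins to each reference (Biopython global
aligner, BLOSUM62, gap open/extend −11/−1); references under 50% alignment
identity are ignored (a coarse stand-in for an E-value cutoff), and indel
columns make no calls. The consensus is a strict majority of mapped
reference residues; ties give no call. A site is emitted when one C↔U
substitution at one codon position recreates the consensus; if several
single edits would, C→U is preferred over U→C and earlier codon positions
over later, one site per codon. Effects: ORF-restoring (internal stop
removed), stop gain (consensus is a stop), start gain (codon 0, ACG→AUG),
silent, missense. Every emitted site satisfies a checked invariant: editing
`codon_before` reproduces `codon_after`, whose translation is `aa_after`.

Percentages are rounded half-up to one decimal, matching the reporting
precision of organelle editing surveys; all derived figures are computed
from stored counts, never stored separately. The mitochondrial U→C share
computes to 23.4% (52/222) from its counts.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| repeat `min_len` / `min_identity` | 100 bp / 0.90 | organelle junction repeats of interest exceed 100 bp; 0.90 matches the cross-genome survey threshold |
| repeat seed `k` | 21 | specific in 10⁵–10⁶ bp genomes; guaranteed seedable in planted repeats |
| mismatch stop run | 3 | separates ≥90%-identity repeat bodies from flanking noise |
| anchor `min_anchor_len` | 25 | unique in both genomes at these sizes with overwhelming probability |
| chain `max_gap` | 5000 bp | bridges spacer/repeat anchor deserts in ~160 kb genomes; must stay below the smallest block displacement |
| `min_block` | 1000 bp | suppresses micro-blocks from repeat copies; real LCBs are tens of kb |
| junction `window` | 100 bp | junction repeats abut boundaries (distance 0); window covers boundary jitter |
| scenario `max_events` | 4 | exhaustive and instant for n ≤ 5 blocks |
| editing `min_ref_identity` | 0.5 | drops unrelated references without suppressing diverged true homologs |

## Known limitations

Gapless repeats only (no indel-tolerant identity); pairwise genome
comparison only (no multi-genome alignment); linear block model with a
fixed origin; no Hannenhalli–Pevzner polynomial distance (BFS suffices for
organelle block counts); editing prediction is comparative only and cannot
call sites without informative references, and does not model non-coding or
insertion/deletion editing.
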