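# Methods

## The problem and the model

A hairpin-bearing non-coding locus is modelled as

```
5'-flank  +  left arm  +  loop  +  reverse_complement(left arm)  +  3'-flank
```

where the arms (inverted repeats, ≥18 bp in the datasets this package
targets) can base-pair into a stem and the intervening loop (~25–27 bp) is
recurrently replaced by its own reverse complement ("inversion"). Because
the two loop orientations are mutually reverse-complementary, an alignment
that stacks them columnwise scores most loop positions as substitutions.
The package quantifies the consequences for distance-based species
identification and removes them by orientation normalization.

## Hairpin detection

`find_inverted_repeats` reports every maximal hairpin: equal-length arms
around a loop of at most `max_loop` bp, where the reverse complement of the
left arm differs from the right arm at no more than `max_arm_mismatch`
positions. Two conventions make the annotation well defined:

* **Arms begin and end on exact complementary pairs.** A mismatched pair at
  the loop boundary belongs to the loop, not the stem; without this rule the
  mismatch budget lets arms creep into the loop and the reported loop
  shrinks below its structural extent. A consequence is that a deletion
  removing the innermost base of one arm shortens the detectable arm by one.
* **Maximality.** For a fixed loop interval the interior mismatch count is
  non-decreasing in arm length, so each loop interval contributes exactly
  one (maximal) hairpin; nested duplicates do not arise.

Ambiguity codes never pair. Candidates are sorted by arm length (desc),
loop length (asc), then position. Defaults — `min_arm=18`, `max_loop=40`,
`max_arm_mismatch=2`, `min_callable_loop=10` — are sized for a
trnH-psbA-like locus, where all reported arms are at least 18 bp and loops
25–27 bp; the mismatch budget is exposed because real arms may carry
lineage-specific substitutions.

`anchor_shared_hairpin` makes per-record detection consistent across a
dataset: a left-arm consensus (per-position majority over each record's best
exact-arm hit, right-justified at the loop boundary) is built once, and each
record's candidate closest to that consensus is chosen. Records whose best
loop is shorter than `min_callable_loop` — e.g. after a large loop deletion
— are flagged degenerate; records without detectable arms get an empty
degenerate annotation. The detector is validated against an exhaustive
oracle that enumerates all (loop interval, arm length) candidates on the
complement pair matrix.

## Orientation calling and the matrix pair

Orientation labels are dataset-relative and arbitrary: the reference loop is
that of the lexicographically first non-degenerate sequence id (invariant to
input order). Each loop is compared by Levenshtein edit distance (edlib) to
the reference loop and to its reverse complement — edit distance rather than
Hamming because real loops carry 1-bp indels. Closer to the reference → "A",
closer to the flipped reference → "B"; ties and degenerate loops →
"undetermined". `build_matrix_pair` flips the loop (an involution that
changes nothing outside the loop interval) of every sequence not already in
the target configuration; undetermined sequences pass through unaltered into
both matrices, and the flip is recorded as a 0/1/? character so the
inversion event itself remains available as a single binary character
rather than a block of spurious substitutions.

## Alignment

`progressive_align` is a conventional progressive aligner: a guide tree from
average-linkage clustering of k-mer distances (k=8; smaller k saturates on
few-hundred-bp loci and produces noise trees), then profile–profile merges
with an affine-gap Gotoh DP on column frequency vectors. Defaults
(`match=+1, mismatch=−1, gap_open=10, gap_extend=0.5`, terminal gaps free)
are DNA-typical; no claim of bit-compatibility with any published aligner is
made, and externally produced aligned FASTA can be imported to bypass the
module. Pairwise alignment is the same DP on single-sequence profiles and is
checked against brute-force enumeration of all alignments on short strings.

Short sequences whose 5' region misaligns against a profile of long ones are
handled by `realign_leading_region(n_cols=45, short_threshold=300)`: the
residues of each short row falling in the first `n_cols` columns are
re-placed, by a small DP, against the profile of the long rows only —
long rows and all other columns are untouched, so the operation preserves
every row's ungapped sequence and is idempotent. The "edited" pipeline flag
is exactly "unedited + this operation".

## Distances and the barcode gap

All distances are uncorrected p-distances (mismatches / compared sites).
Gapped characters are excluded; ambiguity codes are treated like gaps. Two
exclusion modes exist: pairwise deletion (drop a column only for the pair
compared; default for the full matrix feeding trees) and complete deletion
within a set (drop columns gapped in any member; default for conspecific
statistics, where length variants would otherwise leak into the counts).
The per-species report gives n, variable sites (count and % of mean
ungapped length), maximum intraspecific distance, minimum interspecific
distance against all remaining sequences, and a `gap_violated` flag
(max intra > min inter). NA distances (no comparable sites) are excluded
from the extrema with a logged count.

## Trees

NJ (canonical Q-criterion, negative branch lengths clamped to 0, final
three-cluster closed form) and UPGMA (size-weighted average linkage,
ultrametric by construction) break ties lexicographically on the clusters'
smallest leaf ids, so both are invariant to input order. Fitch parsimony
treats gaps and ambiguity as missing data. `parsimony_search` is exhaustive
over all unrooted topologies up to 9 taxa and otherwise NNI hill-climbs from
the NJ tree with a seeded neighbour order; replicating a full TBR search
with large tree buffers is deliberately out of scope, as the parsimony
results are used qualitatively. Bootstrap support is column resampling with
a seeded generator; datasets without variable sites get NaN supports.
`conspecific_cluster` asks whether any edge of the unrooted tree separates
exactly the species' leaves — a rooting-free formulation of "the species
clusters together".

A known degeneracy, verified against an independent NJ implementation:
when several conspecific sequences are *exactly* identical and embedded in
a cluster of close species, NJ's arbitrary resolution of the resulting
zero-length polytomy need not place them as a clade, so
`conspecific_cluster` can be false even though the sequences are
indistinguishable. UPGMA does not exhibit this on the datasets used here.
Real datasets almost always carry residual intraspecific variation that
breaks the ties.

## Simulator

`simulate` draws a pure-birth (Yule) species tree normalized to height 1,
hangs a star of `n_per_species` tips (branch `within_species_depth`, default
0.1) under each species, builds a root locus `flank + arm + loop +
revcomp(arm) + flank`, and evolves it branchwise with:

* substitutions — Poisson(`sub_rate`·length·branch), equal-rate base
  replacement; by default arms are protected (`protect_arms=True`), because
  across real datasets the arms are effectively invariant (they are what
  makes the hairpin recognizable), and unprotected boundary substitutions
  would make detectability itself stochastic;
* indels — Poisson(`indel_rate`·length·branch), 1–3 bp, never touching the
  arms so planted coordinates stay defined;
* slippage — ±1 bp in mononucleotide tracts ≥5 bp, Poisson per tract;
* inversions — Poisson(`inversion_rate`·branch) reverse-complement
  replacements of the current loop; parity defines the leaf's orientation
  truth ("A" = root form).

The three outermost loop pairs are forced non-complementary so the
stem–loop boundary is structurally unambiguous (otherwise chance pairing
lets the maximal stem absorb loop bases and "planted coordinates" would be
ill-defined). Defaults (`n_species=21, n_per_species=3, root_length=380,
arm_len=18, loop_len=27, sub_rate=0.03, indel_rate=0.001,
slippage_rate=0.05, inversion_rate=2.0`) give a locus in the 200–500 bp
range with a few percent interspecific divergence and frequent orientation
polymorphism. Every event is logged (type, branch, position), and per-leaf
final hairpin coordinates are recorded, so tests can condition on what
actually happened rather than on expectations.

`make_polymorphic_fixture` rejection-samples seeds until (a) at least *k*
species carry both orientations and (b) every species satisfies the true,
orientation-corrected barcode gap (max intraspecific < min interspecific
edit distance on loop-canonicalized sequences). Condition (b) encodes the
study design being emulated: recognized, distinct species whose gap holds
once inversions are factored out — the analysis then asks whether
unrecognized inversions mask it. With `k=0` the first seed is accepted
unconditionally.

## The synthetic study stand-in

`synthetic_study.build_study_standin()` constructs, deterministically and
entirely in code, a 35-sequence / 21-species dataset with the structure of
the published Gentianaceae design: six polymorphic species with 3–4
sequences each, 15 singletons, 18 bp arms, 25 bp loops in the
*Gentianopsis*-like genus and 27 bp elsewhere, sequence lengths 214–489 bp,
a poly-A length variant, two shared indels marking one *Frasera* pair, and
one sequence (the *Comastoma* analogue) whose loop is deleted to 3 bp plus
1 bp of arm, leaving its orientation uncallable. Planted substitution
counts are placed in flank zones never deleted by any sequence, so exact
quantities emerge from the pipeline by construction: a 19/15/1 orientation
partition (the original study assigned the deletion-bearing sequence a
form from phylogenetic context, which an automated caller deliberately
refuses to do), raw variable-site counts of 17/17/17/21/23/25 collapsing to
0/0/0/0/2/4 after normalization, 5 same-orientation substitutions between
the crinita- and thermalis-like species versus 17 conspecific
opposite-orientation differences, a barcode gap violated in 5 of 6
polymorphic species raw and 0 of 6 uniform, and UPGMA conspecific
clustering of only the algida-like species raw versus all six uniform.

It is **not** the real data: flanks and loop content are random under a
fixed seed, interspecific distances are only order-of-magnitude realistic,
and printed distance values that depend on one specific aligner's gap
placement inside the loop (which excludes loop columns from the distance
denominator) are reproduced as patterns, not to five decimals. Passing
tests on the stand-in therefore demonstrate that the machinery recovers
planted structure of the study's shape, not that it reproduces the exact
historical alignment.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout. All randomness flows through
seeded `numpy` generators; reruns are byte-identical. Negative NJ branch
lengths are clamped to zero and logged. Zero comparable sites → NaN
distance, excluded downstream with a log entry. Single-record alignment and
single-species gap tables degrade gracefully (warning, NA fields); trees
require ≥3 sequences and are skipped otherwise by the pipeline. Problem
sizes in the test suite and acceptance script (hundreds of bp, tens of
sequences, hundreds of oracle replicates) are desk-scale choices that keep
the full validation run in well under the times a laptop user would tolerate.
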