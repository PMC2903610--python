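# loopinv

Inversion-aware analysis of hairpin-bearing plastid barcode loci.

Non-coding chloroplast spacers such as *trnH-psbA* — the leading candidate
for a supplementary plant DNA barcode — often contain a short loop (~25–27
bp) flanked by inverted repeats of ≥18 bp. The loop recurrently flips into
its own reverse complement during evolution, and these inversions occur
*within* species. A naive alignment then treats the two orientations as a
block of substitutions: a conspecific pair that differs only in loop
orientation can look more divergent than two different species that share an
orientation, inflating intraspecific distances, collapsing the barcode gap,
and misplacing sequences in identification trees.

`loopinv` packages the remedy as a pipeline for barcoding and phylogenetics
practitioners:

1. **detect** the hairpin: all maximal inverted repeats with arms of at
   least `min_arm` bp (interior mismatches up to `max_arm_mismatch`) around
   loops of at most `max_loop` bp, anchored across a dataset by an arm
   consensus;
2. **call** each sequence's loop orientation ("A" or "B", relative to an
   arbitrary dataset reference) by Levenshtein distance of the loop to the
   reference loop and to its reverse complement;
3. **flip** one orientation class to build the *uniform* matrix (loop
   replaced by its reverse complement), keeping the *raw* matrix alongside
   and recording the inversion as a single binary character;
4. **compare**: progressive multiple alignment of each matrix, uncorrected
   p-distances with gap exclusion (p = mismatches / compared sites),
   per-species barcode-gap tables (number of variable sites, max
   intraspecific p-distance, min interspecific p-distance), NJ / UPGMA /
   Fitch-parsimony trees with bootstrap support, and a conspecific-cluster
   test (does one edge of the unrooted tree separate exactly that species'
   sequences?).

A truth-labelled simulator (`loopinv.simulate`) generates stem-loop loci
evolving with substitutions, short indels, mononucleotide-repeat slippage
and Poisson loop-inversion events on a birth-process species tree, and a
deterministic synthetic stand-in dataset (`loopinv.synthetic_study`)
reproduces the structure of the published Gentianaceae study design (35
sequences, 21 species, six inversion-polymorphic species).

## Worked example

```python
from loopinv import (SimConfig, anchor_shared_hairpin, build_matrix_pair,
                     call_all, conspecific_cluster, distance_matrix, nj,
                     progressive_align)
from loopinv.distances import barcode_gap_table
from loopinv.simulate import make_polymorphic_fixture, polymorphic_species

cfg = SimConfig(seed=42, sub_rate=0.05, indel_rate=0.0, slippage_rate=0.0,
                inversion_rate=3.0, within_species_depth=0.05,
                n_species=6, n_per_species=3)
result, seed = make_polymorphic_fixture(cfg, k=2)
records = result.records

ann = anchor_shared_hairpin(records)
calls, counts = call_all(records, ann)
print(counts)
pair = build_matrix_pair(records, ann, calls, target_configuration="B")
species = {r.id: r.species for r in records}
for name, recs in (("raw", pair.raw), ("uniform", pair.uniform)):
    aln = progressive_align(recs)
    tree = nj(distance_matrix(aln))
    table = {r.species: r for r in barcode_gap_table(aln, species)}
    poly = sorted(polymorphic_species(records))
    for sp in poly:
        print(name, sp, "max_intra=%.4f" % table[sp].max_intra,
              "min_inter=%.4f" % table[sp].min_inter,
              "clusters=%s" % conspecific_cluster(tree, species, sp))
```

prints (the rejection sampler accepts seed 48):

```
{'A': 11, 'B': 7, 'undetermined': 0}
raw sp02 max_intra=0.0343 min_inter=0.0396 clusters=True
raw sp05 max_intra=0.0605 min_inter=0.0184 clusters=False
uniform sp02 max_intra=0.0079 min_inter=0.0342 clusters=True
uniform sp05 max_intra=0.0053 min_inter=0.0158 clusters=True
```

In the raw matrix sp05's intraspecific divergence (0.0605, driven almost
entirely by the ~20 loop sites that differ between orientations) is more
than three times its distance to the nearest other species, so its barcode
gap is violated and its sequences do not cluster. Normalizing the loop
orientation drops the intraspecific divergence by an order of magnitude and
restores both the gap and the clustering for every polymorphic species.

The same pipeline is available from the shell:

```bash
loopinv simulate --seed 3 --out sim.fasta
loopinv run --fasta sim.fasta --outdir out --trees nj,upgma
```

`out/` then contains the orientation report, both alignments, distance
matrices, barcode-gap tables, newick trees and a `summary.json` comparing
gap violations and conspecific clustering between the raw and uniform
matrices.

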