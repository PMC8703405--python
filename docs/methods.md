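# Methods

`mosaicpaint` reconstructs the genome composition of an inbred offspring
derived from a marker-assisted backcross. It covers the computational part
of a reference-guided assembly study: placing de novo scaffolds on a
reference, connecting them into pseudomolecules, validating the build by
locating known genes, classifying trio SNPs by parental origin, and
painting the offspring genome in fixed windows. Because the sequencing
reads behind such studies are rarely released, the package ships a
first-class synthetic-data generator that reproduces the *structure* of
the problem — two related founder genomes, a third unknown source, a
segment-wise mosaic offspring, fragmented scaffolds, a trio VCF — with
ground truth for every stage.

## Synthetic data model

Founders. Each chromosome starts from an i.i.d. random ancestral sequence.
Polymorphic sites are drawn per bp at `snp_rate` (default 0.005, i.e. one
site per 200 bp — a deliberately dense, desk-scale setting that gives
every 50 kb window ~100+ informative SNPs). Every site is biallelic: the
ancestral allele plus a minor allele private to exactly one founder,
chosen with probabilities `minor_founder_probs = (0.25, 0.25, 0.50)` for
(parent A, parent B, unknown U). The doubled rate for U models an
unrelated contaminant source that is more diverged from both parents than
they are from each other. This asymmetry is what makes U segments
identifiable: at a U-private site an offspring segment from U matches
neither parent ("other"), while at a parent-private site it necessarily
mimics one parent. With symmetric divergence, two thirds of the sites in a
U segment would vote A-like or B-like in equal proportion and the window
dominant class would be a coin flip; no windowed classifier can recover U
under that model, so we do not simulate it.

Offspring. A copy-paste mosaic: segment lengths are `min_segment_len`
(default 100 kb) plus an exponential with complementary mean
(`mean_segment_len` default 150 kb), origins i.i.d. from `target_fracs`
(default 0.61/0.23/0.16, the kind of recurrent/donor/unknown split seen
after a single backcross with background selection). Adjacent same-origin
segments are merged, so the truth segments are maximal runs tiling each
chromosome. All samples are fully homozygous — the lines are inbred;
residual heterozygosity is deliberately not modelled and heterozygous
genotypes are handled purely as a classifier decision (below).

Scaffolds. The offspring is partitioned into scaffolds with lognormal
lengths (mean 25 kb, sd 15 kb — matching short-read assembler output with
N50 in the mid-20 kb range), each independently reverse-complemented with
probability 0.5 and perturbed by substitutions at `scaffold_error_rate`
(default 1e-3). A floor of 200 bp avoids unplaceable fragments. Truth
placements (chrom, start, end, strand) are emitted per scaffold.

VCF. One record per catalogued site at which the three samples (offspring,
parent A, parent B) are not all identical, with homozygous diploid
genotypes and constant QUAL 60; `low_qual_frac` injects QUAL-10 sites to
exercise the quality filter. Coordinates are 1-based throughout the
library; only the BED writer uses 0-based half-open intervals.

What the generator does *not* emulate: read-level errors and genotype
likelihoods (the pipeline consumes a called VCF), indels and structural
variation, repeat families, recombination interference, and segregation
distortion. Passing tests therefore demonstrate the correctness of the
placement/painting logic under substitution-only divergence, not
robustness to misassembly or miscalled genotypes in real data.

## Scaffold placement

Seed-and-chain: the reference is indexed by exact k-mers (k = 15 by
default; k-mers occurring more than `max_occ` = 50 times are masked as
repetitive; k-mers containing N are skipped). Query k-mer hits are merged
along diagonals into maximal exact runs, then chained per (chromosome,
strand) with a weighted longest-increasing-subsequence DP that maximises
anchored bases minus a gap penalty of 0.5 bp per bp of length difference
between the reference-side and query-side gaps, with both gaps capped at
10 kb. The single best chain (ties broken by chromosome name, then
reference start — deterministic output) becomes the placement; chains
below 100 anchored bases leave the scaffold unplaced, which is a value,
not an error. Identity over the chained span is estimated in O(n):
anchored columns match exactly, equal-length inter-anchor intervals are
compared column-wise, and unequal intervals contribute their length
difference as non-identity. This is exact for substitution-only
divergence and approximate in the presence of indels, which is acceptable
because no per-scaffold identity is interpreted downstream beyond ranking.
k = 15 with `max_occ` = 50 resolves 500 kb random chromosomes uniquely;
genome-scale plant references would want a larger k and repeat-aware
masking.

## Pseudomolecule construction

Placements are sorted by reference start per chromosome. The gap between
consecutive components equals the projected reference gap (an N row in the
AGP; zero-length gaps are omitted), and a leading N gap is inserted when
the first component starts beyond position 1, so pseudomolecule
coordinates track reference coordinates. Overlapping projections are
resolved greedily left to right: the lower-scoring scaffold is trimmed by
the overlap on its conflicting end, or dropped to the unplaced list if its
interval is fully contained in the other's. Trimming rather than dropping
preserves both components' unique sequence. `genome_size` counts scaffold
bases only (gap Ns excluded); whether unplaced scaffolds should count
toward an assembly's size is a reporting choice — they are excluded here
and listed separately. The AGP v2.1 file plus the scaffold FASTA
reconstruct the pseudomolecule FASTA byte-for-byte (tested).

## Assembly statistics

N50 uses the descending-cumulative-sum convention: the smallest length L
such that scaffolds of length ≥ L contain at least half the total bases;
ties need no special handling under this definition. Reported percentages
use half-up rounding to match how summary tables are conventionally
printed (banker's rounding would turn 62.5% into 62). Sequencing depth is
reported as total bases over reference size; published depth figures
sometimes use a different, unstated denominator, so depth is a
convenience, not a validated statistic.

## Gene localisation

A query gene is seeded and chained exactly like a scaffold, on both
strands of every chromosome; the chained interval is then extended by the
uncovered query flanks (substitution-only model, so flanks project 1:1)
and clipped at chromosome ends. Candidates are ranked by
identity x query-coverage — the natural product form of a "highest
similarity and coverage" criterion, which has no canonical combining rule
— with ties broken by identity then (chromosome, start). Hits with
identity < 0.8 or coverage < 0.5 are reported as no-hit. Full-query
extension is what gives base-exact intervals even when terminal k-mers are
destroyed by substitutions. The distance between two located genes is the
outer span, max(end) − min(start): for two tandem genes this is the only
convention that reproduces printed kb separations from their top-match
coordinates. Hits on different chromosomes raise an error naming both —
a real outcome for paralog-rich families that deserves surfacing.

## Painting

Sites are kept if QUAL ≥ 30 (inclusive), biallelic, and SNP-only.
Classification: offspring = parent A ≠ parent B → A-like; offspring =
parent B ≠ parent A → B-like; offspring matching neither parent → other;
all three identical, or any heterozygous or missing genotype →
uninformative (excluded from every count — with inbred lines a het call
is most likely a genotyping artefact). Windows are anchored at position 1
(window i covers [(i−1)w+1, iw], ceil(L/w) windows per chromosome);
window sizes default to 50 kb and 100 kb, bracketing typical *indica*
rice LD (~75 kb). The dominant class is the argmax of window counts; an
empty window is MISSING (rendered white), and an exact tie is labelled
"other" — the conservative choice that inflates neither parental class.
Composition is reported both over raw SNPs and over non-MISSING windows,
with counts and half-up integer percentages.

## QTL zoom

A region `chrom:start-end` selects windows on the genome-anchored grid
with index in (⌊start/w⌋, ⌈end/w⌉]: boundary windows are included whole
(the zoom shares the whole-genome grid), and a window ending exactly at
the region start is outside it. Dominant labels are run-length encoded
into maximal same-origin segments, preserving MISSING runs; segments tile
the zoomed window list exactly. With ≥ 10 informative SNPs per window,
segment boundaries localise true recombination breakpoints to within one
window.

## Problem sizes and determinism

Tests and the acceptance script run the generator at desk scale — 1 Mb
(2 x 500 kb) for assembly round trips, 5 Mb (10 x 500 kb) for painting
recovery — sizes at which every property of interest (unique k-mer
placement, ≥ 100 SNPs per window, several hundred scaffolds) already
holds. Whole-genome scale changes only memory and wall time, not the
logic. All randomness flows through `numpy.random.default_rng` seeded per
stage from the configured seed, so reruns are byte-identical file-for-file
(the pipeline manifest records the config hash and seed).

## Known limitations

* Substitution-only sequence model: no indels, so AGP coordinates and
  identity estimates are exact only in that regime.
* Best-chain-wins placement: a scaffold spanning a true structural
  rearrangement relative to the reference is placed by its larger
  colinear piece; no split placements.
* The dominant-type window rule is deliberately simple (no HMM
  segmentation, no imputation); short double-crossover segments below the
  window size are invisible.
* The unknown founder must be more diverged than the parents are from
  each other to be detectable at all (see the divergence model above);
  composition attributed to "other" is a lower bound in principle.
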