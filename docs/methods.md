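# Methods

This note documents the models, conventions and numerical choices behind
`sinepop`, and what the synthetic-data generator does and does not emulate.

## Sequence conventions

All coordinates are 0-based, half-open. Sequences are upper-case over
`{A, C, G, T, N}`; `N` never counts as a match in any comparison (alignment,
TSD calls, tandem repeats, microhomology). The insertion-bearing allele is
"filled", the insertion-free allele "empty"; at a locus the element span
`[s, e)` lies on the filled allele and the target-site duplication (TSD)
convention places both copies outside the span: the left copy ends at `s`,
the right copy starts at `e`.

## Element annotation

The family consensus is 208 bp with fixed regions: tRNA-related `[0, 75)`,
body `[75, 152)`, tail `[152, 208)`. The published region lengths
(75 + 75 + 56) leave 2 nt unaccounted; they are assigned to the body.

**Global alignment** is Needleman–Wunsch with match +1, mismatch −1, linear
gap −2 — the scheme is a package choice, as no scoring was published — with a
deterministic traceback (ties: diagonal, then up, then left). Identity is
matches over alignment columns. Family membership requires body identity
≥ 0.76, the conventional conservation threshold for assigning SINE copies to
one family; elements under 50% overall identity are rejected as unalignable.

**Indel calls.** Under a linear gap cost, co-optimal alignments of a long
random insertion fragment it into nearby gap runs (the diagonal-preferred
traceback picks one such tie). Indel reporting therefore merges same-kind gap
runs separated by ≤ 3 aligned columns and reports the total gap-column count
as the indel length; only indels ≥ 3 bp within the body are listed.

**Tail motifs.** TGTAA copies are counted as the longest tandem
(non-overlapping, adjacent) run; poly(A) requires a run of ≥ 5 A's at or
after the last TGTAA copy (anywhere when there is none). Classes:
TGTAA-poly(A) when both motifs are present, else whichever is present, else
none.

**Promoter boxes.** The pol III internal promoter motifs are scanned as
IUPAC consensus strings — A box `TRGCNNARYNNG`, B box `GWTCRANNC` — with at
most 2 mismatches, the A box restricted to the first 40 nt and the B box to
positions downstream of the A box; the best hit is the fewest-mismatch,
leftmost one. These are canonical motif strings, not fitted models; on random
75-mers the A box false-positive rate at ≤ 2 mismatches is appreciable
(tens of percent), which is acceptable because the scan is descriptive.

**Hairpin folding** is maximum base pairing (Nussinov recursion) with pairs
A–T, G–C and the G–T wobble, minimum loop 3 nt, and a deterministic
traceback that takes the outermost pair whenever optimal. The call reports
the longest stack of nested pairs and its loop. This is a combinatorial
stand-in for thermodynamic folding: adequate for comparing the stem-loop
character of SINE and LINE tails, silent about free energies. Note that with
wobble pairs the pair count is invariant under sequence reversal but not
under reverse complement (a G:T pair maps to A:C); the reverse-complement
invariance holds for the Watson–Crick pair set (`wobble=False`).

**Transcript surveys** use Smith–Waterman local alignment on both strands
with blastn-like scores (+2/−3, gap −5) and the published hit gate
(score > 80). The annotation alignment scheme (+1/−1/−2) is deliberately not
used here: under it a perfect single-region hit cannot exceed 80 (the tail
is 56 bp, the tRNA region 75 bp), which would contradict the study design of
counting per-region hits. A hit increments every region whose consensus span
is ≥ 90% covered by the aligned consensus interval; covering all three
regions in one hit counts a full-length transcript copy.

## Insertion forensics

**TSD calls** return the longest k in [2, 31] with
`filled[s−k:s] == filled[e:e+k]`, exact matches only. With random flanks a
chance duplication longer than the biological one can exist; the generator
flags such loci, and the recovery tests certify every discrepancy against a
brute-force scan.

**Flank duplications** compare 100-nt windows on each side of the insertion
junction between filled and empty alleles and report maximal segments
(≥ 10 nt) that are repeats in the filled window (occur ≥ 2 times) and occur
more often than in the corresponding empty window — i.e. repeats the
insertion created. Requiring ≥ 2 occurrences is essential: any substring
crossing a junction is trivially absent from the empty allele without being
a repeat.

**Tandem repeats** are maximal arrays of a primitive unit (1–20 nt) with
≥ 3 copies and ≥ 8 nt total; a trailing partial copy counts when ≥ half a
unit; overlapping arrays collapse to the longest (ties: smallest unit,
then leftmost). The thresholds admit the full published range of flank
repeats — from `(G)38` homopolymers to a 20-nt unit repeated 14 times —
while excluding dinucleotide noise. Offsets are signed from the element
junctions: negative upstream of the 5' junction, positive downstream of the
3' one.

**Flank composition** takes the 50-bp windows immediately outside the
element and its TSD copies and tests the per-locus AT fraction against 0.5
with a two-sided one-sample t-test per side; a zero-variance sample on
target returns t = 0, p = 1 by a degeneracy guard.

## Excision footprints

The excised allele is anchored to the filled allele by its longest shared
prefix and suffix (each ≥ 30 nt, else the alleles are declared not
comparable). Everything between the anchors on the excised side is the fill;
filled-side flank bases lost between the anchors and the element (plus its
right TSD copy) are the deletion; the microhomology is the longest exact
suffix of the fill equal to the bases immediately following it, searched up
to 25 nt. When the anchors meet on the excised allele (a clean excision) the
right anchor is trimmed to abut the left one, which keeps the left anchor
maximal and yields an all-zero footprint. Chance single-base anchor
extensions shift the inferred fill by one base; the generator flags such
plants (`clean=False`) and `plant_clean_excision` rejects them.

## Population genetics

Statistics per (locus, population): f_SINE = (2·n_II + n_IA)/(2n),
Het = n_IA/n, missing genotypes excluded from n. The Hardy–Weinberg test is
the conditional exact test: given the allele counts, a configuration with h
heterozygotes has probability ∝ n!/(n_II! h! n_AA!)·2^h, and the p-value
sums all configurations whose probability does not exceed the observed one
(ties included; weights are computed with log-gamma functions and compared
with a 1e-9 log tolerance). Ecotype statistics pool individuals across the
populations of each ecotype and report unweighted across-locus means,
matching how the published tables aggregate.

**Distances.** Nei (1972) standard distance with J sums over loci and the
two alleles per locus; the ratio is clamped to ≤ 1 before the log, and a
zero between-population identity (disjoint alleles at every locus) is
reported at a cap of 10.0 and flagged. Nei (1983) D_A is available as an
alternative; the choice is recorded in the matrix metadata.

**Neighbor joining** follows Saitou–Nei with the Studier–Keppler Q
criterion. Ties in Q break on the lexicographically smallest pair of node
labels (an internal node carries the smallest leaf label beneath it), so the
tree is reproducible; negative branch lengths are clamped to zero and
counted. On additive matrices the algorithm provably returns the generating
tree, which the tests exercise with random additive metrics.

**AMOVA** encodes each individual as its per-locus insertion dosage (0/1/2;
individuals with any missing genotype are dropped) and partitions squared
Euclidean sums of squares among groups, among populations within groups and
within populations, with the standard nested-ANOVA coefficients for unequal
sizes. Negative variance components are truncated to zero for the percentage
breakdown (flagged), but Φ statistics use the raw components. Permutation
p-values (seeded) use (B+1)-denominator estimators: individuals across
populations for Φ_ST, whole populations across groups for Φ_CT, individuals
across populations within groups for Φ_SC. With few populations the Φ_CT
permutation space is tiny (3 distinct reassignments for 2+2 populations), so
its p-value is coarse by construction.

## Copy number

The standard curve is an OLS fit of Ct on log10(copies) (≥ 3 points spanning
≥ 2 decades); slopes outside [−3.6, −3.1] — amplification efficiencies
outside ~90–110% — raise a warning, never an error, since the published
slope −3.11 sits at the band's edge. Replicates are averaged on the Ct scale
before inversion. Copies per genome = copies in reaction × genome size
(3.534 pg) / input DNA mass; the input mass is an explicit plate column
because no single value is canonical. Group contrasts use one-way ANOVA
between ecotypes and among populations within each ecotype.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study's headline conditions: element identity
uniform on [0.77, 0.94] (substitutions only, the tail motif block frozen);
TSD lengths on 2–31 nt with ~78% of the mass on 3–8 nt (the published
distribution is only described qualitatively, so the weights are a package
choice); the three tail motif classes planted by minimal edits of the
consensus tail; flanks AT-enriched at 0.283 per A and T (56.6% AT);
excisions with microsatellite fill and junction microhomologies; genotypes
drawn binomially under Hardy–Weinberg at specified frequencies; Ct values on
the published regression with Gaussian noise (0.05 cycles for plasmid
standards, matching the published R² = 0.999; 0.2 cycles for genomic
unknowns), the dilution series spanning 7 decades so genomic inputs are
interpolated. The deterministic `table1_fixture` rebuilds the published
genotype table by exact integer arithmetic — het = round(Het·n),
n_II = round(f·n − het/2), n_AA = n − n_II − het at n = 10 — and validates
each cell, so recomputing statistics from it reproduces every printed value
without sampling.

It does **not** emulate: indel-rich or phylogenetically structured sequence
evolution (substitution-only divergence), linkage between loci, read-level
sequencing error, PCR dropout or null alleles, or plate effects in qPCR.
Passing tests therefore demonstrate correctness of the analysis on data with
exactly the declared structure, not robustness to alignment ambiguity or
genotyping error in real resequencing data.

Ambiguity is handled by flagging, not by silent correction: a planted TSD
can be masked by a longer chance duplication, and an excision anchor can
extend by a chance base; the ground truth records both, recovery is asserted
on the unambiguous plants, and every discrepancy is certified against a
brute-force recomputation.

## Problem sizes and calibration designs

The recovery suites use 500 planted insertions and 200 planted excisions;
oracle-equivalence checks enumerate all genotype tables with ≤ 25
individuals (HWE), random pairs ≤ 12 nt (alignment), sequences ≤ 12 nt
(hairpins), strings ≤ 60 nt (tandem repeats) and ≤ 12 individuals (AMOVA).
The Hardy–Weinberg null calibration draws 200 loci of 2000 diploids at
frequencies uniform on [0.2, 0.8]: the exact test's p-value is discrete, and
its largest probability atom (~0.2 at n = 50, ~0.03 at n = 2000) bounds how
close to uniform the p-distribution can be, so a Kolmogorov–Smirnov check is
only meaningful once the atoms are below the KS noise floor. The AMOVA null
calibration uses 200 data sets of 4 populations × 8 diploids × 5 loci at a
common frequency with 99 permutations each. The copy-number power design
follows the published ecotype means (3.5×10⁵ vs 2.3×10⁵ copies per genome)
with an SD of 0.3×10⁵ and 30 samples per group.

## Known limitations

* The alignment scoring schemes (global +1/−1/−2; survey +2/−3/−5 with the
  > 80 gate) are package choices calibrated to the study's qualitative
  statements, not published parameters.
* The hairpin model maximizes pair counts, so stems with equal counts but
  different stabilities are indistinguishable.
* Φ_CT permutation p-values are coarse whenever few populations exist.
* Published per-locus ecotype frequencies are not derivable from the
  per-population table under any simple pooling (the original pooling is
  unknown); the ecotype aggregate checks therefore treat the printed
  per-locus ecotype values as inputs.
* Real allele sequences for the published loci are accepted as user-supplied
  FASTA (the accession ranges are documented with the data availability of
  the original study) but are never downloaded by the package.
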