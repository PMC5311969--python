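# Methods

## Problem and model

Pollen DNA in honey records which plants a honey bee colony foraged on.
The pipeline treats each hive × month honey sample as a mixture of
plant taxa: paired-end amplicons of a universal plant barcode marker
(*rbcL*-style, ~550 bp amplified in 2 × 300 bp reads) are merged,
matched to a reference library of barcode sequences with three-rank
taxonomy (species, genus, family), and the per-taxon read counts are
converted to percentages — a *semi-quantitative* measure of DNA
abundance (PCR and copy-number biases mean read share is not exactly
pollen share; relative ranking is the meaningful signal). Honey use is
then compared with floral availability from zone-based surveys of
plants in flower.

## Read processing

* **Trimming** — the tooling convention "quality trimmed" is realized
  as a 3′ non-overlapping mean-quality window trim: the read is cut
  after the last window (default 4 bases) whose mean Phred quality is
  at least the threshold (default Q20). Both knobs are configurable;
  on uniformly high-quality reads the trim is a no-op, and a uniformly
  bad read trims to nothing and is rejected at merging.
* **Merging** — mate 2 is reverse-complemented, every overlap length
  from `min_overlap` (default 20) upward is scanned, and the overlap
  maximizing matches − mismatches wins (ties toward the longer
  overlap, so identical mates merge to a single read length).
  Disagreements resolve to the higher-quality base; an exact quality
  tie keeps mate 1's base with the minimum of the two qualities, so
  consensus quality never overstates confidence. Merges whose best
  overlap exceeds a 10% mismatch fraction are rejected with a reason
  code, and per-sample accounting enforces
  `pairs_in = merged + rejected` and `merged = kept + length_filtered`.
* **Length filter** — "greater than 450 bp" is read strictly: a 450 bp
  merge is dropped, 451 bp is kept. The default simulated amplicon is
  550 bp so correct merges pass comfortably.

## Reference search

Scoring is optimal local alignment under match +1, mismatch −2, gap
open −2, gap extend −2 (the megablast-style reward/penalty family),
computed by Biopython's C `PairwiseAligner`. The top-hit set is every
reference attaining the maximum raw score — an exact integer tie. Bit
scores S′ = (λS − ln K)/ln 2 use published ungapped constants for
+1/−2 (λ = 1.28, K = 0.46); since the transform is strictly monotone,
ties are identical on either scale (asserted on every hit set), and the
constants are configuration rather than results-critical. No identity
or coverage cut-off is applied by default; optional `min_identity` /
`min_query_coverage` flags exist and default to off.

Two engines share that scoring. The exhaustive engine aligns against
every reference and is the default and the oracle — desk-scale
libraries (up to a few thousand references) make this tractable. The
seeded engine aligns only references sharing at least one exact k-mer
with the read (default k = 11); it equals the exhaustive engine
whenever the true top alignment contains one exact k-mer match, which
holds with large margin at the simulated 0.5% per-base error rate. The
bundled study configuration uses k = 16, which for ~550 bp amplicons at
these error rates and divergences still guarantees seeding of every
tied top hit while keeping candidate lists near family size.

## Taxonomic assignment

Tied top hits collapse to distinct (species, genus, family) triples and
the read is assigned at the lowest common rank: one triple → species
(or genus, for a genus-level reference with empty species); several
species of one genus → genus; several genera of one family → family,
with the contributing genera recorded and rendered as the sorted
slash-joined group label (`Cotoneaster/Crataegus/Malus`); several
families → unknown. Reads with empty hit sets count as unknown in the
identifiable-read percentage denominator (post-length-filter reads
only). The regional checklist filter is a deterministic re-statement of
a manual curation step: a taxon is retained iff its label or any
constituent genus appears on the checklist, and removed taxa leave the
proportion denominators entirely (removals are logged with read
counts).

## Composition and diversity

Proportions are percentages of a sample's retained identifiable reads.
Pooling across hives defaults to summed read counts ("pooled-counts"),
consistent with reporting "% of all DNA reads"; an unweighted
mean-of-proportions mode exists because published per-hive tables carry
no counts. Major forage is strictly > 1% of reads. Diversity is the
Gini–Simpson complement D = 1 − Σp²: the published range of values
(0.6–0.85, higher in the more even month) is only consistent with the
complement form, not with Σp² or 1/Σp².

## Survey analysis

Availability is the deduplicated set of genera (and of families, via
the reference's genus → family map; survey genera without a mapping
count as their own singleton family) in flower anywhere per month;
"combined" is the union over months. Use-versus-availability
percentages are rounded half away from zero — the rule is pinned by
published count/percent pairs (18/80 → 23%, 45/360 → 13%), which
banker's rounding or truncation cannot reproduce. Honey labels match
survey lists at genus level after whitespace/case normalization, with
family groups contributing every constituent genus. Area of occurrence
is the summed area of zones (not individual flowerbeds — the measure is
explicitly approximate) where the taxon flowered that month. Phenology
concordance flags any taxon detected in honey in a month its genus was
not recorded in flower, the signature of carry-over from stored honey.

## Statistics

* Spearman's rho on average ranks (= Pearson on rank vectors); p from
  the t approximation for n > 8, exact permutation enumeration for
  n ≤ 8. Hive-pair concordances are Bonferroni-adjusted over all
  pairs × months.
* Mann-Whitney U reports both the exact two-sided p (all C(n1+n2, n1)
  labelings, doubled smaller tail capped at 1 — feasible and default
  for n1+n2 ≤ 12) and the tie-corrected normal Z without continuity
  correction, because published month comparisons print Z values even
  at N = 3.
* Fisher's exact test for r × c tables enumerates every table with the
  observed margins (n ≤ 500) and sums the probabilities of tables no
  more probable than observed (relative tolerance 1e-7, the convention
  of standard implementations); for 2 × 2 this equals the
  hypergeometric two-sided sum.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with everything deterministic given the seed:

* **Reference library** — one uniform root sequence; family ancestors
  derive from it by per-site substitution at `d_family` (default 0.20),
  genus ancestors from family ancestors at `d_genus` (0.08), species
  from genus ancestors at `d_species` (0.02, zero allowed as the
  identical-congener limit). This yields the hierarchy the assignment
  logic relies on: within-genus identity > within-family > between-
  family. Defaults are 6 families × 2 genera × 2 species of 550 bp.
* **Reads** — per pair, a taxon is drawn by its true proportion, a
  reference of that taxon uniformly; mate 1 is the first 300 bases,
  mate 2 the reverse complement of the last 300; each base substitutes
  independently with the error rate (default 0.005, a polished-
  Illumina-like figure), uniformly over the three alternatives.
  Qualities are the constant Phred score matching the error rate in
  expectation (Q23 at 0.005); there is no quality variation along the
  read, no indel error by default, and no PCR/chimera/copy-number
  bias — so passing tests demonstrate correctness of the analysis
  chain, not robustness to those real-data artifacts.
* **Study design** — the default study is 3 hives × 2 months with
  10,000 pairs per sample: 10 honey taxa on a geometric abundance
  profile (ratio 0.5, a few-dominant-taxa shape), of which 4 flower in
  both months and 3 in each single month, so each month's honey holds
  7 taxa and phenology concordance holds by construction. All hives in
  a month share one true mixture; only sampling noise separates them,
  which is what makes pairwise hive concordance near 1. The survey has
  20 zones totalling 34.2 ha with Dirichlet areas and a
  grassland/woodland/horticulture habitat mix, plus 40 survey-only
  background genera so availability far exceeds use. The checklist
  assigns native/both statuses to honey genera and horticulture to the
  background flora, exercising the status × forage-class test. The
  acceptance script runs this design at 2,000 pairs per sample to keep
  its runtime modest; the test suite's recovery check runs the full
  10,000.

## Numerical choices and degenerate inputs

Ties in the merge overlap scan break toward the longer overlap; ties in
alignment top hits preserve library order. Proportions must sum to 100
within 1e-6 before Simpson's D is computed. Zero retained reads, empty
groups, zero-variance rank vectors, zero availability denominators and
contingency tables beyond the enumeration bound all raise informative
errors rather than returning degenerate numbers. Seeds are split with
`numpy.random.SeedSequence` so reference, survey and per-sample read
streams are independent, and rerunning any command with the same seed
reproduces byte-identical files.

## Limitations

Proportion recovery is limited by binomial sampling noise (±2
percentage points needs ~10⁴ reads for minor taxa) and, in real data,
by marker resolution: many congeners are indistinguishable at this
locus, so genus- and family-group labels are the honest resolution for
part of any real sample. The availability statistics treat a zone as
occupied by a taxon wholly or not at all; no abundance-in-flower
weighting is attempted. The published per-hive proportion-table
statistics (combined Simpson's diversity, pairwise hive correlations)
are computed by `published_table_statistics` when such a table is
supplied as TSV; no such table ships with the package.
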