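# honeyforage

Honey DNA-metabarcoding analysis of honey bee foraging: from paired-end
*rbcL* amplicon reads and a taxonomically annotated plant barcode
reference library to per-hive plant composition, major/minor forage
classification, diversity, and use-versus-availability statistics
against a floral survey.

Honey contains pollen DNA from the plants a colony foraged on. Sequencing
a universal plant barcode marker (*rbcL*) from honey and matching the
reads to a reference library yields a semi-quantitative picture of which
plants the bees actually used — which can then be compared with what was
*available*, recorded by field surveys of plants in flower across zones
of the landscape. The package is aimed at molecular ecologists running
such studies, and ships a synthetic-data generator with known ground
truth so the entire chain is testable without any sequencing data.

## The method

Per hive × month honey sample:

1. **Read processing** — 3′ sliding-window quality trim (Q20, window 4),
   merge of each 2 × 300 bp mate pair over the best overlap (maximum
   matches − mismatches, quality-weighted consensus), and a strict
   length filter: only merged amplicons > 450 bp continue.
2. **Reference search** — each read is scored against every reference by
   optimal local alignment (Smith–Waterman; match +1, mismatch −2, gaps
   −2) and the *top-hit set* is every reference tying the maximum score.
   Bit scores S′ = (λS − ln K)/ln 2 are reported; being monotone in S
   they preserve the tie structure. A k-mer-seeded accelerator
   reproduces the exhaustive engine exactly at realistic error rates.
3. **Taxonomic assignment** — tied top hits collapse to their lowest
   common rank: one species → species; several species of one genus →
   genus; several genera of one family → a family-level multi-genus
   group (e.g. `Cotoneaster/Crataegus/Malus`); several families →
   unknown. Taxa absent from the regional checklist are removed.
4. **Composition** — read counts → proportions (%) of retained reads;
   taxa > 1% are *major* forage; richness and Gini–Simpson diversity
   D = 1 − Σp².
5. **Survey joins** — genera/families in flower per month, flowering
   density per m², use-versus-availability percentages (half-away-from-
   zero rounding), approximate area of occurrence, and phenology
   concordance (honey detections outside a taxon's flowering window are
   flagged as carry-over).
6. **Statistics** — pairwise hive concordance (tie-corrected Spearman
   with Bonferroni), month comparisons (Mann-Whitney U, exact by
   labeling enumeration at small n), and status × forage-class
   association (Fisher's exact for r × c tables by full enumeration).

## Worked example

Simulate a 3-hive × 2-month study (10 honey taxa with a geometric
abundance profile, 0.5% per-base error), run the pipeline and report:

```
$ honeyforage simulate demo --seed 3 --read-pairs 60
dataset written to demo
$ honeyforage run demo/config.yaml
results written to demo/results
$ honeyforage report demo/results
# Honey metabarcoding run summary

Overall identifiable reads: 100.00%
April: richness=7 Simpson's D=0.652
  major forage: Genus01a sp1, Genus01b sp1, Genus02a sp1, Genus02b sp1, Genus03a sp1, Genus03b sp1
May: richness=6 Simpson's D=0.680
  major forage: Genus01a sp1, Genus01b sp1, Genus02a sp1, Genus02b sp1, Genus04b sp1, Genus05a sp1

Use versus availability:
      April family: 4 of 33 in flower (12%)
        May family: 4 of 37 in flower (11%)
   combined family: 5 of 46 in flower (11%)
      April  genus: 7 of 37 in flower (19%)
        May  genus: 6 of 41 in flower (15%)
   combined  genus: 9 of 52 in flower (17%)

Carry-over flagged taxa: none

Statistics:
  spearman_A_vs_B_April: statistic=0.9247 p=0.007143 (n=7, exact)
  ...
  mwu_richness_April_vs_May: statistic=1 p=0.3 (n=3, exact)
  status_x_forage_class: statistic=0.5556 p=1 (n=9, exact)
```

Reading: every kept read was identifiable to at least family level; the
true April mixture has seven taxa, six above the 1% major-forage
threshold (the geometric profile puts the seventh at ~0.8%, and at this
shallow 60-pair depth one May taxon went undetected); the bees "used"
only ~11% of the plant families available in flower; Simpson's D ≈ 0.65
matches the simulated mixture's true diversity (1 − Σp² = 0.661); and
the three hives' compositions are strongly concordant (Spearman's rho >
0.9 in April). The exact numbers depend on the seed and sampling depth.

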