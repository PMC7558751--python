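# parascreen

Analysis toolkit for **dual-guide CRISPR (enCas12a-style) genetic-interaction
screens** and for **detecting functional buffering between paralogs** in
monogenic knockout-screen panels.

Paralogous genes often back each other up: knocking out either gene alone has
little fitness cost, so both stay invisible to single-gene CRISPR screens,
yet the double knockout is lethal. `parascreen` implements the two
complementary ways of finding such pairs:

* **the screen arm** — design a dual-guide construct library, turn pooled
  read counts into fold changes, and score genetic interactions with the
  trimmed-Z dLFC statistic;
* **the cohort arm** — classify gene expression across a cell-line panel
  with a Gaussian mixture, call per-line loss of function, and test whether
  losing one paralog makes the other essential (Fisher's exact test with
  Benjamini–Hochberg FDR).

Both arms ship with synthetic-data generators that plant known ground truth,
so every statistic can be validated end to end without any external
download.

## The statistics

For a screen with a plasmid reference and r replicates per cell line, counts
are pseudocounted (+5), scaled to a common mean depth (500 reads/construct),
and converted to construct-level log2 fold changes vs the plasmid; replicate
LFCs are averaged into screen-level LFCs.

* **SMF** (single-mutant fitness) of gene *g*: mean LFC of its
  *gene-control* constructs (gene guide + nonessential-control guide),
  averaging the A-position and B-position means.
* **Observed DMF** of pair *(a, b)*: mean LFC of the dual-targeting
  constructs (18 per pair for a 3×3 guide design, both orientations).
* **Expected DMF** = SMF(a) + SMF(b)  (additivity in log space).
* **dLFC** = observed DMF − expected DMF; negative values indicate a
  synthetic sick/lethal interaction.
* **zdLFC**: per cell line, dLFC standardized by the mean and sample SD of
  the dLFC distribution after removing the top and bottom 2.5 % of values,
  so the synthetic-lethal tail does not inflate its own yardstick.
  A pair is a **hit** when zdLFC < −3 (strict).

For the cohort arm, a gene is **LOF** in a cell line when it has a damaging
mutation, log2 TPM < 1.0, or copy number < 0.1; it is **essential** when its
Bayes Factor exceeds 10. For each directed paralog pair (A | B) the 2×2
table of cell lines (LOF(B) × essential(A)) gets a one-sided Fisher's exact
test, BH-corrected across all tested pairs.

## Worked example

Simulate a screen of 100 gene pairs, 10 of them carrying a planted
interaction of −2 (log2), at 500 reads/construct and 3 cell lines × 3
replicates, then score it:

```bash
parascreen simulate --n-pairs 100 --n-planted 10 --seed 1 --out demo
parascreen score --counts demo/counts.tsv --samples demo/samples.tsv \
    --library demo/library.tsv --out demo_scores
parascreen qc --counts demo/counts.tsv --samples demo/samples.tsv \
    --library demo/library.tsv --out demo_qc
```

prints

```
simulated 3060 constructs -> demo
9 hit pairs (9 in all lines) -> demo_scores
{
  "separation_auc": { "LINE1": 0.917, "LINE2": 0.918, "LINE3": 0.921 },
  "mirror_r":       { "LINE1": 0.913, "LINE2": 0.917, "LINE3": 0.917 },
  "min_replicate_r": 0.919
}
```

The 3060 constructs are 100 pairs × 18 dual constructs + 200 genes × 6
gene-controls + 60 essential-control constructs. Nine of the ten planted
pairs are called at zdLFC < −3 in every cell line; the QC block shows
essential-control dropout separation (AUC ≈ 0.92), near-perfect A-B vs B-A
mirror-construct agreement (r ≈ 0.91, i.e. no positional bias), and high
replicate concordance. The first scored pair in `demo_scores/gi_scores.tsv`:

```
pair_id            cell_line  observed_dmf  expected_dmf  dlfc    zdlfc   hit
GENE0000_GENE0001  LINE1      -1.579        0.731         -2.310  -3.573  True
```

a planted pair: its observed double-mutant fitness is far below the additive
expectation from the two single-mutant fitnesses.

The cohort arm runs the same way from gene × cell-line TSV matrices via
`parascreen classify-expression` and `parascreen buffering`, or from Python:

```python
import parascreen as ps
cohort = ps.generate_cohort(ps.CohortSpec(
    n_genes=1000, n_lines=200, n_paralog_pairs=50,
    planted=ps.default_planted_pairs(10), seed=1))
lof = ps.call_lof(cohort.mutation, cohort.expression, cohort.cn)
directed, report = ps.testable_pairs(cohort.pairs, lof, cohort.bf)
result = ps.buffering_scan(directed, lof, cohort.bf)   # sorted by p
```

All ten planted buffering pairs rank at the top of the scan (p ≤ 1e-4,
FDR ≪ 0.01) while the null pairs stay flat.

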