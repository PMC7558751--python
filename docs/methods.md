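# Methods

## Scope and model

`parascreen` analyses two kinds of data about paralog redundancy:

1. **Dual-guide screen counts.** A pooled library of constructs, each
   expressing two crRNAs, is screened against a plasmid reference in one or
   more cell lines. The fitness model is additive in log2 space: the
   expected double-mutant fitness (DMF) of a gene pair is the sum of the
   two single-mutant fitnesses (SMF), and a genetic interaction is a
   deviation from that sum (dLFC), standardized per screen (zdLFC).
2. **Monogenic-screen panels.** Gene × cell-line matrices of expression
   (log2 TPM), essentiality (Bayes Factor), copy number and damaging
   mutations. Functional buffering appears as *synthetic essentiality*:
   gene A is essential specifically in the lines where partner B has lost
   function.

## Screen processing

Counts are processed in the order: add pseudocount, scale each sample to a
common mean, log-transform against the plasmid, average replicates.

| parameter | default | meaning |
|---|---|---|
| `pseudocount` | 5 reads | added to every construct in every sample before scaling; guarantees finite LFCs |
| `target_mean` | 500 reads/construct | per-sample mean after scaling |
| `log_base` | 2 | all fold changes; downstream math is base-agnostic |
| `trim_fraction` | 0.025 | tail mass removed from *each* side before the Z moments |
| `zdlfc_threshold` | −3 | hits are zdLFC strictly below the threshold |

The scaling denominator is the mean of the *pseudocounted* counts, which is
what the stated processing order implies; column means after scaling equal
`target_mean` to ~1e-9 relative error, and that identity is tested.

SMF averages the A-position and B-position control-construct means rather
than pooling constructs, so an unbalanced position count cannot skew a gene
estimate. Genes without control constructs are flagged and their pairs
excluded (and reported) rather than silently dropped.

zdLFC uses `k = floor(trim_fraction * n)` values removed from each tail
(ties broken by sort order) and the sample SD (ddof = 1) of the kept middle;
all pairs, trimmed ones included, are standardized against those moments.
With n ≈ 400 pairs the choice of sample vs population SD moves the score by
< 0.2 %, but it matters for exact reproduction and is therefore fixed and
documented. zdLFC is computed per cell line over the scored gene pairs only
— control constructs are not part of the distribution. A degenerate
(zero-SD) trimmed distribution raises rather than returning infinities.

Because pooled counts measure *relative* abundance, every LFC carries a
compositional offset −log2(Σ w_j 2^t_j) (w: plasmid shares, t: true fold
changes). The offset enters dLFC once with a minus sign (observed shifts by
c, the two SMFs shift by c each) and is absorbed by the trimmed-mean
centering of the Z step; the simulator's closed-form tests account for it
explicitly.

## Library design

Each gene pair is targeted by all guide cross-combinations in both
orientations (n_A·n_B·2 constructs; 18 for 3 × 3). Single-knockout
(gene-control) constructs pair each gene guide with one nonessential-pool
guide, both orientations (2 per guide; 6 per 3-guide gene); essential
controls get the same treatment. Control partners are drawn uniformly from
the pooled nonessential guides, without replacement within one gene's draws
(avoids duplicate constructs), with replacement across genes. The closed
form 2·Σ n_A n_B + 2·Σ n_g + 2·n_ess holds for every seed and is tested as
a property. Guide selection/scoring itself (on-target rules, PAM
constraints) is upstream input, not computed here.

## Screen simulator

The generator runs the additive model forwards. Its defaults are the study
conditions of the screen design it emulates: 3 cell lines × 3 replicates,
500 reads/construct, 3 guides/gene, and a planted interaction of −2 log2
units in recovery scenarios.

* **Guide efficiency** is a per-guide effect ~ N(0, `guide_noise_sd`/√2)
  that travels with the crRNA into every construct (construct-level SD =
  `guide_noise_sd`, default 0.2). Consequences: mirror constructs (A-B vs
  B-A) share a true LFC exactly, matching the empirically observed absence
  of positional effects, and the gene-guide component cancels between a
  pair's observed DMF and its genes' SMFs, leaving the control-partner
  component as the irreducible dLFC noise.
* **Counts** are negative-binomial (gamma–Poisson) with
  var = m + `dispersion`·m², around a log-normal plasmid pool
  (σ = 0.5). `dispersion` defaults to 0.01, which puts simulated replicate
  LFC correlations at ≈ 0.93 — the high-quality regime (reported
  position-level SMF correlations of 0.87–0.94) this generator is meant to
  emulate. `replicate_noise_sd` (default 0.1) adds independent per-replicate
  biological scatter so replicate-correlation QC is meaningful.
* **SMF marginal** for experimental genes: 80 % N(0.05, 0.1) + 20 %
  N(−0.7, 0.3), i.e. mean −0.10 with a slightly positive median and a left
  dropout tail — the marginal shape reported for screens of this design.
  Essential controls draw SMF ~ U(−2, −1); nonessential controls are 0.
* An optional `positional_bias` term exists solely to verify that the
  mirror-correlation QC can detect a biased library; it defaults to 0.

What the simulator does **not** model: sequencing/mapping artifacts,
GC/abundance-dependent dispersion, off-target effects, cell-line-specific
SMF differences (fitness is shared across simulated lines), or
guide-dropout from synthesis errors. Passing recovery tests therefore show
the *statistics* behave correctly under the declared noise model, not that
the pipeline is robust to every failure mode of real screens.

### Recovery behavior and its limits

With 10 % of pairs planted at gi = −2 and 2.5 % trimming, `floor(0.025·100)
= 2` values leave each tail, so 8 planted pairs remain inside the trimmed
set and inflate the trimmed SD to ≈ 0.56. Planted zdLFC therefore
concentrates near −3.3 ± 0.25 and per-pair sensitivity at the −3 threshold
is ≈ 0.92 — intrinsically marginal, which is why recovery is measured
pooled over 20 deterministic scenario replicates (200 planted pairs) rather
than from a single 10-pair draw. False calls among null pairs are
essentially zero (null zdLFC stays above ≈ −1.5).

## Expression classification

Per-gene mean and sample SD of log2 TPM across cell lines are modeled with
a 3-component full-covariance Gaussian mixture (EM, tolerance 1e-6, 10
restarts, seeded; best log-likelihood kept, convergence enforced).
Components map to labels deterministically: highest SD-axis center →
*sometimes* expressed; of the remaining two, lower mean → *never*, higher →
*constitutive*. Exact center ties raise an ambiguity error instead of
guessing. Model selection is offered only as a BIC report
(`bic_report`); the component count is fixed at 3 by design.

## Paralog buffering

LOF(gene, line) = damaging mutation ∨ log2 TPM < 1.0 ∨ copy number < 0.1.
The expression threshold is applied **per cell line**: the contingency
table counts cell lines, so the evidence must be per line (a cross-line
mean would blur exactly the signal being tested; a config switch can
restore the cross-line-mean reading).

Directed pairs (A | B) are testable when: min(identity A→B, identity B→A)
≥ 30 % (min is the conservative combiner; the sources report both
directions without stating one), the pair is one-to-one (neither gene
appears in another pair passing the identity filter), partner B has ≥ 2 LOF
lines and query A is essential (BF > 10) in ≥ 2 lines. Every filter reports
its removal count. The test is the one-sided hypergeometric tail
P(X ≥ overlap); degenerate margins return p = 1 with a flag. BH FDR is
computed across all tested directed pairs.

One-sided Fisher p-values are discrete and conservative: under realistic
margins (~5 % LOF, ~5 % essential of 200 lines) more than half of all null
tables have zero overlap and p = 1 exactly. Null calibration is therefore
assessed as *validity* — the empirical CDF must not exceed the uniform
(one-sided KS) and P(p ≤ 0.05) ≤ 0.05 — rather than exact uniformity,
which no exact conditional test can satisfy.

## Cohort generator

Gene classes are drawn from mixture weights (constitutive 0.41, never 0.26,
sometimes 0.33 — echoing the observed panel-scale split), with (mean, SD)
centers (6, 0.5), (0.3, 0.3), (3, 2.2) and spread 0.3. Per-line expression
is Normal(gene mean, gene SD) truncated at 0 (log2(TPM+1) floor). Mutations
are sparse Bernoulli (0.005) and deep deletions rare (0.005), so depleted
expression is the dominant LOF channel, as in real panels. Bayes Factors
are N(−15, 5) for nonessentials with a 5 % background essential rate at
N(25, 5). A planted pair (A, B) injects LOF evidence for B at `lof_rate`
(default 0.2) through a randomly chosen channel per line and shifts A's BF
into the essential range with probability `penetrance` (default 0.9) in
those lines. Paralog-pair genes are drawn from the constitutive class —
the population the buffering analysis targets — because never-expressed
genes produce degenerate all-LOF margins. Truth tables (gene classes,
generating (mean, SD), planted directed pairs) are emitted so recovery can
be scored without reaching into generator internals.

## Problem sizes used in the shipped checks

Simulation-based checks run at: 100 pairs × 18 constructs (+ controls) per
screen, 3 lines × 3 replicates, 20 scenario replicates for recovery;
cohorts of 1000–3000 genes × 60–200 lines; 1500-gene mixtures for the GMM.
These sizes give stable statistics (binomial SEs of 1–3 % on the reported
rates) while keeping the whole suite in the low minutes on one CPU.

## Known limitations

* The zdLFC trimmed-Z is contaminated when true interactions exceed the
  trim fraction (see above); with hit rates ≫ 5 % a larger trim or a
  null-model fit would be needed.
* The additive expectation ignores epistasis between guides of the same
  gene and any positional efficiency differences; both are QC'd, not
  modeled.
* The Fisher buffering test conditions on margins; with < 2 LOF lines a
  pair is untestable regardless of effect size — a coverage, not power,
  limit.
* Exact reproduction of any real screen depends on log base, SD convention
  and trim tie-breaks; all are fixed and documented here for that purpose.
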