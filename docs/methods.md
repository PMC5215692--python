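# Methods

## Data model and panel orientation

All genotype handling is oriented by an explicit per-SNP risk/other
allele pair carried in the panel file. Dosage is the count of risk-allele
copies (0/1/2); missing calls stay in the matrix as NaN and are dropped
complete-case per test. The bundled panel covers 29 SNPs over 19
cytogenetic-band loci; because the exact allele definitions of the source
panel were published only as risk-allele frequencies, the bundled
risk/other letters are marked `convention` in the panel file — they fix
an orientation without asserting laboratory identity. One SNP
(rs2066847) is in reality an insertion variant and is likewise coded with
conventional substitution alleles. Four panel SNPs have risk-allele
frequency above 0.5 in controls; "common vs rare" language is therefore
never used internally — only explicit risk-allele orientation.

The printed summary tables of the motivating study ship as fixtures
(`table1`–`table3`). They are inputs to tally and summary operations,
never recomputation targets: several printed odds ratios are not
reconstructible from the printed frequencies under any standard 2×2
formula (e.g. frequencies 0.06/0.01 imply OR ≈ 6.3 where 3.8 is
printed), and two cells conflict between table and text (a CI low bound,
stored from the text with a provenance note; one composite-row p-value,
stored from the table). Percentages in the clinical summary use
round-half-up with missing values excluded from the denominator; the
printed smoking row rounds inconsistently and is documented, not chased.

## Association battery

Each marker × comparison × genetic model yields one 2×2 test:

* allelic: risk vs other allele counts (two chromosomes per subject);
* carrier (dominant): dosage ≥ 1 vs dosage 0 subjects.

Pearson's χ² (no continuity correction) is used unless any expected cell
is below 5 (Cochran's rule), in which case the two-sided Fisher exact
test is substituted and flagged. Odds ratios are `ad/bc` with Woolf
log-scale 95% CIs; when a cell is zero, 0.5 is added to all four cells
for the OR/CI only, never for the test statistic. Markers monomorphic in
both arms are flagged untestable (p = 1, OR = 1) and excluded from
tallies. Hardy–Weinberg consistency is a 1-df χ² goodness-of-fit against
p², 2pq, q² at the sample allele frequency; monomorphic samples return
p = 1 by convention.

The Bonferroni denominator is the number of *loci* (19 for the bundled
panel), not SNPs — 0.05/19 reproduces the conventional 2.6e-3 threshold
for this panel — and is a configurable knob. Tallies count SNP rows by
default; the composite row is countable via a flag because published
counts include it in some strata and not others.

The composite NOD2 marker is 1 if any member dosage ≥ 1, 0 if every
*observed* member is 0, missing only when all members are missing
("optimistic absence"; a `strict` policy that propagates partial
missingness is available). Composites are indicators, so only the
carrier model applies to them.

## Stepwise modelling

Logistic fits are maximum likelihood by IRLS: convergence when the
largest coefficient change is below 1e-8, cap 50 iterations. Complete or
quasi-complete separation is detected (coefficient escaping |β| > 15 on
the dosage scale, or vanishing working weights) and flagged, returning
the last numerically stable iterate; rank-deficient designs raise an
error naming the collinear columns. The selection criterion is the
likelihood-ratio test (most stable at a few hundred subjects per arm;
Wald and score were the alternatives), with conventional `p_enter` =
0.05 and `p_remove` = 0.10 — both configurable. Ties break by candidate
order then name, making the path deterministic. Forward selection
terminates at an LRT-stable subset; when several stable subsets exist
the greedy endpoint need not be the highest-likelihood one, which is an
inherent property of stepwise selection, not an implementation defect.
Candidates are carrier-coded by default (matching the genotype-table
analyses that feed it); dosage coding is available. The composite NOD2
indicator replaces its member SNPs in the candidate set when
significant. Interaction screening adds one product term per pair of
selected markers and LRT-tests it against the main-effects model.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
under a case-control (fixed group sizes) sampling design:

* group sizes default to the study design: 537 controls, 708 cases split
  237 (L1) / 171 (L2) / 300 (L3);
* per-SNP, per-group risk-allele frequencies default to the published
  case/control values; the all-CD case frequency is applied to every
  site because per-site frequencies were never published — simulated
  site contrasts are therefore null unless the user overrides them, and
  the ground-truth file records exactly what was generated;
* genotypes are drawn from Hardy–Weinberg proportions within each group;
* optional pairwise LD between SNPs sharing a locus block: a pair is
  drawn as two haplotypes from the 4-haplotype distribution with
  D = r·√(p_a q_a p_b q_b); infeasible r fails fast with the feasible
  interval reported. Multi-SNP blocks are approximated by a chain of
  pairs, keeping feasibility checks exact;
* per-SNP dropout at a configurable missing rate.

Each (group, SNP-or-pair) draw uses its own PRNG stream spawned from the
master seed, so outputs are bit-identical under reruns and stable under
unrelated config edits. What the generator does *not* emulate: genome
hitchhiking beyond the configured pairs, population stratification,
covariate–genotype dependence, genotyping batch effects. Passing tests
on these cohorts therefore validate the statistical machinery under the
model's own assumptions, not robustness to real-data artefacts.

## Genetic risk score and ROC

Weights are ln(OR) taken from an association table (all-CD allelic
results by default; per-site weighting available). "Positive scores" is
implemented as orientation: a protective marker (OR < 1) has its allele
flipped (oriented dosage 2−d) and OR inverted so every weight is
non-negative and all markers are retained; an alternative reading that
simply drops OR < 1 markers is available by flag. The allele-count score
sets unit weights with the same orientation, so its cutoffs are in
"risk alleles". Whether the motivating study weighted by allelic or
genotypic ORs, re-estimated per site, is unknowable from the published
record; the default here is documented, not asserted as the original
choice. Missing dosages contribute the marker's cohort-wide mean
oriented dosage — using the subject's own case/control group mean would
leak the outcome into the score.

ROC curves sweep thresholds over the pooled unique scores (positive
when score ≥ threshold), bracketed so the curve runs (0,0)→(1,1). The
AUC is U/(n₁n₂) with ties one-half; the trapezoidal integral of the
swept curve is asserted equal at every call since the two are
mathematically identical. The AUC p-value uses the tie-corrected normal
approximation to U; an exact permutation version exists for ≤ 30 pooled
scores and doubles as its oracle. The operating cutoff maximizes
Youden's J and is reported as the midpoint between the optimal threshold
and the next lower distinct score; at a tied optimum the descending
sweep keeps the first (highest-threshold, most specific) point.

## Numerical and design notes

* χ²/Fisher p-values and the Mann–Whitney U come from scipy; the test
  suite checks them against hand-rolled textbook/enumeration oracles so
  the implementation and its reference stay on separate routes.
* The IRLS fitter is checked against statsmodels log-likelihoods to
  1e-6 on random datasets; stepwise selection is replayed by an
  independent statsmodels-based implementation and certified LRT-stable
  by exhaustive subset enumeration.
* Simulation-heavy checks use the study's group sizes where the check is
  about the study conditions (708/537 GRS cohorts, 100 seeds), and
  reduced-but-calibrated sizes elsewhere (e.g. 500+500 null cohorts for
  type-I calibration, 10,000 per arm for ln-OR recovery); these sizes
  are the package's own choices and are fixed in the tests.
* Simulating from the published 2-decimal frequencies yields weighted
  GRS AUCs centred near 0.78 — somewhat above the 0.70 measured on the
  real data — because the rounded frequencies imply slightly stronger
  contrasts than the published odds ratios. The tests treat the
  published AUCs as qualitative anchors only.

## Known limitations

No trend (Armitage) test, covariate-adjusted association, permutation
p-values or FDR; no penalized regression or multinomial site model; no
cross-validation of the GRS (in-sample weights carry optimism); VCF
input is matched by variant ID only. These are scope boundaries, not
roadmap items.
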