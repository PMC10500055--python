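# Methods

## Barrier indices and the cascade

Each reproductive barrier is quantified as `RI = 1 − 2H/(H + C)`, with
*H* an outcome of interstrain (or hybrid-line) crosses and *C* the same
outcome of intrastrain controls sharing the female strain — female
strains differ in male acceptance and fecundity, so controls are always
matched on the female side. The index is scale-invariant (proportions
and mean counts enter identically), lies in [−1, 1], is antisymmetric
under exchange of H and C, and is returned as NaN when `H + C = 0`
(barrier unmeasurable; skipped downstream).

Sequential contributions follow `AC_n = RI_n (1 − Σ_{i<n} AC_i)` with
total `T = Σ AC_i`. The implementation computes the recursion directly;
the algebraic identity `T = 1 − Π(1 − RI_i)` is used as an independent
oracle in the tests (agreement to 1e−12 over random ladders). T is
order-invariant although individual contributions are not; with all RI
in [0, 1], T ∈ [0, 1] and is monotone in every barrier. Negative RIs can
compound to T < −1; values are reported as computed, never clamped.
Unstudied barriers are skipped and later positions renumber — they are
not imputed as zero, since a missing measurement is not evidence of
absence.

Re-cascading *rounded* published per-barrier values does not generally
reproduce published totals for partially isolated pairs (those were
computed from unrounded estimates); only totals structurally forced by a
complete first barrier (T = 1) are exact, and only those are asserted
exactly.

## Outcome metric per barrier

The mapping from experimental stage to H/C metric is fixed by the study
design and configurable per barrier:

| barrier | records | metric |
|---|---|---|
| sexual isolation (parentals) | P generation | copulation proportion (assessed pairs only) |
| hybrid-♀ inviability, CI-free | P | mean daughters per female-bearing cross |
| hybrid-♀ inviability, with CI | P, untreated | proportion of crosses with ≥1 daughter |
| hybrid-♀ behavioural sterility | F1-female mating trials | copulation proportion |
| hybrid-♀ physiological sterility | F1-female oviposition | proportion with any F2 offspring |
| hybrid-♀ reduced fertility | F1-female oviposition | mean F2 brood over offspring-bearing crosses |
| hybrid-♂ inviability | virgin F1 females | mean sons over offspring-bearing crosses |
| hybrid-♂ behavioural sterility | F2-male backcrosses | copulation proportion |
| hybrid-♂ physiological sterility | F2-male backcrosses | proportion with ≥1 daughter |
| hybrid-♂ reduced fertility | F2-male backcrosses | mean daughters over daughter-bearing crosses |

Conditional means deliberately use offspring-bearing crosses only
(occurrence and intensity are separate barriers); occurrence metrics use
all replicates as denominator. Copulation denominators exclude records
whose mating state was not observed. Hybrid-male barriers from
behavioural sterility onward are estimated separately against
parental-type females of both strains and the two indices arithmetically
averaged before entering the cascade. Where tetracycline-treated
(endosymbiont-free) replicates exist, all barriers except the with-CI
inviability variant use them, so the CI-free ladder is not contaminated
by CI. Significance (contingency test for proportions, permutation test
for counts) is annotation only: the cascade uses every estimate, bold or
not.

## Statistical decision layer

Binary outcomes: Pearson's chi-squared when every cell of the
contingency table exceeds five (Yates-corrected on 2×2, matching the
usual R default), else Fisher's exact test. The 2×2 Fisher p is the
hypergeometric closed form (two-sided: sum of table probabilities not
exceeding the observed one, with a 1e−7 relative tie tolerance as in
standard implementations). For r×c tables the margin-constrained space
is first counted by dynamic programming; up to 200,000 tables it is
enumerated exactly, beyond that a seeded Monte-Carlo estimate (default
10,000 tables drawn by label permutation) is returned with its
simulation standard error. Bonferroni correction is `min(1, p·k)` with
*k* the number of single comparisons within one group test.

Count outcomes: all-pairs contrasts with three interchangeable engines —
Tukey's HSD on a normal linear model when Shapiro–Wilk and Levene
diagnostics (α = 0.05) pass, a Poisson GLM with quasi-Poisson or
moment-matched negative-binomial variance and Bonferroni-adjusted Wald
contrasts on request, and a distribution-free permutation engine
(Welch-t statistic, max-T familywise adjustment, 10,000 label
shuffles, fixed seed) as the reference route so results never depend on
a fitting engine. Sperm totals: Shapiro–Wilk per group at 0.05 (the
conventional check at these sample sizes; configurable), then Welch's
t-test if both groups pass, else the Wilcoxon rank-sum test with
continuity correction; medians and quartiles are reported alongside.
All tests are two-sided; significance at p < .05.

Sperm totals are estimated from three randomly chosen of eight spots of
a 20-µL suspension: `sum × 20 / 3`, doubled for seminal vesicles because
one of the male's two vesicles is opened.

## Synthetic data

The generator reproduces the crossing design: for each ordered strain
pair it emits parental inter- and intrastrain crosses, F1-female mating,
oviposition and virgin-oviposition trials for hybrid and control lines,
and F2-male backcrosses to both parental female strains. Mating is
Bernoulli; brood sizes are negative binomial (mean µ, dispersion k;
Poisson as k → ∞) — overdispersion is the norm for parasitoid clutch
data; daughters are binomially thinned from the brood; virgin and
unmated females produce sons only. CI zeroes the daughters of affected
crosses with penetrance *c* (all-or-nothing per cross, matching the
occurrence collapse seen in the data; binomial thinning available).
Hybrid effects are multiplicative factors on mating probability, brood
size or daughter share. Daughters lost to inviability or CI are counted
as sons in the record; parental brood totals are not used by any
barrier metric, so this bookkeeping choice is inert.

Defaults emulate the study conditions: 40 replicates per combination
(the CI experiment's scale), intrastrain mating probability 0.75 and
~60% daughters among mixed broods (the range of the control bars in the
study's figures), mean brood 30 with dispersion k = 5, and CI penetrance
0.525 (the value whose all-or-nothing signature `RI = c/(2 − c)` equals
the published 0.356).

`true_ri` returns the model-implied expected value of each barrier's
index in closed form, using the negative-binomial zero mass
`P0 = (k/(k+µ))^k` for occurrence metrics and the zero-truncated mean
`µ/(1 − P0)` for conditional count metrics. These are targets for the
*estimator applied to the model*, so estimation bias (Jensen curvature
of the index in finite samples) is part of what the recovery tests
measure: over 500 replicate experiments at n = 40 the mean estimate per
barrier stays within ±0.03 of the closed form (within ±0.01 in
practice).

Sequence simulation uses Jukes–Cantor-style site flipping on a star tree
of clade ancestors. Branch flip fractions are calibrated through the
multiplicative identity `1 − (4/3)d = Π(1 − (4/3)f_branch)` so expected
leaf-to-leaf p-distances hit the requested between-/within-clade
targets; multi-clade targets are solved by least squares in log space.
Randomness derives from one seed with per-group substreams keyed by a
CRC of the group label, so adding a combination never perturbs existing
draws and equal seeds give bit-identical output.

What the generator does *not* emulate: host-quality and block effects,
temporal drift between experimental stages, observation error in sexing,
within-strain genetic variation, or imperfect endosymbiont transmission.
Passing recovery tests therefore shows the estimators are consistent
under the stated sampling model, not that real data meet that model.

## Distances and delimitation

Uncorrected p-distances (mismatches over compared sites) with pairwise
deletion of gap/ambiguity sites by default; complete deletion is an
option (the study's software default is unstated, and reproducing its
printed clade means would additionally need the archived sequences, so
both policies are exposed). Delimitation is single-linkage: clusters are
connected components of the graph with edges `d < threshold` — the
transitive interpretation a fixed barcode gap implies. Raising the
threshold can only coarsen the partition. The BSC partition thresholds
pairwise total isolation at 0.8 by default — just below the 0.83–1.0
band treated as substantial isolation — splitting a pair when *either*
direction exceeds it (one-way isolation already restricts gene flow);
0.95 is reported alongside where relevant. Concordance is scored per
pair (lumped/split agreement, explicit conflict lists) plus the Rand
index.

## Numerical and design choices

* Full-precision propagation everywhere; rounding only at display
  (proportions 1 d.p., indices 3 d.p.).
* Ties in the two-sided Fisher p use a 1e−7 relative tolerance on table
  probabilities.
* Empty groups yield NaN metrics and skipped barriers, never silent
  drops; degenerate tests (all values tied) return p = 1 with a warning
  rather than failing.
* "Ecological isolation" is carried as a qualitative annotation and
  never enters the numeric cascade.
* The pipeline's problem sizes (40 replicates per combination, 500
  recovery replicates, 10,000 permutations, 658-site barcodes) are the
  study's own scales and default throughout.

## Limitations

Published per-barrier indices are printed rounded, so partially isolated
pairs' totals can only be reproduced approximately from them. The exact
p-values of the study are not reproducible without its deposited
replicate-level data; the statistical layer is instead validated by
construction (enumeration oracles, null calibration). The backcross
averaging precedes the cascade, so a strain-asymmetric hybrid-male
barrier is represented only by its mean.
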