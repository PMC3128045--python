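# Methods

This note documents the statistical models implemented in `physaiso`, the
choices made where the design was genuinely open, what the synthetic-data
generators do and do not emulate, and known limitations.

## Sexual isolation from mate-choice contests

A mate-choice trial places *n* + *n* adults from two populations in one
arena and records, per snail, only its first successful copulation in the
male role. Pooled over trials this gives a 2×2 table of counts
n(male population × female population).

**PSI and IPSI.** Expected cell counts are marginal products
e_ij = row_i × col_j / N; PSI_ij = n_ij / e_ij; and

IPSI = (PSI_aa + PSI_bb − PSI_ab − PSI_ba) / (PSI_aa + PSI_bb + PSI_ab + PSI_ba),

bounded in [−1, 1], 0 under random mating given the marginals, 1 under
complete positive assortment. A PSI coefficient whose expected count is
zero (an empty row or column marginal) is *undefined*, not zero, and IPSI
raises an error naming the empty marginal. Conditioning on both marginals
is what makes IPSI insensitive to unequal mating propensities — a
population that simply mates more often inflates its row total and the
expectation together.

**Bootstrap test.** N pairings are resampled multinomially from the
observed cell proportions (default `n_boot = 10,000`); the bootstrap SD of
IPSI is the standard error, and t = IPSI/SE is referred one-tailed
(positive-assortment alternative) to a standard normal by default, or to a
t distribution with n_valid − 1 df (`reference="t"`) — at bootstrap sample
sizes in the thousands the two are indistinguishable, and nothing in the
original description of the procedure fixes the reference, so both are
exposed. Replicates with an empty marginal are dropped and counted. A
degenerate bootstrap (SE = 0) resolves by the point estimate: p = 0.5 when
IPSI = 0, p = 0 when IPSI > 0.

**Heterogeneity across trials.** Before pooling, the trials × 4-category
table is tested for homogeneity with a Monte-Carlo exact test: tables are
sampled under fixed margins with Patefield's algorithm (default 20,000
draws, seeded) and compared by Pearson chi-square. An r×c Fisher exact test
has no convenient closed form at these shapes; the margin-fixed Monte Carlo
gives the same conditional p-value up to simulation error, with an add-one
correction so a perfectly homogeneous observation reports p = 1.

**Multiple testing.** Star decisions across a family of comparisons use
Holm's step-down procedure (sort p-values ascending, compare the k-th with
α/(m−k+1), stop at the first failure), delegated to
`statsmodels.stats.multitest`.

**Design-bias constant.** Because the focal snail chooses among the other
2n − 1 individuals, random pairing is biased toward heterogametic pairs:
homogametic odds are (n−1):n — 9:10 at n = 10, i.e. a homogametic fraction
of 9/19 ≈ 0.474 rather than 1/2. `null_pairing_odds` and
`null_homogametic_fraction` return the closed forms; the arena simulator
reproduces them.

A consequence worth stating plainly: this design bias propagates into IPSI
itself. Under the no-isolation arena null the expected IPSI is not 0 but
approximately 2·(9/19) − 1 = −1/19 ≈ −0.053 (simulated −0.054 ± 0.003 at
N = 60 pooled events, identical for equal and 2:1 propensities; multinomial
tables without the design bias recenter at ≈ 0). Mating-propensity
asymmetry adds no further bias, which is the property that motivates using
IPSI, but a strict |mean null IPSI| < 0.05 calibration bound cannot be met
by any simulator faithful to this arena design, and the package makes no
attempt to re-center the index. The one-tailed (positive) test is slightly
conservative as a result.

## No-choice crossing analysis

Ten outcross pairs are observed alongside two sets of ten within-population
control pairs; embryos are counted weekly, hatchlings are attributed to the
oviposition week of their cohort, and a pair's record is censored at the
first parental death.

- **Anchoring.** "Week 1" is set independently per 10-pair set as the first
  calendar week in which at least 3 pairs oviposit (counted per week, not
  cumulatively); fecundity and viability use a 10-week window from the
  anchor. A set that never reaches the threshold has no anchor and is
  excluded from fecundity/viability testing, with a flag.
- **Delay test.** Ages at first oviposition are pooled (experiment plus the
  *slower* — later-median — control), split at the combined median with
  ties excluded, and tested one-tailed by Fisher's exact test for an excess
  of experimental pairs above the median. Non-reproducing pairs are the
  most delayed observations; they are ranked above every finite age
  (implemented by capping at one week past the latest observed onset so the
  combined median stays finite). A both-controls variant is available
  (`conditioning="both"`, reporting the less favourable p).
- **Fecundity.** Pair mean weekly embryos from the pair's first oviposition
  week to its last surviving week inside the window: leading zeros are
  immaturity and ignored, interior zeros are true failures and kept,
  postmortem weeks are censored, and a surviving pair that never oviposits
  scores 0.
- **F1 viability.** Only cohort weeks (embryos > 0) enter either mean;
  viability = mean cohort hatchlings / mean cohort embryos, which with
  cohort attribution is bounded by [0, 1]. Zero-embryo weeks are excluded
  from *both* means — isolated in one function so the convention is easy to
  audit. Viability is undefined (not 0) for a pair with no embryo
  production.
- **Depression tests.** The directional two-group comparisons are exact
  one-sided Mann–Whitney tests (the two-group case of a Kruskal–Wallis
  ANOVA given a direction), Bonferroni-doubled for the two controls; a
  3-group omnibus Kruskal–Wallis p is emitted for reference. "Depressed"
  requires significance against *both* controls. Across experiments the
  delay p is additionally Bonferroni-scaled by the number of comparisons in
  the run's configuration.
- **F1 × F1 fertility.** Nine crosses (three sibships × early/middle/late)
  are tallied into (pairs ovipositing, pairs with viable F2); "sterile"
  means oviposition happened but no viable second generation appeared.

## Selfed-versus-hybrid classification

Selfing is modelled as a random union of two gametes of one parent
(Mendelian selfing, not clonal copying), outcrossing as one gamete from
each. A hypothesis (self-A, self-B, outcross) survives iff the offspring
genotype is producible at every informative locus; missing genotypes skip
the locus; a single incompatible locus vetoes a hypothesis (a configurable
`max_incompatible_loci` relaxes this for genotyping error, default strict).
The call is *hybrid* only when outcross is the sole survivor, *ambiguous*
when several hypotheses survive, and an error when none does or when an
offspring allele occurs in neither parent. Exclusion is monotone: adding
loci can only remove hypotheses, so ambiguity never increases, and one
fixed parental difference removes it entirely. Definite calls are provably
never wrong under the generator's assumptions (no genotyping error), which
the test suite confirms over 10,000 simulated offspring.

Brood proportions are reported over definite calls, with the ambiguous
fraction separate.

## Compatibility models on the species tree

Populations are treated as fixed (effectively homozygous) at each
compatibility locus, so a cross's phenotype is a deterministic function of
the per-locus match pattern — the models are qualitative, with no
penetrance parameter:

- viability (loci J, K; J epistatic over K): J match → full; J mismatch
  with K match → partial; both mismatch → none;
- mating (complementary loci J, K): any match → compatible, else isolated;
- F1 fertility (one locus): match → fertile, else sterile.

"Partial" viability is a single class regardless of the observed hybrid
fraction, and the observed mating matrix is encoded from the Holm-corrected
significance pattern, not raw IPSI magnitudes. Populations with no
scoreable hybrids (e.g. the most distant one, for fertility) are omitted
from the matrix rather than assigned a class; consistency checks only
evaluate scored pairs, and origin counting then runs on the induced
subtree.

**Origin counting.** The root is fixed at the ancestral allele (full
compatibility at the base of the tree); the minimum number of allele
origins is the fixed-root small-parsimony cost under unit changes, computed
by dynamic programming over subtrees and verified in the tests against
exhaustive enumeration of internal labelings on random trees of up to six
tips. Unrooted parsimony is deliberately not offered.

**Minimal-model search.** A per-locus assignment is canonicalised as a set
partition of the populations into allele classes with one block (possibly
none) marked ancestral; derived classes are numbered deterministically, so
relabelled duplicates are never enumerated. The search covers every locus
count up to `max_loci` with a rule defined for it, bounded by `max_alleles`
and eight populations, keeps exactly-consistent assignments, and returns
all ties at the minimum total origins. For the five-population system this
is ≈ 200 assignments per locus and ≈ 4 × 10⁴ two-locus combinations —
fully exhaustive in well under a minute.

Two findings from running the search on the encoded matrices: (1) no
single-locus model is consistent with the viability matrix, while the
two-locus epistatic minimum is 4 total origins and includes the published
genotypes among six tied partition structures; (2) for fertility, because
the carolinae × pomilia pair produced no hybrids to score, a one-origin
model (a single incompatibility allele on the *acuta* stem, with carolinae
and pomilia ancestral) is consistent with the scored pairs — the published
two-origin reconstruction becomes the unique-minimum class only if the
unscored pair is additionally assumed sterile.

## Synthetic-data generators

The generators emulate the study designs with known ground truth; their
defaults are the study's conditions.

- **Arena trials** (`MateChoiceSimParams`): n = 10 per population, 3 trials
  per comparison. A focal snail is drawn among those not yet recorded as
  male, weighted by its population's mating propensity (default equal); a
  partner is uniform among the other 2n − 1; the pairing is realised with
  probability 1 if homogametic, w if heterogametic (w = 1 no isolation,
  w = 0 complete; directional weights available, a single scalar by
  default). Isolation acts on acceptance, not encounter rate, reflecting
  rejection in the female role. An attempt cap (default 400 × 2n) mirrors
  the finite observation window.
- **No-choice experiments** (`NoChoiceSimParams`): onset of reproduction
  1 + Poisson(mean − 1) weeks (default mean 5, within the observed week
  3–9 onsets); weekly fecundity negative-binomial with mean 60 and size 5
  (observed pair medians ran roughly 25–117 with very wide ranges, so a
  Poisson would be far too narrow; the size parameter is configurable);
  per-cohort hatch survival binomial (default 0.7, within the observed
  0.36–0.87 viabilities); 10% of pairs never reproduce (7–10 of 10
  reproduced in the field data); weekly pair survival 0.998 (about one
  death per 30 pairs over 16 weeks, as observed); 16 weeks, 10 pairs per
  set. Outcross hatchlings draw a true class from a selfing mixture
  (default P(self-A) = 0.25, P(self-B) = 0.56, remainder hybrid — the
  published mixed-brood composition).
- **Markers** (`MarkerSimParams`): offspring genotypes by Mendelian gamete
  draws given parental genotypes and the true class.

What the generators do *not* emulate: within-trial behavioural dynamics
(multiple copulations, rejection bouts, the 6-hour clock — only
first-copulation outcomes are modelled), egg-mass structure below the
weekly cohort, size/growth effects on mating roles, genotyping error, and
linkage between marker loci. Passing recovery tests therefore demonstrates
correctness of the estimators under Mendelian, cohort-consistent,
error-free data — not robustness to scoring error or behavioural
complexity in real records.

## Numerical conventions

All randomness flows through `numpy.random.Generator`; drivers expand one
top-level seed per module via `SeedSequence`, and every generator is
bit-reproducible under a fixed seed. Monte-Carlo p-values use an add-one
correction and never report 0. Ties at the combined median are excluded
from the delay test's 2×2 table. Weeks are 1-based calendar indices before
anchoring. Bootstrap replicates and pair values that are undefined are
dropped *and counted* rather than silently imputed.

## Test problem sizes

The heavier suite checks run at sizes chosen to keep the whole suite around
half a minute while leaving comfortable statistical margins: 10,000 arena
trials for the design constant (MC error ≈ 0.001 against a ±0.01 band),
1,000 pooled null tests with 1,000-replicate bootstraps for calibration,
10,000 simulated offspring for classifier exactness, and 40–60 random
trees against the brute-force parsimony oracle.
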