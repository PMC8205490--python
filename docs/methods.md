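# Methods

## The classification model

An accession's seed aliphatic glucosinolate (GSL) profile is reduced to
three enzyme states and one chemotype label.

**MAM (GS-Elong).**  C3 = 3MT + 3MSO + 3OHP + Allyl; C4 = 4MT + 4MSO +
4OHB + 3-Butenyl + 2-OH-3-Butenyl (µmol · g⁻¹ seed).  A strict C3
majority calls MAM2, a strict C4 majority MAM1.  "Majority" is read as a
strict inequality everywhere in the package: an exact tie — and any
profile whose two chain totals both sit at or below the detection floor
(`floor`, default 0) — is refused as `undetermined` rather than guessed.

**AOP (GS-AOP).**  Three fractions share the total short-chain aliphatic
pool (all nine compounds) as denominator: alkenyl = (Allyl + 3-Butenyl +
2-OH-3-Butenyl)/T, alkyl = (3OHP + 4OHB)/T, MSO = (3MSO + 4MSO)/T.  The
strictly largest fraction names the state (AOP2 / AOP3 / AOP null).  MT
compounds appear in the denominator only, so the three fractions can sum
to < 1; a profile whose pool is mostly MT is still called by the argmax
but flagged `mt_dominated`, since such profiles sit upstream of the AOP
step and the call is weakly informative.

**GS-OH.**  Functional epistasis: the enzyme's substrate (3-Butenyl)
exists only in MAM1/AOP2 accessions, so outside that background the
state is `masked` and no amount of 2-OH-3-Butenyl is interpreted.  Where
readable, 2-OH-3-Butenyl/(2-OH-3-Butenyl + 3-Butenyl) > `gsoh_threshold`
(default 0.5, mirroring the majority logic) calls a functional enzyme.

**Chemotype.**  (MAM2, null) → 3MSO; (MAM1, null) → 4MSO; (MAM2, AOP3) →
3OHP; (MAM1, AOP3) → 4OHB; (MAM2, AOP2) → Allyl; (MAM1, AOP2) →
3-Butenyl or 2-OH-3-Butenyl by GS-OH state.  Any undetermined input
propagates.  Every profile maps to exactly one of the eight output
labels (seven chemotypes + undetermined), and all calls are invariant
under positive rescaling of the profile.

## Heritability and adjusted means

For each compound the fixed-effects model `amount ~ accession +
replicate + plate` (all categorical) is decomposed by sequential Type-I
sums of squares with accession first, computed by orthogonal projection
(accession absorbed by within-group demeaning, then the replicate and
plate dummy blocks added Frisch–Waugh style).  The four components
partition the total SS exactly (±1e-9 relative), and broad-sense
heritability is the accession share, H² = SS_accession/SS_total — the
eta-squared of a replicated fixed-effects design.  For balanced designs
this is order-insensitive.  H² is invariant under affine rescaling of
amounts.

Two properties of this estimator matter for interpretation:

* Its null expectation is (a−1)/(ar−1) ≈ 1/r for a accessions and r
  replicates (the SS share of pure noise is Dirichlet-distributed), so
  with 2 replicates the estimator cannot fall meaningfully below ~0.5.
  The simulator validates requested targets against this bound; recovery
  experiments at a target of 0.3 use 4 replicates.
* It is a fixed-effects SS share, not a REML variance-component ratio;
  no shrinkage, no mixed model (deliberately out of scope).

Adjusted per-accession means ("emmeans") are model predictions averaged
uniformly over the observed replicate and plate levels.  For balanced
designs this equals the accession's arithmetic mean; under unbalanced
plate assignment it corrects accessions measured on biased plates (the
package's tests verify this against explicit normal equations).
Accessions never measured for a compound get 0 (treated as below
detection) with a warning.

PCA of the accession × compound emmean matrix centers columns and, by
default, scales them to unit variance (`scale=True`; recorded as a
switch because both conventions are defensible — unscaled PCA lets the
high-abundance compounds dominate).  Scores/loadings come from the SVD;
variance shares are λ_k/Σλ; component signs are fixed so the
largest-magnitude loading is positive.

## Environment-association models

Accessions are assigned `south` when strictly below a piecewise-constant
boundary latitude (default: 42.5° N west of 2° E for the Pyrenees,
45.5° N between 2–18° E for the Alps, 46.5° N east of 18° E for the
Carpathians; points exactly on the boundary are `north`).  The boundary
is a configuration object, not a constant, because any published
"mountain chain" split is an approximation.

The response is either the binary Allyl vs 2-OH-3-Butenyl contrast
(coded 0/1 and fit by OLS — a linear probability model, keeping the
analysis within plain `lm` semantics) or the side-chain carbon number
(3/4 from the MAM state).  Regional fits use main effects (genomic
group + five covariates); the pooled fit adds the geography main effect
and all geography × covariate and geography × genomic-group
interactions.  Per-term p-values are Type-II partial F-tests, the
conventional choice when a single p per term is reported.  Factor
levels with fewer than two observations are merged into `other` with a
warning; rank-deficient designs are reported (aliased columns named via
pivoted QR), not silently repaired.

## Haplotype trees

Distances are raw p-distances with pairwise deletion: only sites where
both sequences carry an unambiguous A/C/G/T are compared.  This is the
minimal-assumption metric appropriate to within-species divergence
(a few percent), where multiple-hit corrections are negligible.

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q
criterion.  Determinism: taxa are processed in lexicographic label
order and Q ties are broken by the smallest (i, j) index pair.
Negative branch lengths are clamped to zero with the deficit moved to
the sibling edge, preserving the pair's summed length.  Rooting places
the root at the midpoint of the outgroup's pendant edge; the operation
dissolves a previous binary root first, so it is idempotent and
preserves all tip-to-tip path lengths.

Bootstrap supports resample alignment columns with replacement, rebuild
the NJ tree per replicate, and score each internal edge of the original
tree by the fraction of replicates containing the same bipartition
(bipartitions normalized to the side away from a fixed anchor taxon).
Supports live in [0, 1] and are deterministic given the seed.

**Clade cutting.**  The ingroup is cut into k clades by greedily cutting
edges in order of decreasing branch length (ties by preorder position),
skipping any cut that fails to separate a new tip-bearing component.  A
depth-based rule ("cut the k−1 edges nearest the root") was considered
and rejected: clade radiations are nearly star-like, so NJ resolves the
backbone into arbitrary near-zero edges whose depths interleave with
within-clade edges, and depth cutting then splits inside clades before
separating them.  Length-based cutting targets exactly the deep
divergences that define haplotype groups, recovers the simulated eight
clades exactly, degrades to a single clade at k = 1 and to singleton
clades at k = n.  Clade↔chemotype concordance is majority-label purity
per clade, size-weighted for the overall score.

## Loss-of-function frequencies

Chemotype calls partition the classified cohort into *expressed*
(C4-alkenyl: 3-Butenyl and 2-OH-3-Butenyl, where GS-OH has a phenotype)
and *masked* (everything else); undetermined accessions join neither.
Carrier fractions are kept as exact rationals (`fractions.Fraction`) and
rounded half-away-from-zero to three decimals only for display.
Mutation-class carriers are supplied as a table rather than called from
sequence — variant calling is out of scope — and a class whose masked
carriers cannot be ascertained is reported `Unknown`, never imputed.
Enrichment uses the one-sided Fisher exact test (alternative: LOF more
frequent in the masked set), per class and pooled, with the
conditional-MLE odds ratio; the test is exact at these counts, and the
suite verifies scipy's p-values against a direct hypergeometric tail
enumeration to 1e-12.

## The synthetic cohort generator

The generator's defaults are the study conditions the analyses assume:
797 accessions × 2 replicates on 17 plates, 23 detected compounds, a
chemotype mixture of 47% Allyl / 27% 2-OH-3-Butenyl with the remainder
spread over the other five classes, dominance 0.85 and a heritability
target of 0.83.

**Accessions.**  Chemotypes are multinomial in the configured weights
(with at least two carriers of every positive-weight class guaranteed at
n ≥ 50, so all eight MAM clades — three C3, five C4 — and six AOP
structures A–F are represented).  Major-chemotype accessions go south
with probability 0.5, where Allyl and 2-OH-3-Butenyl are separated
sharply at the configured longitude; all other accessions (and the
remaining majors) are placed north, where every chemotype co-occurs.  A
GS-OH LOF allele is drawn for every accession — at rate 0.147 where the
locus is masked, and deterministically consistent with the chemotype
where it is expressed — so the epistasis-conditioned frequency contrast
has a planted signal.

**Profiles.**  log-amount = genetic value + replicate + plate +
residual.  Genetic values of the nine short-chain compounds encode the
chemotype composition (dominant compound carries the `dominance` share,
the other eight split the rest evenly — the within-chemotype leakage is
deliberately a free parameter, as no canonical value exists) times a
per-accession size effect (sd 0.25 on the log scale); the fourteen
long-chain/indolic fillers get independent per-accession effects
(sd 0.35).  Amounts are log-normal: positive, right-skewed, with
multiplicative noise — the standard shape of HPLC metabolite data.

Noise is calibrated so the *realized* SS-share heritability matches the
target on the scale the ANOVA actually runs on (raw amounts):
with ratio = ((a−1)r − (ar−1)t)/((ar−1)t − (a−1)) the within/between
variance ratio that yields SS share t, the filler log-noise solves
Var(e^ε)/Var(e^g) = ratio, i.e. σ_w² = log(1 + ratio·(1 − e^(−σ_g²))).
The nine chemotype compounds instead get a modest fixed-CV noise floor
(≈20% at the default target, scaling to exactly zero as t → 1): their
compositional genetic variance is enormous by construction, so their
realized H² runs high — which is also what real chemotype-determining
compounds do — while the 14 fillers pin the across-compound *median* at
the target.  Within-noise splits 83% residual, 15% plate, 2% replicate.

**Sequences.**  One random root; eight clade ancestors mutated from it
at `clade_mutation_rate` (default 0.06/site); tips mutated from their
clade ancestor at `tip_mutation_rate` (default 0.008); an outgroup
mutated from the root at 4× the clade rate.  Gap-free and equal-length
by construction.  Defaults give within-clade p-distances ≈ 0.016,
between-clade ≈ 0.12 and outgroup distances ≈ 0.26, comfortably
separating the scales the tree stages rely on.

**Environment.**  The five covariates (bio5/bio6 in °C, bio13/bio14 in
mm, coast distance in km) are smooth latitude/longitude gradients plus
substantial local noise (sd 2.5 °C, 9–14 mm, 70 km).  The noise level is
a deliberate realism choice: purely gradient-driven layers are nearly
collinear, which would make partial F-tests of any single layer
powerless by construction, whereas real climate layers decorrelate
locally.  The genomic group is a six-level categorical with
region-dependent frequencies.  When effect sizes are supplied, the
Allyl/2-OH-3-Butenyl contrast is re-drawn from a logistic model on the
standardized covariates (optionally with separate southern slopes), and
the truth records are updated consistently; with all slopes zero the
contrast is independent of geography — the null used to check p-value
calibration.

**What the generator does *not* emulate.**  No linkage or coalescent
structure (clades are categorical states, not genealogies); no
recombination, structural variants or transposable elements; no
compound-to-compound correlation beyond the chemotype composition and
the shared size effect — so the PCA eigenstructure of real data, which
reflects unknown pathway covariances, is not reproduced and no specific
PC1+PC2 share is asserted; no spatial autocorrelation beyond the smooth
covariate gradients; no measurement censoring at a detection limit.
Passing tests therefore demonstrate that the *procedures* recover known
structure under the stated statistical assumptions, not that real data
satisfy those assumptions.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at the
study size (797 accessions × 2 replicates × 23 compounds; seconds per
stage) and the tree stages at 60–100 accessions with 100 bootstrap
replicates, which keeps every deep split's support estimable while the
whole suite completes in a few minutes.  Association-model calibration
uses 200 null replicates (Kolmogorov–Smirnov uniformity at the 1% level)
and 100 replicates for power at the configured slope of 1.5 per SD.
Exact comparisons are asserted to 1e-12 (closed forms, Fisher
enumeration), linear-algebra identities to 1e-8–1e-10, and stochastic
recoveries at ±0.05 (heritability medians) or ±4 percentage points
(chemotype frequencies at n = 797).
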