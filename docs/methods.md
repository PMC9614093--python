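# Methods

## Data model

A roster is two delimited tables. The ego table has one row per child
(identifier, age in months, the child's own race category set and
languages, out-of-home-childcare flag, urbanicity label, optional zip-level
neighborhood race/language proportion profiles). The alter table has one
row per network member: person or group node, relationship label, age in
years, race category set, language set (with a preverbal flag for infants),
the contexts in which the alter interacts with the child, and three
optional intensity measures. Multi-valued cells use `|`; neighborhood
profiles are serialized inline as `category:proportion` items. Races follow
a fixed seven-category vocabulary with alias normalization; unknown tokens
are row-level errors that list the vocabulary.

Two protocol variants are modeled, mirroring how such questionnaires are
administered in practice: a longer *lab* form that collects relationship
intensity but not interaction contexts for density, and a shorter *museum*
form that collects contexts (hence density and component-attribute
patterns) but not intensity. Metrics whose ingredients were not collected
are explicit missing values, never zeros.

### Group nodes

A multi-person node such as "daycare/preschool class" counts toward network
size, and its context memberships participate in tie inference (the class
is tied to the named friends from that class). It is excluded from
kin/adult/intensity denominators and from race/language profiles unless the
relevant attribute was actually reported, since person-level demographics
of a group are undefined. A person appearing in two contexts is one node
with two context memberships, not two nodes.

## Structure

Ties are inferred *only* from shared contexts — pairwise acquaintance
questions would make a parent interview impractically long — so every
component is a union of overlapping contexts. Density is 2T/(N(N−1)),
undefined below two alters; the component ratio (C−1)/(N−1) is 0 for a
single component and 1 when every alter is isolated. Components come from
`networkx` connected components; tests check them against an independent
reachability oracle.

## Composition

Kin classification is a normalized lookup in a shipped label→kin taxonomy
(configurable via YAML/CSV; unknown labels are an error in strict mode,
non-kin with a warning otherwise). The adult boundary is 13 years: age < 13
codes "child", ≥ 13 "adult", missing age stays missing and leaves the
adult-proportion denominator.

Intensity is a cohort-level composite. Over the pool of all relationships
with all three measures (activity count, ordinal closeness on any numeric
scale, waking-hours share in [0, 1]), each measure is z-scored — population
(n) denominator; any consistent choice yields the same split — the three
z-scores are averaged, and relationships above the pooled median are
labeled high, the rest low. Ties at the median go to "low": deterministic,
and with distinct scores and an even pool the split is exactly half/half.
A zero-variance measure contributes 0 for everyone, with a warning. The
pool is defined by the caller; the cohort scorer pools every person alter
with complete intensity data.

## Diversity

Entropy is −Σ p log₂ p with the 0·log 0 ≡ 0 convention, over category
proportions among alters with a known attribute (missing-attribute alters
are dropped and proportions renormalized). A multi-category individual is
collapsed to "Mixed/Biracial" for entropy only; the raw category set is
retained on the record because EI sameness compares sets: an alter is
same-race iff their category set intersects the child's, so a Black/White
biracial child matches White, Black, or Black/White alters. An alter
labeled only "Mixed/Biracial" (component races unknown) compared to a
monoracial child is coded missing rather than guessed. Linguistic sameness
codes an alter different iff they speak a language outside the child's set;
preverbal infants are therefore same. EI = (D−S)/(D+S) over coded alters —
the denominator excludes uncodable alters rather than using raw N, since a
missing attribute cannot be either same or different.

Language entropy buckets each alter into English-monolingual,
English-bilingual, non-English-monolingual, other-multilingual, or
preverbal. Rare categories ("Native American", "Other") are kept distinct;
nothing is pooled.

Component-level entropy is computed over each component's own members; the
zero-entropy proportion divides by the number of components with a defined
entropy. The typology is: overall entropy 0 → *no-diversity*; entropy > 0
and zero-proportion ≥ 0.5 → *segregated*; entropy > 0 and zero-proportion
< 0.5 → *integrated*. Two boundary cases are resolved explicitly: a
zero-proportion strictly between 0 and 0.5 falls in *integrated* (the three
classes then partition all networks), and a network whose components are
each homogeneous but of different races (entropy > 0, zero-proportion 1) is
*segregated* with a warning — it is patterned maximal segregation, and
real cohorts rarely contain it, but synthetic ones do.

Numerical tolerances: profile sums are validated to 1 ± 1e-9; entropies
below 1e-12 are treated as exactly 0 so that float noise cannot flip the
typology.

## Cohort statistics

Network variables are skewed and collinear, so the default association
measure is the Spearman rank correlation (average ranks for ties, two-sided
p, listwise deletion per pair — not per table, because density and
intensity exist only for protocol subsets). "FDR" is Benjamini–Hochberg,
applied as one family over all cells of an emitted correlation table; the
method name is recorded in the run metadata. Network size is
√(x + 0.5)-transformed before the OLS of size on age, childcare, and their
interaction (small-count response). The childcare group comparison is a
Wilcoxon rank-sum test: W is the Mann–Whitney U of the first group; for
combined n ≤ 20 the two-sided p is an exhaustive enumeration over rank
assignments (handles ties exactly), larger samples use the tie-corrected
normal approximation with continuity correction.

## Synthetic cohort

The generator emulates the study conditions the package is designed for:
280 children, ages uniform on 6–60 months. Per child, network size is a
negative-binomial count (gamma–Poisson mixture, dispersion 22) with mean
3.9 + 0.20·age + 2·childcare, clipped to [3, 40] — overdispersion chosen
because an SD of ~5 at mean 11 exceeds Poisson noise. Kin count is
1 + Poisson(3.9) capped at N (targeting a kin share near 0.5 that falls
with N); kin populate a single "family" context with realistic role/age
structure. Non-kin fill 1 + Poisson(0.05 + 0.008·age + 0.07·N) disjoint
activity contexts (≤ 6), which is what yields more components and lower
density in larger networks; a childcare child always has a daycare context
containing a class group node and a teacher. Urban children (65%) draw
non-kin demographics from their own Dirichlet neighborhood profile, which
induces the network↔neighborhood diversity correlation in the urban
stratum only; suburban/rural children draw from a fixed homogeneous mix
independent of their profile. Intensity measures exist for lab-protocol
children only (children ≥ 36 months are museum protocol with probability
0.85) and are stochastically higher for kin, which links kin share to
high-intensity share.

All draws flow from two substreams (ego table, alter table) spawned from
one seed, so output is a pure function of (config, seed) and equal seeds
give byte-identical tables.

What the generator does **not** emulate: household/sibling correlation
across egos, seasonal or weekday structure, non-uniform age sampling,
socioeconomic gradients, and any fit to a real dataset. Passing tests on
synthetic cohorts therefore demonstrate correctness and calibrated
structure of the *pipeline*, not empirical claims about real children.

## Problem sizes in the test suite

Randomized oracle checks use 1000 rosters of ≤ 12 alters; structural
emulation checks run the default 280-child cohort over 20 seeds; null-rate
checks use 200–250 replicates of 40–50 observation cohorts. These sizes
give stable Monte-Carlo margins (assertions leave ≥ 2 SE of slack) while
keeping the whole suite around ten seconds.

## Known limitations

- Tie inference cannot see acquaintance outside shared contexts, so density
  is a lower bound relative to a full pairwise survey.
- The closeness instrument's scale is not fixed; any numeric ordinal is
  accepted, and affine rescaling provably does not change the median-split
  labels.
- The kin taxonomy ships with common English labels; site-specific rosters
  should extend it via `--taxonomy` rather than rely on the lenient
  unknown-label fallback.
- Whether the home context should connect to other home-based contexts
  (e.g. a babysitter at home) is a coding decision; contexts are taken
  exactly as labeled.
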