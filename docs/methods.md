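# Methods

## The inference problem

Four microbial habitats ("compartments") are sampled on each farm of a dairy
network: grassland soil, grass phyllosphere, cow-teat surface, and bulk-tank
raw milk. The question is whether the genus-level community composition of
milk can be traced back along the chain soil → phyllosphere → cow-teat →
milk, and which environmental conditions and farming practices modulate the
strength of each step. Each farm is one replicate; compartments are network
nodes; a link's weight within a farm is the similarity of the two
compartments' genus profiles.

## Normalization

Counts are rarefied per sample to a common depth (default 10,000 reads) by
multivariate-hypergeometric subsampling — random selection of reads without
replacement, which is unbiased for relative abundances. Samples at or below
depth are kept whole rather than dropped: losing a farm's compartment would
cost an entire replicate, a worse bias than a slightly unequal depth.
Relative abundances are computed per domain (16S and 18S are separate
sequencing runs with no common scale), and the merged table keeps each
domain's within-sample sum at 1. A merged row therefore sums to 2; because
this is constant across samples, renormalizing to an overall sum of 1 (the
`renormalize_merged` switch) is a uniform rescale with no effect on
correlations — both behaviors are provided since the original choice is not
documented anywhere we know of.

## Per-farm links and the consensus network

The link strength is the Pearson correlation across genera of the two
compartments' relative-abundance vectors, after removing genera absent from
both (a genus absent everywhere carries no information about transfer and
would inflate the correlation through the shared zero). Fewer than 3
remaining genera, or a constant vector, makes the correlation undefined; such
edges are recorded as missing, not zero. Significance uses the *t*
distribution with *n*−2 degrees of freedom and Benjamini–Hochberg control
over the complete farm × pair family, with the retained-edge rule *q* < 0.001
(the source analysis states both an FDR correction and a 0.001 threshold
without fixing the scale; the adjusted-scale reading is the default and a
raw-p mode is available).

Farm networks are combined into a consensus network: nodes absent from any
farm are dropped, and each conserved pair receives the
magnitude-weighted average CN = Σ_f α_f ω_f with α_f = |ω_f|/Σ_g|ω_g|
(undefined farm edges are excluded from the denominator; CN = 0 when every
farm weight is 0). This weighting is a convex combination, so |CN| never
exceeds the largest per-farm |ω| and unanimous weights pass through
unchanged. The consensus p-value is a farm-level bootstrap: farms are
resampled with replacement B times (default 2000) and the two-sided p-value
is 2·min(P(CN\* ≤ 0), P(CN\* ≥ 0)), floored at 1/(B+1). A farm-level
bootstrap was chosen because farms are the replication unit; the reference
consensus implementation's p-value computation is not documented.

Per-farm weights entering the consensus are the raw significant correlations
(non-significant edges contribute 0), since link strengths are reported on
the correlation scale. The signed weighted topological overlap transform

ω_ij = (a_ij + Σ_{u≠i,j} a_iu a_uj) / (min(k_i, k_j) + 1 − |a_ij|),
k_i = Σ_{u≠i} |a_iu|

is implemented and can be switched on (`use_wto`) to feed
shared-neighbour-reinforced weights into the consensus instead; both routes
are reported because the original description is ambiguous on this point.

No compositionality correction (e.g. CLR) is applied by default, matching
the source procedure; a log10(x + 10⁻⁶) transform of the retained
proportions is available as an option.

## Driver models

Per significant consensus link, the per-farm raw correlations are the
response. The covariate set is reduced in three stages:

1. **Redundancy filter** — greedy elimination until all quantitative pairs
   satisfy |r| < 0.6 (the variable with the largest mean absolute
   correlation among violating pairs is dropped first; categorical variables
   are always kept). The absolute-value reading of the threshold is used.
2. **Shadow-feature selection** — every column gets three independently
   permuted "shadow" copies; a 500-tree random-forest regressor is fitted
   and a variable scores a hit when its importance exceeds the maximum
   shadow importance. Over n_iter (default 100) iterations, a two-sided
   binomial test (p = 0.5) at the Bonferroni-adjusted level α/p (α = 0.05)
   confirms or rejects each variable. This is a from-scratch implementation
   of the z-score shadow-attribute algorithm; the multiplicity adjustment
   mirrors the reference implementation's default, and the enlarged shadow
   ensemble raises the maximum-shadow bar. Both matter at this design size:
   with ~12 covariates and 44 farms the luckiest covariate has a chance
   correlation of |r| ≈ 0.35 with any noise response, and a single-copy,
   unadjusted screen confirms it in roughly half of null datasets — after
   which the post-selection F-test is anti-conservative. With the enlarged
   ensemble and adjustment, pure-noise responses confirm nothing in the
   vast majority of replicates while a genuine planted driver is still
   confirmed essentially always. By default only confirmed variables enter
   the regression stage; undecided (tentative) variables can be included
   with `tentative_policy="keep"` at the cost of null-calibration.
3. **Stepwise AIC** — bidirectional OLS term selection minimizing
   AIC = n·ln(RSS/n) + 2(k+1) over candidates built from the retained
   variables: linear terms, squared terms, and all four products of the
   linear/squared columns of each variable pair (squared × squared
   included). No marginality constraint is imposed — a squared term may stay
   without its linear parent. Ties break toward the smaller model.

Post-fit: standardized coefficients β_std = β·sd(x)/sd(y) (whole columns,
including squared and product columns); variance decomposition by sequential
(Type-I) sums of squares in stepwise entry order, with an
averaged-over-orderings option (all orderings up to 7 terms, a seeded sample
beyond) since the original variance-percentage method is unspecified; and
quadratic optima. The optimum of a variable retained with both x and x²
is computed by partial derivation on the raw covariate scale,
x\* = −b₁ᵉᶠᶠ/(2·b₂ᵉᶠᶠ), where the effective coefficients add each retained
interaction term's contribution with its partner factor fixed at the sample
mean — the optimum of an otherwise-average farm. An optimum is reported only
for concave fits (b₂ᵉᶠᶠ < 0) and flagged interior when it falls inside the
observed covariate range. Dummy coding uses the first level alphabetically
as reference.

## Covariate derivation

Grazing pressure per season is LU·t/A (livestock-unit days per hectare; one
LU = one dairy cow); the annual value is the seasonal sum. Manure nitrogen
uses fixed contents — liquid 5 kg N m⁻³, diluted liquid 3 kg N m⁻³, solid
5 kg N t⁻¹ — divided by plot area and averaged over a 3-year window (years
missing from a record count as zero applications and are logged).
Total_manure = Liquid + Solid; Total_N_fertilization = Total_manure + N_ind;
Manure_prop = Total_manure / Total_N_fertilization with the convention 0
when total fertilization is 0. Vegetation records use Braun-Blanquet codes
converted to midpoint covers (r = 0.1, + = 0.5, 1 = 3, 2 = 15, 3 = 37.5,
4 = 62.5, 5 = 87.5 %; configurable, as the conversion table lives in the
phytosociological literature rather than any single source), renormalized
to 100 %; evenness is Pielou's J = (−Σ pᵢ ln pᵢ)/ln S, undefined (signalled,
not zeroed) for a single species. Published evenness values in this system
(0.13–0.37) are low for the reported richness — possibly a non-standard
base or absolute-cover variant; the standard J is implemented and the
discrepancy is documented here, not resolved.

## Co-occurrence summaries

Presence is strict positivity after rarefaction — no minimum-abundance
floor, since no detection threshold is documented. Farm-level compartment
genus sets are unions over the compartment's samples; network level unions
over farms. The four-set Venn partition is counted exactly over the 15
exclusive regions; shared fractions are percentages of the union, reported
to one decimal. Richness summaries report min/max/mean, the standard error
sd/√n (the "SE" label is taken at face value), the coefficient of variation
as a ratio, and the cumulated (union) genus count. A per-genus table of the
fraction of farms supporting each region is also emitted.

## Synthetic data

The generator emulates the study design: 44 farms × 4 compartments ×
2 marker domains, one sample each, ~10,000 reads, genus pool sizes 1917
(prokaryote) and 1080 (fungal) matching the observed totals. Each
compartment's pool shares a 40 % core with the others (echoing the observed
37.6–47.4 % four-compartment sharing) plus a compartment-specific tail;
within-pool concentrations are lognormal and **independent across
compartments**, so that with zero mixing the expected cross-compartment
correlation is 0. The lognormal σ increases along the chain (0.7, 1.2, 1.4,
1.5): soil communities are the most even and milk the most dominated, as in
real data, and this gradient sets how fast transfer signal decays.

Latent compositions are chained per farm: phyllosphere = λ₁·soil +
(1−λ₁)·e_p; teat = λ₂·phyllosphere + (1−λ₂)·e_t; milk = λ₃·teat +
λ₄·e'_p + (1−λ₃−λ₄)·e_m, with e fresh Dirichlet draws (total concentration
100) and counts multinomial at the nominal depth. The direct
phyllosphere→milk term deliberately carries a **fresh pool draw** e'_p —
habitat-characteristic flora reaching the tank through air, hay or handling
— rather than the farm's realized phyllosphere: a realized-composition term
would bolt soil signal directly onto milk and make the absent soil→milk
edge correlate at r(s,p)·r(p,m) ≳ 0.1, destroying the property that the
skip edge is a true null whenever the chain links are strong enough to
detect. With this structure the soil imprint reaches milk only through the
full three-step chain.

Default mixing: λ₁ peaks at 0.4 under a logistic-quadratic response to soil
pH with the planted optimum at pH 7.0 (inside the generated range 5.5–7.9)
and per-farm logit noise sd 0.2; λ₂ = 0.3, λ₃ = 0.28, λ₄ = 0.2 constant.
These values were chosen so that the default scenario reproduces the
qualitative consensus structure the method is meant to detect — four
significant chain links with weights in the few-tenths range, and skip
edges (soil–cow-teat, soil–milk) below the retention thresholds — which it
does across the large majority of generator seeds.

Covariates are drawn with independent uniform marginals over the observed
farm-network ranges, with structural identities enforced by rejection
(texture and vegetation covers close to 100 %; seasonal grazing pressures
sum into the annual range; manure/fertilization totals consistent;
Manure_prop zero rule). At the design size of 44 farms the categorical
frequencies reproduce the observed counts exactly (milking preparation
1/26/17 none/dry/humid; teat care 35/9 yes/no). Covariates are independent
of one another — the generator does not attempt to replicate the real
covariance structure of practices, so tests passing here say nothing about
collinearity-driven failure modes on real records beyond what the
redundancy filter handles.

## What the tests do and do not show

Synthetic recovery tests show that the pipeline detects a planted chain at
the study's design size and recovers an interior covariate optimum within
±10 % of the covariate range, and that a structurally null edge stays below
|CN| = 0.1. They do not show field validity: real communities are not
Dirichlet-multinomial, real transfer is not a single linear mixing
proportion, and real covariates are collinear. Reduced problem sizes are
used where a property needs many replicates — the mixing-monotonicity grid
runs at 20 farms with 300+150 genera, and the null-driver replicate loop
uses 60-tree forests with 25 shadow iterations — sizes chosen to keep the
full suite comfortably under typical CI budgets while leaving the
conclusions unchanged at larger sizes (spot-checked during development).

## Numerical choices

- Rarefaction: `numpy` multivariate hypergeometric, per-sample, seeded.
- Undefined correlations are missing, never 0; they are excluded from both
  the FDR family and the consensus weighting denominator.
- Stepwise ties (< 10⁻⁸ in AIC) resolve toward the smaller model, making the
  selection invariant to column order except at exact ties.
- The bootstrap p-value is floored at 1/(B+1): B resamples cannot certify a
  smaller tail.
- A single pipeline seed is fanned out counter-based
  (`SeedSequence(entropy=seed, spawn_key=(stage,))`) so any stage can be
  re-run in isolation with the same stream; all derived seeds are < 2³¹.
- TSV floats are written at 12 significant digits so a round trip is
  value-exact at that precision.

## Known limitations

- The consensus bootstrap treats farms as exchangeable; spatial or
  elevation-driven dependence between farms would make the p-values
  anti-conservative.
- Stepwise AIC over a quadratic-plus-interactions dictionary at n = 44 can
  overfit (adjusted R² well below R²); the reported model p-value is not
  corrected for selection.
- Correlations on relative abundances are compositionally biased; the
  optional log transform mitigates but does not remove this, and no CLR
  option is provided because the reference procedure used none.
- The genus-exclusion rule conditions on presence in at least one of the two
  compartments, which ties the effective n of each farm-pair test to
  community richness.
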