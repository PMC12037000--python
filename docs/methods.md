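# Methods

## The Biobank Impact Factor

`bifactor` scores the influence of biobanks — collections of human
biological material linked to health information — from the documents
that *mention* them rather than only the papers that cite them, because a
large fraction of biobank use never results in a citation to the
resource's flagship papers.

**Research impact.** For each biobank, mentions are counted as distinct
documents per type i ∈ {publications, grants, patents, clinical trials,
policy documents}. Within the scored cohort the counts are standardized
per type and range-limited:

    z_i = clip((r_i − μ_i) / σ_i, −1, 1),      R = Σ_{i=1..5} z_i ∈ [−5, 5]

μ_i and σ_i are the cohort mean and sample (ddof = 1) standard deviation
of type-i counts. The clip is how we read "normalized at [−1, 1]": a
min–max rescaling was rejected because saturation at ±1 per type is what
anchors R = 5 as "exceptional visibility in every channel". A type with
zero cohort variance contributes 0. Consequences worth knowing: R is
invariant to adding a constant to every biobank's count in one type, and
is non-decreasing in a biobank's own count.

**Disease impact.** Three raw components per biobank — scope (number of
distinct MeSH conditions on its mentioning publications), depth (mean,
over those conditions, of the biobank's share of all corpus publications
on the condition), and rare-disease share (the biobank's fraction of all
corpus publications tagged with a rare condition) — are each put through
the same standardize-then-clip map over the cohort, giving D = Dscope +
Ddepth + Drare ∈ [−3, 3]. The raw definitions are deliberate strategy
points (`disease_impact_raw` is separable) since only the component
*names* and the [−1, 1] contribution of each are fixed by the design;
standardization mirrors R for internal consistency. An empty
rare-condition list zeroes Drare for every biobank with a warning rather
than erroring.

**Composite.** With age Y = reference_year − establishment_year, floored
at 1 to keep new biobanks finite:

    bIF = (0.9·R + 0.1·D) / Y,   so Y·bIF ∈ [−4.8, 4.8],

and 4.8 = 0.9·5 + 0.1·3 is the score of a one-year-old biobank saturating
every component. The weights are arguments of `compute_bif`; at (1, 0)
the ranking reduces to ranking by R/Y, which the tests exercise as a
sensitivity property. The scored cohort defaults to biobanks with at
least 20 mentioning publications, and the same cohort supplies μ_i, σ_i —
whether the standardization population should instead include sub-cutoff
biobanks is genuinely open; we chose the self-consistent option (scored
set = standardization set).

## Hidden citations, reach, locality, coauthorship

A *hidden citation* is a mentioning publication whose outgoing citations
include none of the biobank's reference papers. Biobanks without
reference papers raise a distinct exclusion signal (`NoReferencePapers`)
rather than reporting 0 — an unassessable biobank is not an uncited one.
Grants, patents, trials and policy documents are excluded from the
denominator. *Scientific reach* is the size of the deduplicated set of
documents citing at least one mentioning publication.

Locality attributes a publication to the host country (institution) if
*any* author affiliation matches; a fractional-counting variant was
considered and rejected for v1 — the any-author rule is the simplest
defensible reading and the one the synthetic generator plants exactly.
Significance comes from a permutation null: biobank labels are permuted
over mention slots, a degree-preserving rewiring of the bipartite
mention graph that holds each biobank's mention count and each
document's mention slots fixed (asserted every iteration). The empirical
p-value uses the +1 correction, p = (1 + #{null ≥ observed}) / (1 + n_iter),
so p ∈ [1/(n_iter+1), 1] and the test is exact under exchangeability.

Coauthorship-for-access statistics scan author lists against the team
and PI rosters; `pi_share ≤ team_share` holds by construction since PIs
are team members. Quintile contrasts (top vs bottom 20% by bIF) use
Welch's t-test with t-based 95% CIs; the degenerate all-equal case is
reported as p = 1 rather than NaN.

## Cocitation network

Each citing article contributes +1 to every pair of distinct biobanks
whose mentioning publications it cites; "frequently cited together" is
operationalized as a weight threshold (default `min_weight=2`,
configurable — no canonical threshold exists). Communities are found by
Leiden modularity optimization (igraph/leidenalg) under a fixed seed;
the algorithm is a contract (deterministic under seed, modularity
reported), not a mandate. Partition–category alignment uses NMI
normalized by the geometric mean of entropies, computed directly from
the contingency table; the arithmetic-mean variant is available. The
doubly degenerate case (one community *and* one category) is defined as
1.0 — the partitions are identical — while a single trivial side scores
0. sklearn's geometric NMI serves as an independent cross-check in the
tests.

## Funding alignment

Publications per RCDC funding category are regressed on raw (unlogged)
mean annual funding in USD by OLS with intercept; Pearson r summarizes
alignment, and per-category representation is the residual as a percent
of the expected count, 100·(actual − expected)/expected, rounded to
integer percent for display only. Whether log axes would be more
appropriate is left configurable by passing transformed series; raw
scale is the default reading of the reported correlation.

## Feature regression

The 14-feature model is log(bIF + 1) = β₀ + Σ βⱼXⱼ + ε with Gaussian ε,
fitted by a Gaussian GLM (statsmodels) — a literal reading of the
log-transformed response with additive normal error; a gamma GLM was
rejected for v1. Features enter as binary class indicators (top-decile
flags for cohort size and PI prestige, a high open-data-index flag).
P-values are Bonferroni-corrected with m = 14; the correction is
monotone by construction. Rows with bIF ≤ −1 are dropped with a warning;
perfect collinearity raises an error naming the offending columns.
Reported diagnostics: R², deviance and Pearson χ² (total and per
residual degree of freedom).

## Synthetic corpus generator

The generator plants every parameter the estimators later recover:

| parameter | default | emulates |
|---|---|---|
| `hidden_citation_rate` | 0.412 | observed mean hidden-citation rate |
| `home_bias` | 0.735 | observed mean national share |
| `institution_bias` | 0.40 | institutional share conditional on national (0.294/0.735) |
| `doc_type_mix` | (0.842, 0.060, 0.057, 0.007, 0.035) | corpus-wide mention totals across the five types |
| `mean_mentions_per_biobank` | 102 | total mentions / number of biobanks |
| coauthor mixture | Beta(2,18) w.p. 0.3, Beta(8,2) w.p. 0.7 | bimodal team-coauthorship with mean ≈ 0.59 |
| reference papers | 1–3 per biobank | ≈ 2 flagship papers per biobank |
| `n_disease_categories` | 20 | the 20-category MeSH disease scheme |

Per-biobank mention counts are Poisson draws around log-normal
intensities, exp(loc_i + scale_i·z_b), with a single standard-normal
visibility factor z_b shared across the five types: this yields the
heavy tail (log-normal was chosen over a power law — two parameters,
finite moments) and the cross-type correlation that makes composite
ranking meaningful. When `mention_loc` is not given, locations are
derived from `mean_mentions_per_biobank × doc_type_mix` so the log-normal
mean matches the target; the per-type `mention_scale` defaults to 1.2.
RCDC tags are allocated so category counts equal slope·funding + N(0,
noise_sd); the default slope makes the mean tag rate 0.6 per publication
and is recorded in the truth record. Reference papers are generated as
ordinary team publications flagged in `biobanks.csv` but not
mention-linked, which keeps the planted hidden rate exactly the Bernoulli
rate over mentioning publications. Background "external" articles cite
mentioning publications (co-citing two biobanks with probability
`cocite_prob`) so reach and the cocitation network are nondegenerate.
`home_bias=None` draws affiliation countries uniformly, giving an
exchangeable null with no planted locality — the right control for the
rewiring test, since `home_bias=0` is degenerate (the observed share is
identically zero).

What the generator does *not* emulate: author disambiguation noise,
multi-biobank mentions in one paper, citation aging, real geographic
funding structure, or any calibration to the real dataset's exact distributions.
Passing recovery tests therefore demonstrates estimator correctness
under the planted model, not that real corpora satisfy that model.

## Problem sizes and numerical choices

Recovery studies run at desk scale: hidden-rate recovery on corpora of
~6,000 mentioning publications (binomial SE ≈ 0.006, tolerance ±0.02),
home bias on ~1,000 publications (±0.04), the rewiring null with 199–999
iterations, regression calibration with 100–200 replicates of n = 500
fits. Sample SDs use ddof = 1 throughout; ties in bIF rankings break
lexicographically by name; all simulations are reproducible from a
single integer seed routed through `numpy.random.default_rng`.

## Known limitations

- The raw disease-component definitions and the rare-disease list are
  inputs/strategy points, not canon; alternative definitions plug into
  `disease_impact_raw`.
- Corpus-level headline statistics (mean hidden rate 41.2%, national
  share 73.5%, etc.) can only be reproduced from the real frozen deposit
  via an export to the documented corpus dialect; the package does not
  guess the deposit's schema.
- In-memory lists of dataclasses are comfortable to ~10⁶ documents;
  larger corpora would warrant a columnar refactor.
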