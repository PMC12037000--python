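# bifactor

Tools for quantifying the scientific and disease impact of **biobanks** —
repositories of human biological samples linked to health data — from the
research documents that *mention* them, not only the papers that cite
them. Citation counts systematically understate biobank impact: many
papers that use a biobank never cite its flagship ("reference") papers.
`bifactor` is aimed at bibliometricians, biobank operators and funders
who want a reproducible, multi-dimensional impact accounting.

## What it computes

**Biobank Impact Factor (bIF).** Mentions of a biobank are counted as
distinct documents across five types — publications, grants, patents,
clinical trials, policy documents. Per type, counts are standardized
within the scored cohort and range-limited,

```
z_i = clip((r_i − μ_i)/σ_i, −1, 1),      R = Σ_{i=1..5} z_i ∈ [−5, 5]
```

Disease impact adds three standardized, clipped components — scope
(breadth of conditions studied), depth (share of each condition's
literature), and rare-disease share — giving `D ∈ [−3, 3]`. The final
age-normalized score is

```
bIF = (0.9·R + 0.1·D) / Y,        Y·bIF ∈ [−4.8, 4.8]
```

where `Y` is the biobank's age in years; 4.8 = 0.9·5 + 0.1·3 is the
score of a one-year-old biobank saturating every component.

Around the score, the package provides:

- **hidden citations** — mentioning publications citing none of the
  biobank's reference papers — and **scientific reach** (unique articles
  citing the mentioning publications);
- **locality analysis** (host-country / host-institution shares) with a
  degree-preserving **rewiring null model** and exact permutation
  p-values;
- **coauthorship-for-access** statistics (team / PI coauthor shares);
- the biobank **cocitation network**, Leiden communities, and NMI
  against disease-category labels;
- **funding-representation residuals**: OLS of publications per RCDC
  category on NIH-style funding, with surplus/deficit percentages;
- a 14-feature **impact regression**, `log(bIF+1) ~ X1..X14`, with
  Bonferroni-corrected p-values;
- a **synthetic corpus generator** with planted, recoverable ground
  truth (hidden rate, home bias, coauthorship mixture, funding slope)
  for validating every estimator.

See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a synthetic corpus (100 biobanks, realistic defaults), score
it, and measure hidden citations:

```
bifactor simulate --out corpus --seed 7
bifactor bif --corpus corpus --out scores.csv --min-pubs 20
bifactor hidden --corpus corpus --out hidden.csv
```

The scores table ranks the 69 biobanks passing the 20-publication
cutoff; the top rows from the run above:

```
biobank_id  name                    R         D        Y   bIF
bb0054      Synthetic Biobank 0054  5.000000  2.000000  13  0.361538
bb0096      Synthetic Biobank 0096  3.737539  1.975585  14  0.254382
bb0028      Synthetic Biobank 0028  4.751098  2.000000  20  0.223799
```

`bb0054` saturates all five mention channels (R = 5, each clipped
z-score at +1) and two of the three disease components, and divided by
its 13-year age scores bIF = 4.7/13 ≈ 0.36 — strongly above-average
impact for its age. The hidden-citation table averages a 0.406 hidden
rate across 99 assessable biobanks, recovering the generator's planted
rate of 0.412: roughly two of every five mentioning papers never cite
the biobank's reference papers.

Every subcommand (`simulate`, `bif`, `funding`, `network`, `hidden`,
`locality`, `coauthorship`, `glm`, `report`) writes its outputs plus a
JSON run manifest (seed, config hash, input checksums) and is
deterministic given a seed. The same functionality is importable from
`bifactor.impact`, `bifactor.citations`, `bifactor.network`,
`bifactor.disease`, `bifactor.features` and `bifactor.synthetic`.

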