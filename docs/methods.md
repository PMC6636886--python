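# Methods

## The corpus model

A coded corpus is three linked tables sharing an article key: a **source**
table (article metadata), a **bct** table (every technique coded per
article, linked or not), and a **link** table (one row per article-level
BCT–MoA link statement). Each link row carries the author's raw mechanism
label and definition, the resolved mechanism category (one of 26 constructs,
OTHER when the label maps onto none of them, UNRESOLVED before resolution),
and three coding flags stored as their literal numeric codes: explicitness
(1 = some inference needed, 2 = none), grouping (1 = one-to-one, 2 = part of
a group statement), and empirical status (1 = mechanism not measured,
2 = measured but the link untested, 3 = link tested). Group statements are
assumed to have been expanded into pairwise rows at coding time; the flag is
preserved for reporting only.

Label resolution is deterministic: canonical construct labels match after
normalization (lowercase, trimmed, whitespace collapsed, quotes stripped),
then a small curated synonym seed (typographic variants plus the
self-efficacy ≡ Beliefs about Capabilities equivalence); everything else
resolves to OTHER. The seed is deliberately minimal — full coder judgment
cannot be automated, and guessing would contaminate the category marginals.

## The enrichment test

The unit of counting is the article: a link contributes at most once per
article, enforced by deduplication over (article, BCT, MoA category); when
duplicates disagree on flags the more informative survives (higher
explicitness, then higher empirical status). Cell counts k(B, M), marginals
m_B and m_M, and the total N are computed at one of two scopes:
**categorized-only** (default; links whose mechanism is OTHER/UNRESOLVED
are excluded from cells, marginals, and N — the scope the test is meant to
run on, since uncategorizable labels cannot form cells) or **all-links**
(for descriptive totals and sensitivity analysis).

Each described cell is tested against p₀ = (m_B/N)(m_M/N) with the exact
binomial upper tail P(X ≥ k), X ~ Binomial(N, p₀), computed through the
binomial survival function (`scipy.stats.binom.sf(k-1, N, p0)`) — no normal
approximation, no cancellation-prone 1 − CDF subtraction; an independent
direct-summation oracle over exact binomial coefficients backs it in the
test suite (agreement to 1e-12, exhaustive for all k at N ≤ 60). Cells
never described (k = 0) are not tested. Significance is raw p < α with
α = .05 by default — deliberately a minimal descriptive criterion, with no
multiple-testing correction; a Benjamini–Hochberg option exists behind
`TestConfig(adjust="bh")` as a clearly labelled extension.

Two caveats are inherent to the statistic. First, the marginals are
estimated from the same data being tested, so a genuinely enriched cell
inflates its own row and column totals and the realized null expectation;
the measured enrichment is attenuated relative to the generating mechanism.
Second, the per-cell binomial nulls are not independent (they share
marginals), so the family of p-values is approximately, not exactly,
uniform under independence — the calibration battery below quantifies this.

Summary statistics of a significant link set (links, per-axis counts, means
and maxima, coverage of the 93-technique and 26-construct spaces) round
half-up: means to two decimals, coverage to whole percent.

One published quantity is deliberately not recomputed: the per-link
p-values of the original tables. The N used there (total links minus an
unreported number of uncategorizable ones) and the scope of its marginals
are not stated, so those p-values are transcribed as printed (censored
entries like "<.001" kept verbatim and parsed at their bound) rather than
re-derived. Both scopes are implemented so users with the full deposited
dataset can run either.

## The synthetic generator

`generate_corpus` emulates a literature-coding corpus, not article text:
each of `n_articles` articles draws a link count from a negative binomial
matched by moments to mean 9.56 / SD 13.80 (the overdispersion a real
coding corpus shows; SD > mean rules out Poisson), floored at one link
because inclusion requires one — the floor lifts the realized mean by about
P(X=0) ≈ 0.2. Links are drawn without replacement within the article from
cell probabilities ∝ w_B · w_M · propensity(B, M). Default marginal weights
are illustrative, not estimates: rank^-0.5 over the 93 techniques (top
share ≈ 6%) and rank^-1 over the 26 mechanisms (top share ≈ 26%, mirroring
the observed concentration of links on one dominant mechanism). Flags
default to the reported proportions (33% inference-needed, 12% one-to-one,
0.9% tested; the measured-but-untested share is not reported and defaults
to 5%). A 5% OTHER rate emulates uncategorizable labels. One
`numpy.random.default_rng(seed)` generator drives everything; identical
configs yield identical corpora.

What the generator does **not** emulate: coder disagreement, correlated
technique co-occurrence within articles, behavior-specific link structure,
and secular trends. Passing calibration/power batteries therefore
demonstrates the test's operating characteristics under clean marginal
structure, not performance on real coding noise.

### Battery conditions

Calibration and power are measured on a restricted 20 × 10 uniform link
space with 250 articles averaging 16 links (≈ 4,000 links per corpus), so
every cell's expected count is ≥ 5 — the regime where the binomial null is
informative. Under independence the mean false-flag rate at α = .05 over
200 seeded replicates is ≈ 0.02. For power, two cells are planted at twice
the marginal product; their realized null-expected counts are ≈ 22
(satisfying the ≥ 10 precondition despite the marginal-inflation
attenuation described above), and mean sensitivity over 200 replicates is
≈ 0.92. In smaller spaces, where a planted cell is a large share of its own
marginals or the within-article without-replacement draw flattens cell
probabilities, the same 2× multiplier yields substantially less measurable
enrichment; the battery sizes were chosen so the stated preconditions
actually hold.

## Heat map

The p-value matrix has one cell per tested link; untested cells carry NaN.
Rows and columns are clustered independently by average-linkage
agglomeration on Euclidean distances over −log10(p) (p clamped below at
1e-16, capping the scale at 16; untested cells imputed at p = 1, i.e. zero
evidence). The published figure does not state its algorithm, metric, or
linkage, so the published ordering is not a reproduction target; this
choice emphasizes strong links while the clamp bounds their influence, and
both metric and linkage are arguments. SciPy's agglomeration is
deterministic for a fixed input order with ties merging lowest-index
first; determinism is guaranteed for the CSV/JSON data artifacts, not for
raster bytes (fonts vary by platform). Untested cells render in an
off-white outside the p colormap so "never described" is distinguishable
from "described but weak".

## Package shape

The analysis is exposed statsmodels-style: `LinkEnrichmentModel`
(constructed `from_corpus`, or directly from statements or a frequency
table) with `fit()` returning `LinkEnrichmentResults` carrying the per-link
estimates, `summary()`, the two table views, and plotting. The underlying
functional modules (`registry`, `corpus_io`, `link_stats`, `link_test`,
`heatmap`, `synthetic`) remain public and are what the model objects
compose; the `bctmoa` CLI wraps them thinly.

## Known limitations

* Registries are shipped CSVs and user-replaceable, but a replacement BCT
  registry is only validated for format, uniqueness, and code pattern — not
  for being the canonical taxonomy.
* The synonym seed covers only unambiguous equivalences; corpora with rich
  free-text labels will show high OTHER rates unless the user extends the
  map, which shrinks the tested N.
* The test conditions on the observed marginals rather than modelling them;
  no small-sample correction is applied for the marginal-estimation
  attenuation noted above.
* `corpus_summary` divides mean links per article by articles contributing
  ≥ 1 link; other denominators (e.g. screened articles) would give slightly
  different means.
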