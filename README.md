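# bctmoa

Evidence synthesis of the links that behavioral-intervention authors describe
between **behavior change techniques** (BCTs, the 93 techniques of BCT
Taxonomy version 1) and the **mechanisms of action** (MoAs) through which
those techniques are hypothesized to change behavior (26 constructs: the 14
Theoretical Domains Framework domains plus 12 constructs frequent across
behavior-change theories).

The package is for behavioral scientists and systematic reviewers who have a
coded corpus — per article, which BCTs were used and which BCT–MoA links the
authors stated — and want to know which links are described *more often than
marginal usage alone would predict*.

## The statistic

Let k(B, M) be the number of distinct articles describing a link between
technique B and mechanism M (a link counts at most once per article), m_B and
m_M the row and column totals, and N the corpus-wide link total. Under
independent use of techniques and mechanisms the null probability of the cell
is the marginal product

&nbsp;&nbsp;&nbsp;&nbsp;p₀ = (m_B / N) · (m_M / N),

and each described cell is referred to a one-tailed exact binomial upper tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ k),&nbsp;&nbsp;X ~ Binomial(N, p₀),

with links reported at p < .05. The p-values rank links by frequency
*relative* to overall technique and mechanism usage; they are descriptive,
not causal. Results feed two published-style table views (grouped by BCT and
by MoA) and a hierarchically clustered p-value heat map.

## Worked example

```python
import bctmoa as bm

# synthetic corpus of 120 articles; one link planted at 3x independence
cfg = bm.SyntheticConfig(n_articles=120, seed=11, propensity={("1.1", 4): 3.0})
corpus, truth = bm.generate_corpus(cfg)

res = bm.LinkEnrichmentModel.from_corpus(corpus, alpha=0.05).fit()
cell = {(r.bct_code, r.moa_id): r for r in res.results}[("1.1", 4)]
print(cell.k, round(cell.expected_count, 2), round(cell.p, 5))
print(bm.recovery_metrics(res.results, truth, alpha=0.05))
```

prints

```
15 5.08 0.00025
{'sensitivity': 1.0, 'false_flag_rate': 0.0658578856152513}
```

The planted link — Goal setting (behavior) → Beliefs about Capabilities —
was described in 15 articles against a null expectation of 5.08, giving
p ≈ .0003: the generator's ground truth is recovered, while about 6.6% of
the many small-count null cells are flagged at the raw .05 criterion.
`res.summary()` prints the run header (scope, N, significant-link counts and
coverage) and the strongest links; `res.plot_heatmap("out/heatmap")` writes
the clustered heat map (PNG/SVG) plus its deterministic CSV/JSON data
artifacts.

The same pipeline is scriptable from a shell:

```sh
bctmoa simulate --n-articles 120 --seed 11 --out sim/
bctmoa test --source sim/source.csv --bct sim/bct.csv --link sim/link.csv --out run/
bctmoa reproduce-tables --out tables/
```

`reproduce-tables` reloads the packaged transcription of the study's
significant-link tables (87 links at p < .05 across 277 articles) and
reports its summary: 87 links, 51 of 93 BCTs (55%), 24 of 26 MoAs (92%),
mean 1.71 MoAs per BCT (max 5) and 3.63 BCTs per MoA (max 8).

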