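# bymtrends

Bayesian spatiotemporal smoothing and trend classification for block-level
survey indicators.

Health-program surveys often report indicators for hundreds of small
administrative areas ("blocks") across a handful of survey rounds, with as
few as 19 respondents per block-round. Raw proportions at that scale are
too noisy to compare or map. `bymtrends` is for epidemiologists and
program-evaluation analysts who need block-level levels and trends they can
defend: it smooths the raw estimates with a Besag-York-Mollié (BYM) spatial
model, asks whether the time trend genuinely varies between blocks, and
classifies each block's trend with an explicit posterior-probability rule.

## The model

For block *i* and round with time value *t* (years since the first round):

    y_it ~ Binomial(n_it, logit⁻¹(η_it))        (binary indicators)
    y_it ~ Poisson(n_it · exp(η_it))            (count indicators)
    η_it = α + β·t + u_i + v_i [+ δ_i·t]

where `u` is an intrinsic CAR (ICAR) spatial effect on the block contiguity
graph (blocks that share a border are neighbours), `v` is iid unstructured
heterogeneity, `β` is the state-average per-year trend and `δ_i` is an
optional per-block trend deviation (the space-time interaction). Models
with and without `δ` are fitted by a bespoke MCMC sampler and compared by
DIC; the lower DIC wins. Block trends exp(β + δ_i) — odds ratios (binary)
or rate ratios (count) per year — get 95% credible intervals from 10,000
posterior resamples; a CrI entirely above 1.0 means at least a 97.5%
posterior probability of a rise (classified *increase*), entirely below 1.0
a *decrease*, anything else *indeterminate*. Blocks with no respondents are
imputed by the model from their neighbours. See `docs/methods.md` for
priors, the sampler, and validation.

## Worked example

```python
from bymtrends import (ModelSpec, SamplerSettings, fit, make_lattice,
                       select_model, block_trends, summarize_indicator)
from bymtrends.simulate import scenario, generate

graph = make_lattice(6, 6)                       # 36 blocks, rook adjacency
data, truth = generate(graph, scenario("opposite_trends", seed=5, n_range=(100, 100)))

fits = {}
for interaction in (False, True):
    spec = ModelSpec(family="binary", include_interaction=interaction,
                     sampler=SamplerSettings(iterations=3000, burnin=1000,
                                             thin=2, chains=2, seed=20 + interaction))
    fits[interaction] = fit(data, graph, spec)

sel = select_model(fits[False], fits[True])
print(sel.dic_table())
trends = block_trends(sel.chosen, resamples=10_000, seed=30)
print(summarize_indicator(trends, sel, indicator_id="demo"))
```

Output (abridged):

```
         model        dbar        pd         dic
no_interaction 1330.178820 35.365773 1365.544593
   interaction  841.485171 60.811389  902.296560
blocks classified: 12 increase, 11 decrease, 13 indeterminate
per-year OR range across blocks: 0.52 - 2.40
example block B0_0: OR 1.24 [1.06, 1.48] -> increase
```

The interaction model wins by ~463 DIC points because the generated truth
has blocks trending in opposite directions; each block then gets its own
per-year odds ratio, and blocks whose 95% CrI excludes 1.0 are classified.

The `examples/` directory has one short script per capability (contiguity
graphs and the ICAR structure, smoothing one indicator, DIC selection and
trend classification, the full config-driven pipeline), each printing the
numbers it computes. A thin CLI covers batch use:

```
bymtrends simulate --scenario universal_rise --seed 1 --out data/
bymtrends run --config config.yaml --seed 5
bymtrends report --out bymtrends_out/
```

Input formats: an aggregated observation CSV
(`indicator_id,family,block_id,round,y,n`), optionally an individual-level
count CSV (`indicator_id,block_id,round,count,max_count`, aggregated as a
ratio of sums), and adjacency as either a GeoJSON FeatureCollection of
block polygons or an edge-list CSV (`block_a,block_b`).

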