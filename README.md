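# csnq

Scoring and cohort analysis for **child egocentric social networks**.

Developmental psychologists increasingly collect roster data about the
people an infant or young child sees on a regular basis — a parent
interview elicits the network members ("alters"), and a short demographic
form records each alter's age, race, languages, relationship to the child,
and the contexts (family, daycare, swim class, ...) in which they interact.
`csnq` turns such rosters into a per-child metric table and runs the
cohort-level descriptive statistics, so that early social environments can
be quantified and compared across development.

## Metrics

For a child ("ego") with *N* alters:

- **Network size** *N* — unique individuals and groups seen weekly
  (a "daycare/preschool class" may enter as a single multi-person node).
- **Ties & density** — two alters are tied iff they share an interaction
  context; density = 2*T*/(*N*(*N*−1)) for *T* ties, 1 when everyone knows
  everyone.
- **Components** *C* and **component ratio** (*C*−1)/(*N*−1) — connected
  components of the alter–alter graph with the ego removed; each component
  is a union of overlapping contexts (the family, each activity). The ratio
  is a size-normalized fragmentation measure.
- **Composition** — proportion of kin (immediate + extended family),
  proportion of adults (age ≥ 13 years), and proportion of high-intensity
  relationships. Intensity is a cohort-pooled composite: z-scores of
  activity count, parent-rated closeness, and share of waking hours are
  averaged per relationship and median-split into high/low.
- **Diversity** — base-2 Shannon entropy *H*(*X*) = −Σ *p* log₂ *p* of the
  racial / language category mix among alters, and the EI homophily index
  (*D*−*S*)/(*D*+*S*) comparing each alter to the child (−1 fully same,
  +1 fully different). Component-level entropy supports a typology:
  *integrated* (every component mixed), *segregated* (≥ half the components
  homogeneous despite overall mixing), *no-diversity* (entropy 0).
- **Neighborhood entropy** — the same entropy formula applied to zip-level
  category profiles supplied as input (census extracts).

A seeded synthetic-cohort generator (`csnq.simulate`) emits realistic
roster tables — 280 children aged 6–60 months with age-increasing network
size, a family-plus-activities component structure, about half kin, and
urbanicity-dependent demographic mixes — so the full pipeline is testable
without any restricted data.

## Worked example

```bash
csnq simulate --seed 7 --out cohort/
csnq score --egos cohort/egos.csv --alters cohort/alters.csv --out metrics.csv
csnq analyze --metrics metrics.csv --out report/
```

or equivalently in Python:

```python
from csnq import simulate, analysis

egos, alters = simulate.generate_records(seed=7)
metrics = analysis.score_cohort(egos, alters)
print(analysis.summary_table(metrics).round(2))
```

which prints (seed 7):

```
                      mean    sd   min    max    n
variable
network_size         11.81  5.47  3.00  28.00  280
n_low_intensity       4.58  3.69  0.00  16.00  165
n_high_intensity      4.58  1.66  1.00  11.00  165
prop_high_intensity   0.58  0.25  0.08   1.00  165
prop_kin              0.49  0.27  0.06   1.00  280
prop_adult            0.57  0.14  0.20   0.88  280
density               0.34  0.15  0.10   1.00  115
n_components          2.88  1.25  1.00   7.00  280
component_ratio       0.18  0.13  0.00   0.67  280
racial_entropy        1.16  0.68  0.00   2.39  280
racial_ei            -0.41  0.48 -1.00   0.89  280
language_entropy      0.83  0.52  0.00   1.85  280
linguistic_ei        -0.66  0.31 -1.00   0.29  280
```

Each row is one metric over the cohort; `n` varies because density needs
the context question (museum protocol subset) and intensity needs the
lab-protocol measures. `analysis.correlation_table(metrics)` adds the
rank-correlation report against network size and age with
Benjamini–Hochberg FDR-adjusted p-values; on this cohort network size rises
with age (ρ = 0.66), components rise (ρ = 0.58) and density (ρ = −0.27) and
kin share (ρ = −0.74) fall with size — the canonical egocentric-network
pattern the generator is calibrated to.

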