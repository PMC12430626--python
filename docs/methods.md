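# Methods

## Scope and data model

`forcarb` estimates vegetation carbon stocks from stand-level (sub-
compartment) inventory records and values them as carbon sinks. A record
carries: area (hm²), vegetation type (arbor / economic / shrub /
non-stocked), dominant species group, age group (young, middle-aged,
near-mature, mature), standing volume (m³) and the functional zone of the
reserve (core / buffer / experimental). Only live-tree (and, via area-based
means, economic/shrub) vegetation carbon is in scope: soil, litter,
herbaceous and deadwood pools are not modelled, and non-stocked land is
representable but excluded from all carbon computation.

Age strata are the four management age groups above. Parameter tables are
indexed by these four groups plus a pooled `total` stratum; no overmature
stratum is modelled because none appears in the source parameter set.

## Estimators

All four arbor-layer methods are linear in standing volume; their
differences are entirely in the conversion factors.

| method | per-record contribution | parameters |
|---|---|---|
| `variable_bef` | `V·D·BEF(sp, age)·(1+R(sp, age))·CF` | age-stratified rows |
| `bef` | `V·D·BEF_total·(1+R_total)·CF` | pooled rows |
| `volume_conversion` | `V·δ·ρ·γ` | δ=1.90, ρ=0.5, γ=0.5 |
| `continuous_bcf` | `(aV + b)·CF` | species (a, b); CF from the pooled row |

The continuous method's intercept `b` makes the application level a real
modelling choice: applied per species group (`species_aggregate`) the
intercept enters once per species; applied per record it enters once per
record, inflating the estimate by `(n_records − 1)·b·CF` per species. The
API therefore forces an explicit choice; the pipeline default is
`species_aggregate`, which matches how stand-level biomass–volume relations
are fitted (one relation per species-level aggregate, not per inventory
polygon). Under `species_aggregate` the species carbon is allocated back to
records in proportion to volume so that any regrouping (e.g. by zone)
remains consistent; a species group with zero total volume keeps its
intercept-only carbon and is flagged.

Economic forests and shrublands have no volume in the survey; their carbon
is `S·B̄·CF` with mean biomass 23.7 t/hm² (economic), 19.76 t/hm² (shrub)
and carbon fraction 0.47.

Densities (tC/hm²) are computed at aggregation time as carbon/area; a group
with positive carbon on zero area is rejected as inconsistent rather than
silently yielding an infinite density.

### Numerical conventions

All chained arithmetic runs at full float precision; rounding (decimal
half-up, matching how the published money and stock tables are printed) is
applied only at presentation. Price schemes are the one deliberate
exception: a derived scheme price is stored rounded to 2 decimals, because
that is the number actually quoted and used downstream — monetising
unrounded carbon at the 2-decimal price reproduces the published value
tables to the centesimal digit, while an unrounded price chain does not.

## Parameter registry

The per-species expansion parameters (BEF, R, D, CF by stratum) and the
linear biomass equations ship as CSV files inside the package; a frozen
checksum test guards them against accidental edits. `D` and `CF` are
constant across strata within a species; `CF` is constrained to (0, 1) and
all other parameters to be strictly positive. Overrides (YAML or mapping)
replace individual cells and re-run all validations, so an override that
breaks an invariant is rejected at load time.

## Method comparison

Per-method totals are compared by signed relative error against the
arithmetic mean of all supplied totals (no trimming). Pairwise method
differences over the per-species estimates use the two-sided Wilcoxon
signed-rank test: zero differences are dropped (Wilcoxon's original rule,
with the effective n reported), tied absolute differences are mid-ranked,
and for n ≤ 25 the p-value comes from the exact null distribution of the
statistic, enumerated by dynamic programming over the (doubled) ranks;
beyond that a normal approximation with tie and continuity corrections is
used. With seven species groups the exact branch is always taken in
practice. Spearman rank correlations use mid-ranks, with an exact
permutation p-value for n ≤ 9 (all n! orderings) and the t approximation
beyond. The significance level α = 0.05 annotates reports; nothing is
filtered by it, and no multiple-testing correction is applied (the
comparison is descriptive, six pairs at fixed α).

## Valuation

`value = 44/12 · C · P`, with 44/12 the tC→tCO₂e molar mass ratio. Two
built-in schemes: the mean of the eight 2019 pilot-market prices
(27.76 CNY/tCO₂e) and the shadow ("optimal") forest-carbon price, quoted
per tonne of carbon in USD and converted as `USD/tC · 12/44 · CNY/USD`
(10.11 USD/tC → 19.02 CNY/tCO₂e at 6.8985 CNY/USD). The conversion takes
the unrounded chain; converting through the rounded intermediate
(2.76 USD/tCO₂e) would give 19.04 and is not used. The reported value is
the scheme average, which by linearity equals monetising once at the mean
price. Values are carried in CNY and reported also in 万CNY (10⁴ CNY).
Inflation and exchange-rate dynamics are out of scope.

## Synthetic inventory and calibration

The record-level survey underlying the study system is unpublished; the
generator emulates its statistical structure and a calibration step pins
the published marginal totals exactly.

Generation: species are assigned to the 2,425 arbor records (plus 45
economic and 13 shrub records; 2,483 in all) multinomially with area shares
taken from the published/reconstructed species areas (*P. yunnanensis*
0.8852 of arbor area); age groups multinomially within species; zones
independently (0.376/0.164/0.460 core/buffer/experimental, implied by the
published zone stocks and densities), except that young *E. robusta* stands
are placed in the experimental zone, as the reserve's plantations are.
Areas are lognormal (mean = total area / record count, CV 0.8); volumes are
drawn as area × a lognormal volume density whose mean rises with age group
(45/83/180/204 m³/hm², consistent with the published per-age carbon
densities), keeping area and volume physically consistent. Everything is
driven by one `numpy` Generator seed; a fixed seed reproduces the table
byte for byte.

Calibration rescales each targeted group's areas (volumes) by a common
factor, preserving within-group relative structure and hitting group totals
exactly. The study-area fixture targets: per-species areas and
per-(species, age) volumes for the seven arbor species, and the economic
and shrub total areas.

Reconstruction of unprinted marginals (a documented modelling step, not
survey data): per-species volumes for four species are obtained by
inverting the pooled-expansion method on their published stocks or market
values, then rescaled by <0.01% so the seven volumes close the printed
arbor total exactly; missing areas come from published densities, a
published area difference and the arbor-area residual; the per-age volume
split (2.65/63.92/25.24/8.18% young/middle/near-mature/mature) comes from
the published per-age value shares, which under the pooled method are
volume shares.

### What the fixture does and does not show

Quantities pinned by printed marginals — the volume-conversion total, the
pooled-expansion species stocks, the area-based stocks, all valuation rows,
densities, proportions — reproduce the published numbers at printed
precision, for any seed. Quantities that depend on the true
per-species-per-age volume matrix — the totals of the age-stratified and
continuous methods — are reproduced only as closely as the reconstructed
split pins them: the fixture gives 690,892 tC (−0.24%) and 400,307 tC
(−0.016%) against the published 692,548.39 and 400,369.17 tC. Tests assert
these as calibrated claims at 2% relative tolerance. The fixture also
reproduces the *structure* of the published method comparison — all
pairwise Spearman correlations exactly 1 (every method is monotone in
species volume) and all Wilcoxon p-values above 0.05 — but not the exact
p-values, which depend on the unpublished matrix and an unstated software
convention for zeros and ties.

The generator emulates marginal composition, not spatial structure: no
compartment geometry or adjacency, no growth over time, and no
species–zone correlation beyond the *E. robusta* placement. Passing tests
on the fixture therefore validate the accounting pipeline, not any
landscape-level spatial inference.

## Problem sizes

The fixture's 2,483 records run through all five estimators, the
comparison statistics (exact branches at n = 7 species) and reporting in
well under a second; the full test-suite, including property-based checks
and brute-force enumeration oracles (2⁸ sign assignments, 5! permutations),
completes in a few seconds on one CPU.

## Known limitations

- Vegetation carbon only; no soil/litter/herbaceous/deadwood pools.
- Parameters are point values; no uncertainty propagation beyond the
  four-method spread.
- The continuous-method intercepts make that method sensitive to the
  aggregation level; only the two documented levels are offered.
- Currency values are nominal 2019 CNY.
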