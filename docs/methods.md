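# Methods

## Model structure

The engine is an annual-time-step mass balance over the carbon pools of a
Production-Approach HWP inventory: products in use (one pool per end
use), a recovered/recycled pool, landfill fixed and landfill decayable
pools, dumps, and three cumulative emission ledgers (with energy capture,
without energy capture, compost).  All internal arithmetic is in Tg C;
reporting converts to MMT CO₂Eq at 44/12 regardless of the eventual gas
species — the model does not speciate methane versus CO₂, so the
conversion is a carbon-mass convention, not a radiative-forcing claim.

Within one simulated year the operations run in a fixed order:

1. every existing pool decays by its annual loss fraction
   `λ = 1 − 2^(−1/h)`; landfill-decayable and dump losses accrue to EWOEC;
2. the recovered pool's outflow joins the year's discarded stream;
3. the year's harvest is allocated through the primary-product and
   end-use ratio tables; fuelwood-flagged allocations go straight to EWEC;
4. discarded mass is split across the six fates at that year's
   proportions; landfill inflow splits into fixed (`f·L`) and decayable
   (`(1−f)·L`); burned-without-energy and composted inflows emit in the
   disposal year (no residence half-life is defined for them); dumps
   carry no fixed fraction.

Decaying before adding inflows means a cohort takes its first loss the
year *after* it enters a pool; equivalently, mass landfilled in year `d`
holds exactly half its decayable share at year `d + h`.  This convention
is what the engine's closed-form and cohort tests pin down.

Because first-order decay is memoryless, pooled stocks multiplied by a
constant annual fraction are exactly equivalent to tracking every annual
cohort separately; the test suite keeps a deliberately naive per-cohort
implementation as an oracle and requires agreement to 1e-9 relative.

### The recovered loop

Flow diagrams for this model family show recovered material returning to
products in use, but after end uses are aggregated into discard
categories the destination end use of recycled mass is unknowable.  The
design choice here: the recovered pool decays with its own half-life
(2.6 yr default) and its annual outflow re-enters the **next** year's
discarded stream of the same end use, with no category change.  This
conserves mass and invents no end-use assignment, but it is one of the
intra-year conventions on which a reference implementation could differ,
so bit-exact agreement with other codes is not guaranteed; the mass
balance and decay conventions are testable properties either way.

### Shift-year reporting

With `shift_year` (the default), the state computed through year `t` is
reported under `t + 1`: a 1952–2019 harvest yields a 1953–2020 ledger of
68 reporting years.  It is a pure relabelling — shifted output at year
`t` equals unshifted output at `t − 1` — and the reporting layer derives
`n_years` from the ledger rather than hard-coding 68.

## Parameters

Default discard parameters (aggregate categories):

| category | dump half-life | landfill fixed ratio | landfill half-life | recovered half-life |
|----------|---------------:|---------------------:|-------------------:|--------------------:|
| paper    | 8.25 yr        | 0.44                 | 14.5 yr            | 2.6 yr              |
| wood     | 16.5 yr        | 0.77                 | 29 yr              | 2.6 yr              |

Product-specific landfill fixed-carbon ratios (EPA WARM v15 values):
corrugated 0.55, newspaper 0.84, office paper 0.12, coated paper 0.74,
dimensional lumber 0.88, MDF 0.84 (applied to plywood, OSB and MDF under
the "plywood" label), wood flooring 0.95 (in the table but never applied:
no end use matches it).  Their category means are 0.89 (wood) and 0.56
(paper).  IPCC North American bulk defaults: wood 0.9, paper 0.5.
Scenario updates change **only** fixed-carbon ratios and (for the dump
scenarios) fate routing; all half-lives keep their defaults.  Catchall
categories ("wood", "paper", "other_mixed_paper") keep the model defaults
under every EPA scenario.

The dump-closure cutoff defaults to 1995 and is a parameter
(`cutoff_year`); from that year on the dump share of every category's
discards is added to its landfill share.

## Disaggregation and its invariance oracle

All solid-waste pools are tracked per end use and grouped into discard
categories only when the ledger is assembled; grand totals are summed
over end uses in a fixed sorted order, independent of the grouping.  The
wood crosswalk (keyword matching on end-use labels, lowest priority
number wins, equal-priority conflicts are a hard error) therefore only
relabels pools: sub-categorising wood into lumber/plywood/wood with fully
inherited parameters reproduces the aggregate run bit-for-bit, which is
the key correctness oracle for the update machinery.  The paper
expansion, by contrast, splits wood-pulp mass across five categories by
multiplying by per-year fractions; IEEE multiplication does not
distribute over addition, so that path is checked at float-summation
precision (≤ 1e-12 relative) rather than bit equality.

Paper end-use ratios are tonnage shares of a five-category
waste-characterisation series, normalised per year; years before the
series start use the earliest year's shares and years after use the
latest (constant extrapolation — the minimal assumption), and an
all-zero-tonnage year is an error rather than a silent NaN.

## Synthetic inputs

The generator emulates the statistical structure of the California
inventory inputs rather than their values: a harvest series rising to a
1989 peak (5 Tg C/yr at peak by default) and declining ~4.5 %/yr after,
with small multiplicative noise (the peak year is pinned as the strict
maximum); four harvest classes feeding six primary products, with the
wood-pulp allocation stepping to zero after 2001; 224 end uses with
log-uniform in-use half-lives on [2, 150] yr (well under a second to
simulate, so no scaling down is needed anywhere); fate schedules in which
dumps fall from ~55 % of discards in 1952 to 2 % after 1990 while
landfilling rises, recycling grows, and end-of-life burning for energy
stays at zero; and a 1960–2018 waste-characterisation series with a
rising corrugated share and falling newspaper share.  Every stream of
randomness hangs off one seed.

What passing on synthetic data does show: mass conservation, decay
arithmetic, the disaggregation oracle, the sign and ordering structure of
the scenario comparison (every update deepens storage and lowers
emissions; bulk IPCC values move furthest).  What it does not show:
agreement with any real inventory's magnitudes, which depend on the real
harvest volumes, ratio histories and the reference implementation's
intra-year conventions.  Synthetic magnitudes are tuned only to land in
the hundreds of MMT CO₂Eq so plots and tables read naturally.

## Numerical choices

* Ratio tables must sum to 1 per (year, source) within 1e-9; an optional
  renormalisation pass (off by default, CLI `--strict` disables it)
  rescales sums within 1e-6 of 1 — anything worse is a data error that
  should surface, with the offending coordinates in the exception.
* Annual loss fractions use `−expm1(−ln 2/h)` for accuracy at long
  half-lives.
* No rounding happens internally; reports round to 2 decimals at
  presentation, and every identity (additivity, mean-annual ×
  years = cumulative) is tested pre-rounding.
* CSV round-trips are bit-exact: floats are written with shortest
  round-trip `repr` and parsed with round-trip precision.
* Percent change is `100·(baseline − alt)/baseline`, the single formula
  under which deeper (more negative) storage reports negative and reduced
  (positive) emissions report positive.
* Missing harvest years are an error in the input series, but a year with
  zero harvest is fine; NaN anywhere fails fast.

## Limitations

* No methane/CO₂ speciation, no landfill-gas capture, no import/export
  flows beyond the Production-Approach assumption that exports behave
  like domestic products.
* Dumps carry no fixed-carbon fraction; whether they should is left as an
  unexercised default (`dump_is_anaerobic` is reserved but inert).
* The recovered-loop convention above is explicit but not the only
  defensible one.
* The crosswalk ships with a small deterministic keyword rule set, not a
  reconstruction of any full published end-use mapping; real inventories
  should supply their own `crosswalk.csv`.
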