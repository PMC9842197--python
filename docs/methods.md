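# Methods

## Model structure

The simulation advances in yearly ticks.  Within a year the twelve submodels
run in a fixed order chosen by input dependency: exit decisions first (a
farm's books from last year determine whether it continues), then the land
markets and management adaptations that set this year's land configuration,
then the biophysical production chain (herd → fodder → manure → nitrogen →
milk), then governance and settlement.  Milk producer prices for the year are
drawn *before* the first submodel so that every within-year decision —
tenure bids, intensity switches, conversion choices — sees current prices.
The price draw is part of the market environment rather than a farm action,
so it is not counted among the twelve submodels.

All farm and field iteration is in ascending key order, every market
tie-break is explicit (bid, then farmstead distance, then lower key), and a
single seeded RNG stream serves world generation, price draws and inspection
sampling in a fixed consumption order.  A run is therefore a pure function of
(parameters, settings, seed); with zero price volatility and a zero
inspection fraction the RNG is not consumed after setup at all.

### State-variable convention

Immutable identifiers and geometry (`farm_id`, `field_id`, coordinates, the
farmstead location) are not state variables, and neither are the two
bookkeeping caches on farms (`loss_streak`, `years_since_switch`), which are
derivable from the profit and switching history.  Under this convention the
canonical registries hold exactly 7 farm, 8 field and 14 governance state
variables; registry tests pin these counts.

## Behavioral rules

**Exit.**  A farm exits when liquidity drops below the exit floor (default
0 €) or when it has run losses for `max_loss_years` (default 3) consecutive
years.  Exiting farms release herd and land.

**Tenure market.**  Released fields are offered in a single yearly clearing
round.  Each active farm whose holdings (snapshotted at market opening) touch
an offered field bids its myopic expected margin per hectare at its current
intensity; bids at or below the land rent abstain.  The highest bid wins,
ties broken by farmstead distance then lower key; winners hold the field as
rented land at the yearly rent.  Unclaimed fields fall fallow (habitat index
1, slowly recovering soil).  Fallow land is interpreted as *abandoned
grassland*: under a conversion ban the non-arable area (grassland plus
fallow) is non-decreasing, which is how the ban's conservation property is
asserted.

**Intensity adaptation.**  After an inertia period (default 3 years since
the last switch) a farm switches to the intensity class with the highest
myopic expected margin per hectare iff the gain over its current class
exceeds the per-hectare conversion cost; ties keep the current class.
Expected margins use current-year prices and levers and assume the farm's
manure stays on-farm, so expected tax and inspection exposure shapes
behavior even where the manure market could later absorb the surplus (a
deliberate precautionary-expectations rule).

**Land-use change.**  Intensive and very intensive farms convert grassland
to arable when the fixed arable gross margin beats their grassland margin by
more than the conversion cost, limited to a fraction of their grassland per
year (whole fields, at least one in a profitable year, least-fertile fields
first).  The conversion ban blocks this entirely.

**Manure market.**  Farms whose manure nitrogen exceeds the uptake capacity
of their spread area sell to farms with spare capacity, greedily in order of
increasing farmstead distance (ties: lower seller, then buyer key), at the
fixed manure price paid by the buyer.  Remaining nitrogen is spread evenly
over the farm's non-fallow hectares.

**Soil dynamics.**  A field gains fertility (`soil_gain_rate`, default
0.01/yr) when managed extensively within the uptake threshold, and loses
`soil_loss_rate × excess` (default 0.002 per kg N/ha above 170) otherwise,
clamped to [0, 1].  Fallow fields recover at the gain rate — a design choice
for land abandonment the base rule does not address.

## Parameters

The 43 pre-set parameters carry units and documented defaults in
`dairyscape.params.PRESET_PARAM_SPECS`.  The economic core (per-class yields
5/6/8/10 t/cow, stocking 0.8–2.4 cows/ha, variable costs 1 200–3 000 €/cow,
organic/conventional mean prices 500/380 €/t, fixed cost 15 000 €/farm) is
set to central-European magnitudes such that per-hectare margins rise mildly
with intensity (≈ 860–1 580 €/ha at mean fertility) with adjacent-class gaps
below the conversion cost: farms then have a weak intensification pull but
do not all collapse into one class, and taxes or subsidies of realistic size
tip the balance.  Manure nitrogen per cow (120 kg N/yr, within the usual
dairy excretion range) places very intensive stocking above the 170 kg N/ha
uptake threshold (≈ 240–290 kg/ha) and extensive stocking below it
(≈ 100–145 kg/ha), so nitrogen policy discriminates between classes.  Price
volatility (sd of log price, default 0.1) makes yearly class choices flap
occasionally — intended behavior mirroring fluctuating market prices, and
the reason experiments use replications with paired seeds.

A few quantities are fixed structure rather than registry entries: the herd
fertility floor (0.5), the arable gross margin (1 800 €/ha), the maximum
yearly conversion fraction (0.1), the arable and fallow habitat indices
(0.05, 1.0) and fodder intake per cow (5 t DM/yr).

Calibration gate: the shipped defaults keep ≈ 72% of farms active over a
30-year zero-policy run (20 replicates; `scripts/calibrate_baseline.py`),
comfortably above the required 60%.

## Ecosystem-service indices

Climate regulation, water quality and food provisioning are normalized by
landscape maxima (emissions, nitrogen surplus, milk) computed once at setup
from an all-very-intensive, fertility-1 configuration of the same landscape;
freezing the normalizers keeps indices comparable across years and policies.
Soil fertility and habitat provisioning are area-weighted means.  The fifth
service is fixed as water quality (nitrate retention), completing the
explicitly named four.  The joint index is a weighted mean (equal weights by
default); the regulating index is the joint index with zero food weight.

## Experiments

Sweeps are full-factorial over declared parameter/lever value lists;
replication *r* of every design point uses seed `base_seed + r`, so
contrasts are common-random-number comparisons.  Search optimizes a reporter
at the final simulated year, averaged over replications, on the lattice
defined per lever by (min, max, step); methods are exhaustive grid, uniform
random sampling, and first-improvement hill climbing over ±1-step neighbors
(evaluations cached per point).  One-at-a-time sensitivity perturbs a
parameter to (1±δ) of its baseline and reports the central normalized
elasticity; integer parameters are rounded after scaling.  Group contrasts
use Welch's two-sample t test (scipy).

## Study conditions and outcome definitions

Directional policy experiments and the acceptance script use the default
landscape (10×10 fields of 2 ha, 12 farms) over 30 years with 20 paired-seed
replicates; a run's outcome is the mean of a reporter over its final five
years — the end state of a policy era, smoothed over price noise.  These
sizes keep the full suite and the acceptance script in the tens of seconds
while leaving Monte-Carlo error well below the effect sizes involved.

## What the generated worlds do and do not capture

The random world generator produces equal-area square fields, uniformly
drawn initial fertility, round-robin initial intensities and
nearest-farmstead land allocation.  It does not emulate realistic field
geometry, spatially correlated soils, farm-size distributions, off-landscape
feed purchases, succession, or within-year dynamics.  Passing tests
demonstrate the mechanisms (markets, taxes, soil feedbacks, trade-offs)
under these stylized conditions, not quantitative predictions for any real
landscape; the file-based world loader exists precisely so users can supply
more realistic layouts.

## Numerical choices and degenerate inputs

Herd sizes floor to integers; market quantities compare with 1e-9
tolerances; profit statements must satisfy their balance identity to 1e-6
(relative) or settlement raises an accounting error.  A landscape with no
active farms still advances: production reporters are zero, climate and
water indices are 1, food is 0.  Zero-variance group comparisons report
t = 0, p = 1.  Empty inspection samples and zero-volatility price years skip
the RNG entirely so determinism contracts hold exactly.

## Known limitations

Agents are myopic one-year optimizers; there is no anticipation, learning or
heterogeneity in decision rules.  The manure market clears by distance
greedily, not by price formation.  Arable economics are a single fixed
margin.  GHG emissions are herd-proportional only (soil N₂O is folded into
the nitrate pathway to keep the two taxes orthogonal).  Subsidy deductions
reduce government outlays rather than appearing as revenue.  Results should
be read as qualitative policy-response patterns.
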