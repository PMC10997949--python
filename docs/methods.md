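# Methods

## Plug-flow retention time model

The model treats an in-building secondary water supply system as a tree:
an inlet tank, pumped riser legs between tanks and up to each zone's entry
floor, a gravity (or pumped) down-feed through the zone's storeys, and one
horizontal line per floor. Flow is steady and plug (a parcel moves as a
coherent slug at velocity Q/A), so each element contributes volume/flow to
the retention time and the components add:

    HRT(k) = Σ T_tank  +  Σ_legs V_leg / Q_leg  +  Σ_{j=k..top} Vs(j) / Q_cum(j)
             + Vh(k) / Q(k)

* Riser legs run from each tank's floor to the next tank's floor (the last
  leg to the zone entry floor) and carry the summed average demand of every
  floor ultimately fed through that tank. Legs between tanks are charged to
  the zones fed through the downstream tank, so a pumped-zone tap pays for
  both the inlet-to-mechanical-floor leg and the mechanical-floor-to-top leg.
* The down-feed segment through storey j carries the cumulative demand
  Q_cum(j) of the zone's floors from the zone bottom up to j; the sum runs
  from the tap's storey to the zone's top served floor. If a zone's entry
  floor sits above its top served floor, the extra storeys are traversed at
  the zone's full demand (the natural plug-flow extension; the packaged
  layouts have entry floor = top served floor).
* Per-storey standpipe volume uses each traversed storey's own geometry;
  storeys with no floor record (basements, mains-supplied lobbies) fall back
  to building-level defaults. Uniform geometry recovers the
  (number of storeys)·Vs/Q form.

Assumptions: no looped networks, no pressure/pump-curve or transient
hydraulics, no in-pipe decay or regrowth kinetics — HRT is a purely
hydraulic covariate. Taps, storeys, or risers with zero cumulative demand
make the HRT undefined; they are reported with an explicit `stagnant`
status rather than an infinite value so downstream statistics can drop them
deterministically (exclusion counts are carried on association results).

### Verification

`swss_hrt.oracle` re-derives every tap's HRT by explicit parcel tracking
over the enumerated element chain, with segment flows recomputed by
brute-force enumeration of downstream tap sets. The event-based tracker
agrees with the analytic engine to ~1e-15 relative (tested on the packaged
layouts and on 100+ randomized topologies; the test tolerance is 1e-9).
A time-stepped variant advances the parcel in whole dt increments and is
first-order accurate; it exists to confirm the event times are physical,
not for production use.

## Packaged layouts and parameter defaults

Two layouts ship with the package: a 34-storey office tower (inlet tank on
basement floor −2, mechanical floor 23, zones 6–23 and 24–34; floors 1–5
mains-supplied/non-operational) and a 45-storey residential tower
(mechanical floor 30, zones 3–30 and 31–45; floors 1–2 mains-supplied).
Their riser legs therefore span 25/11 and 32/15 storeys.

Defaults, all overridable per floor or per tank in the YAML config:

| parameter | default | rationale |
| --- | --- | --- |
| storey height h | 3.0 m | typical storey rise |
| standpipe diameter ds | 0.05 m | galvanized steel risers are < 50 mm |
| horizontal diameter dh | 0.025 m | 25–30 mm on-floor lines |
| horizontal length l | 10 m | order of an on-floor run; the config leaves open whether l means the full run or the distance to the sampled tap |
| demand | 7 t/month per served floor | mid-range of the 1–14 t/month observed bands |
| inlet tank residence | 4 h | unpublished in practice; chosen with the break tanks so default profiles land in the plausible 6–12 h range |
| break tank residence | 2 h | operator-regulated "avoid prolonged storage" |
| month length | 30 d (2 592 000 s), 1 t = 1 m³ | simplest monthly-tonnage bridge |

With these defaults the office profile spans 5.1–9.5 h (mean 6.6 h). These
storage times are assumptions, not measurements; the absolute HRT level is
only as good as the tank settings, while the *floor-to-floor structure*
(monotone decrease within a zone, pumped-zone excess) is geometry-driven.

Two structural properties hold under uniform demand and geometry: HRT
strictly decreases with storey within a zone (higher taps sit closer to the
entry floor and their down-feed has fewer, faster terms), and scaling all
demands by c scales every non-tank component by exactly 1/c. The often-
quoted "pumped zone always exceeds gravity zone" holds only when the break
tank's dwell plus the extra riser leg outweigh the gravity zone's deepest
down-feed — true at the packaged 2-h break-tank storage, not universally.

## Synthetic observation generator

The generator produces the quantitative endpoints of a tap survey, not
sequences or community tables. What it emulates, per tap:

* consumption bands: floors are assigned low (uniform 1–5 t/month) or high
  (uniform 10–14 t/month) usage with P(low) = 9/16, the banded proportion
  of the motivating survey design;
* log10 16S rRNA gene copies = α + β·HRT_h + N(0, σ), with α = 3.0,
  β = 0.3 log10/h so a building's taps span roughly two orders of
  magnitude — a log-scale response chosen because reported high-floor
  excesses are of that magnitude. Absolute copy numbers are placeholders,
  uncalibrated to any assay;
* Fe (mg/L) = 0.02 + 0.004·HRT_h + noise, truncated at 0 (truncation is
  negligible at the defaults);
* Zn/Cu lognormal around pipe-material means (galvanized plastic-lined
  steel: Zn 0.40, Cu 0.005 mg/L; polypropylene with brass fittings:
  Zn 0.10, Cu 0.069 mg/L), log-SD 0.5.

Noise is calibrated, not tuned: given the realized HRT design x, the
population coefficient of determination of a linear signal b·x plus
N(0, σ²) noise is R² = b²Var(x)/(b²Var(x)+σ²), so
σ = |b|·sd(x)·√((1−R²)/R²) hits any target exactly (population variance,
ddof = 0). Targets default to R² = 0.63 for 16S and r = 0.79 for Fe. One
master seed spawns independent substreams (demands, 16S noise, Fe noise,
metals) via `numpy.random.SeedSequence`, making output tables
byte-identical across reruns.

What the generator does **not** emulate: replicate taps with shared
plumbing history, assay detection limits and censoring, temporal variation,
community composition, or any nonlinearity in the HRT response. Passing
recovery tests therefore demonstrates that the pipeline's statistics are
calibrated and unbiased under the stated linear-Gaussian conditions — not
that real tap-water data satisfy them.

## Association analysis

Pearson r and the simple OLS fit are computed from first principles (the
one-predictor R² equals r² identically; tests cross-check both against
scipy). Significance uses a two-sided permutation test on |r| with the
add-one estimator p = (1 + #{|r*| ≥ |r_obs|})/(B+1): at n ≈ 30 it avoids
normality assumptions, is never exactly zero, and with B = 199 the
achievable rejection rule p ≤ 0.05 has exact level 10/200 = 0.05 under
exchangeability. Undefined-HRT rows are excluded listwise with the count
reported. Results carry both r and r², since published correlation
coefficients are quoted on either scale. No multiple-testing correction is
applied; consumers receive raw p-values.

Monte-Carlo design for the recovery checks: 31 taps (the survey's tap-count
scale) realised as the 31 consecutive served floors 3–33 of the residential
layout, one tap per floor — a fixed design keeps the replicate study clean;
500 noise/demand replicates for R² and slope recovery; 1000 null replicates
(B = 199) for the type-I rate. The slope-bias criterion is a 2-SE z-test:
for the (analytically unbiased) OLS slope the z-statistic is a standard
normal across seed families, so isolated excursions slightly past 2 are
expected about 5% of the time and do not indicate bias.

## Numerical choices and edge cases

* Analytic vs event-tracking tolerance 1e-9 relative (observed ~1e-15);
  the time-stepped tracker is documented O(dt).
* Exact-zero flow (not a small threshold) triggers stagnation handling;
  demands are validated non-negative at construction.
* Group summaries use the sample SD (n−1); singleton groups report the SD
  as undefined rather than 0.
* Degenerate association inputs (constant vectors, < 3 complete pairs,
  length mismatch) raise typed errors rather than returning NaN.
* All file outputs are written atomically (temp file + rename); a failed
  run never leaves a partial table.

## Known limitations

* Steady average flows: diurnal demand patterns, simultaneous-use peaks and
  overnight zero-flow stagnation are outside the model, although the
  first-draw pipe-length arithmetic quantifies which pipe a stagnation
  sample represents.
* Tank residence times dominate the default HRT level and are assumptions.
* The generator's linear-Gaussian endpoints are a deliberate idealization;
  see above for what passing tests do and do not establish.
* Zone ranges are contiguous; buildings with interleaved supply strategies
  on the same riser are not representable.
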