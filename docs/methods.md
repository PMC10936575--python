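# Methods

## The attribution model

`pyrofar` treats "an extreme fire" as a threshold exceedance event:
the event of interest at size *s* is *final fire size > s*. For a
pair of scenarios it estimates the exceedance probabilities p0(s)
(reference landscape) and p1(s) (counterfactual landscape) and forms

- FAR(s) = 1 − p0(s)/p1(s), the fraction of the event's probability
  attributable to the condition that differs between scenarios, and
- RR(s) = p1(s)/p0(s), the risk ratio,

pointwise over a shared fire-size grid. The framework is agnostic
about *which* real-world landscape plays which role, and the role
assignment genuinely flips between use cases: a retrospective
analysis of an observed fire puts the actual (mitigated) landscape at
p0 and the untreated counterfactual at p1, while a prospective
treatment evaluation puts the hypothetically treated landscape at p0
and the actual untreated landscape at p1, so that FAR and RR read as
attributable *benefit* of treating. Because a silent convention error
flips the sign of every conclusion, the API and CLI require the
caller to declare the direction explicitly, and the declaration is
carried verbatim into every report (`direction_note`).

Assumptions: the two ensembles are independent samples of final fire
size under their respective scenarios (no pairing between members is
assumed or used); fire size is a continuous positive quantity; no
confounder adjustment or causal-graph structure is attempted — the
metrics compare two fixed, fully specified simulation worlds.

## Exceedance estimation

Each ensemble's size distribution is smoothed with a Gaussian kernel
density estimator and integrated upward:

- **Bandwidth**: Scott's rule, h = σ̂·n^(−1/5) with σ̂ the sample
  standard deviation (ddof = 1), by default; Silverman's rule or an
  explicit bandwidth in hectares are accepted. Scott is the common
  default for unimodal samples of this size, and the ±3% tolerances
  used on percentile statistics absorb the difference between rules.
- **Grid**: one shared grid per analysis, 512 points, spanning the
  pooled sample range padded by 3 bandwidths per side (≥ 99.7% of
  kernel mass) and floored at 0. Using one grid for every curve makes
  FAR/RR pointwise well-defined.
- **Negative-size mass**: fire sizes are positive, so kernel mass
  smoothed below zero is removed by truncating at the grid and
  renormalizing the density to unit trapezoidal integral. Reflection
  at the boundary was rejected: for realistic inputs the sample sits
  many bandwidths above zero and the correction is negligible, but
  truncation keeps it deterministic and exactly normalized.
- **Integration**: composite trapezoid on the fixed grid, no adaptive
  quadrature — reproducible and grid-exact. Exceedance is the strict
  event P(X > s); for the continuous KDE this is immaterial, and the
  empirical oracle (#{xᵢ > s}/n) adopts the same convention so the
  two estimators are comparable point by point.

Threshold lookups (`far_at`, `rr_at`, percentile events, FAR
crossings) interpolate the *probability* curves linearly and apply
the metric afterwards, rather than interpolating FAR or RR directly;
this keeps the duality FAR = 1 − 1/RR exact at off-grid sizes. FAR
curves need not be monotone, so the reported crossing of a FAR level
is the *first* attainment scanning upward in size.

## Edge cases and numerical floors

Ratios of tail probabilities are numerically treacherous, so the
metric functions never raise on degenerate probabilities — curves
stay total and edge cases are flagged in-band: FAR is NaN where
p1 ≤ 10⁻¹² (no event probability to attribute), RR is +inf where
p0 ≤ 10⁻¹² < p1 and NaN where both vanish. The 10⁻¹² floor separates
true zeros of the empirical estimator from KDE tail dust; curves also
carry an explicit `valid_mask`. JSON reports serialize NaN as `null`
and infinities as `"inf"`/`"-inf"` so files remain strictly valid
JSON and round-trip losslessly.

## Bootstrap uncertainty

Sampling uncertainty is quantified by a nonparametric bootstrap:
members of each ensemble are resampled with replacement
(independently per scenario), the full KDE → exceedance → FAR/RR
pipeline is recomputed per replicate on the *same* grid with the same
settings, and pointwise percentile intervals (default 95%, 1,000
replicates) are reported. The seed is a mandatory argument; identical
seeds give identical bands. This is the simplest defensible
uncertainty for ten-member ensembles; it reflects resampling
variability only, not FARSITE/FSim structural error. Replicates that
resample to zero variance contribute undefined values, and any grid
point undefined in more than half the replicates is flagged
unavailable rather than banded. Band widths should be compared across
analyses at matched thresholds: each analysis's grid extends into its
own tails, where bands are intrinsically wide.

## The synthetic paired-ensemble simulator

The simulator generates the *statistical structure* of paired
landscape fire experiments — one scenario stochastically producing
larger fires than another — without fire-behavior physics. Fires
percolate on a square lattice: each newly burning cell attempts once
to ignite each 4-neighbor, succeeding with the probability of the
*target* cell's fuel state (treatment slows fire entering treated
fuel) times a per-fire weather multiplier. Burned cells never reburn;
spread stops when no new cells ignite.

Defaults, chosen once as a realistic toy scale:

| parameter | default | why |
|---|---|---|
| grid | 64 × 64 cells, 10 ha/cell | 40,960 ha landscape; runs in seconds |
| `p_spread_untreated` | 0.55 | just above the square-lattice bond-percolation threshold (0.5), so the size distribution has a heavy upper tail and treatment moves the extremes |
| `treatment_multiplier` | 0.3 | treated fuel admits fire at 30% of the untreated rate — strong but not fireproof |
| `weather_sigma` | 0.3 | per-fire lognormal multiplier (median 1) emulating between-event weather variability; the lognormal form is a stand-in, as no distributional detail is available for the systems being emulated |
| `n_fires` | 2,000 | enough for stable 90th-percentile statistics in seconds |

Scenarios are coupled by common random numbers: fire index *i* draws
the same ignition site, weather multiplier, and one uniform variate
per directed lattice edge on every landscape. An edge (source →
target) is open iff its uniform is below the target's effective
spread probability, and the burned set is exactly the set reachable
from the ignition through open edges — so reducing any cell's spread
probability can only shrink a given fire. Random treatments drawn
with the same seed take prefixes of one permutation of the burnable
cells, making treated sets nested across fractions; together these
give deterministic per-fire ordering of sizes across treatment
extents, isolating the treatment signal from between-fire noise.

What the simulator deliberately does not reproduce: fire-weather time
series, spotting, suppression, heterogeneous real fuels, and the
absolute scale of real fire-size distributions. Passing tests built
on it therefore demonstrate that the attribution pipeline responds
correctly to a known, monotone treatment effect under stochastic
spread — not that any particular real landscape behaves this way.

## Problem sizes used in tests and checks

The bundled retrospective analysis uses the two 10-member ensembles
as published. Convergence and recovery checks use synthetic lognormal
ensembles of n = 10,000 (KDE vs empirical gap < 0.05; RR at the
reference median within 10% of the analytic two-lognormal value).
The treatment-extent comparison simulates 2,000 fires per scenario on
the default 64 × 64 landscape; bootstrap checks use 120–1,000
replicates on ensembles of 10–1,000 members.

## Known limitations

- Ten-member ensembles give very noisy tail estimates; RR in the
  upper tail has bootstrap bands spanning orders of magnitude, and
  point RR values beyond the 90th percentile should be read as
  order-of-magnitude statements.
- The KDE pathway reports smooth nonzero exceedance slightly beyond
  the sample range (kernel tails); the empirical estimator is exact
  but stepwise. Both are reported so the smoothing assumption is
  auditable.
- Replicates within an ensemble are treated as independent; if the
  underlying simulations were paired across scenarios, the
  independent bootstrap is conservative.
- Attribution here is single-step (landscape condition → fire size).
  Probabilities of necessary/sufficient causation, multi-step causal
  chains, and confounder adjustment are out of scope.
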