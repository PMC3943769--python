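# Methods

## Scope and model

`locustdd` implements a degree-day (DD) framework for the oriental migratory
locust in which daily heat is measured by integrating a polynomial fitted to
the 24-h diurnal temperature course, and in which two classes of "invalid"
heat are deducted before heat is converted into development:

1. **Overflow heat.** Constant-temperature rearing shows the development
   rate rising linearly with temperature up to ~32 °C and flat above it, so
   heat above 32 °C is accumulated separately (the same integral with the
   32 °C base) and excluded from development-effective totals.
2. **Oviposition-ineffective heat.** Females do not lay below a ~21 °C
   floor. During the adult egg-laying window, whole days whose mean
   temperature is below 21 °C contribute their full daily DD to an
   "ineffective" pool that is deducted from the season budget.

The resulting ledger, `standard = effective − overflow − ineffective`, is
what voltinism calculations use, with ~700 DD per egg-to-egg generation and
`generations = (n−1) + [actual − 700(n−1)]/700` (algebraically `actual/700`;
the expanded form is kept because it is how the ledger is conventionally
reported).

## Diurnal curve and integration

Each day's readings (hour indices 1..24) are fitted by least squares with a
polynomial of degree 1–6 (default 6). There is no automatic degree
selection. Coefficients are stored highest-degree first.

The curve's validity domain is [0, 24] hours. The fit uses samples at 1..24,
but a 24-h-long domain is required for internal consistency: a day constantly
one degree above threshold must yield exactly 1.0 DD under both the integral
(area/24) and degree-hours (Σ excess/24) conventions, which a 23-h domain
cannot satisfy. The sub-hour extrapolation to t < 1 is mild for realistic
diurnal fits.

Threshold crossings are bracketed on a 0.01-h grid and refined by Brent's
method to ~1e−9 h; all crossing intervals of a degree-6 curve are retained
and summed, and intervals are clamped to the domain when the day starts or
ends above threshold. The area above the threshold uses the exact polynomial
antiderivative, not quadrature; a midpoint-rule oracle at 10⁴–4·10⁴ points is
used in the tests as the independent check (agreement ≤ 1e−4 DD).

DD accumulation floors at zero; the signed daily-mean value (negative on
sub-threshold days) is exposed only by the method-comparison module, where
the sign error of the daily-mean method is part of the story.

## Method comparison

Four methods are tabulated per day: daily mean (signed), max–min, degree-
hours, and the 24-h integral, with relative error |X−Y|/Y·100 against the
integral. DD values are rounded to 1 decimal and errors computed from the
rounded values, matching how such comparison tables are conventionally
printed (unrounded inputs would give ≈156 % instead of 167 % on the
reference day).

The max–min method has two variants. The citation trail for this method
points to the single-sine formulation, but the published 0.2 DD on the
reference day is reproduced by the triangle formula
(Tmax−C)²/(2(Tmax−Tmin)), not by the sine (≈0.3). Both are implemented; the
triangle is the default so the comparison table reproduces.

## Development-rate regression

Rates V = 1/duration from constant-temperature rearing are fitted by OLS
(scipy `linregress`) within the linear range, default 18–31 °C; observations
outside the range (the >32 °C plateau) are excluded rather than down-
weighted. LTT = −intercept/slope and K = 1/slope are exact derived values.
The reference egg line gives LTT 14.0 °C; the package nonetheless defaults
stage thresholds to 14.2 °C for eggs and nymphs, the value standardized in
prior work on this subspecies, with 21 °C for adults.

## Season simulation

`simulate_development` advances stages by the daily rate V_i = DD_i/K_i,
where DD_i = Σ max(0, min(T_h, 32) − C_i)/24 over the day's hourly readings.
Using the capped degree-hours form (rather than re-fitting a curve per day)
makes the trajectory *exactly* invariant to replacing any reading above
32 °C by 32 °C — the defining property of the overflow plateau — and is the
natural choice for chamber data that are generated hourly in the first
place. The curve-integral method remains available for season ledgers.

Defaults: egg C 14.2 °C, K 200 DD (1/0.005); nymph C 14.2 °C, K ≈ 333 DD
(1/0.003); adult oocyte maturation C 21 °C with K ≈ 167 DD chosen to close
the egg-to-egg budget at ~700 DD. All overridable.

A stage completes when cumulative V_i reaches 1 (recorded at day
resolution). The adult phase is a pre-oviposition lag: either interpolated
against the adult-period mean temperature from the constant-temperature
observations (12.7 d at 30 °C up to 17.4 d at 22 °C, clipped outside) or a
fixed lag. Oviposition — which closes the generation and starts the next
egg cohort — occurs on the first post-lag day with mean > 21 °C; on post-lag
days too cool to lay, the day's DD joins the ineffective pool. Eggs read the
ground sensor when present (eggs develop below ground); other stages read
air. The fractional progress of an unfinished final generation is reported
as completed phases plus the current phase's fraction, over the three phases
of a cycle.

The theoretical generation count n uses the traditional model's 800 DD per
generation: n = max(1, round(total/800)), which reproduces the published
counts (1, 1, 1, 2, 3, 4, 5) for the seven reference sites from their season
totals.

## Synthetic climates

The generator emulates the growth-chamber protocol: one mean temperature per
10-day block, a diurnal cycle of half-amplitude 5 °C by default, and
location-specific season lengths (110 d for the coldest site up to 360 d).
The within-day shape is a piecewise half-cosine with minimum at 05:00 and
maximum at 14:00 — chambers were only specified as "±5 °C", so the shape is
a documented fixture choice and configurable. Each half-cosine limb averages
to the block mean, so the daily mean equals the block mean (exactly in
continuous time, within ~0.1 °C at 24 hourly samples). Optional Gaussian
noise (default off) is driven by a `numpy` generator seeded from the spec;
identical seeds give bit-identical series.

What the generator does *not* emulate: weather fronts and day-to-day
autocorrelation, asymmetric heat waves (so synthetic overflow DD is
conservative), humidity, photoperiod effects (carried as metadata only),
and soil thermal inertia (a "ground" series is just a label). Passing tests
therefore validate the arithmetic and the model's internal contracts on
chamber-like inputs, not forecast skill on real station data.

## Numerical and reporting conventions

* Root tolerance 1e−9 h; bracket grid 0.01 h (finer than any physical
  diurnal feature).
* Daily DD reported to 1 decimal, season totals to integers, generations to
  2 decimals; all rounding happens at serialization, never internally. The
  season report balances its ledger on the rounded integers.
* Days with fewer than 20 hourly readings fall back from the curve fit to
  degree-hours over the available readings, with a warning.
* Relative error against a zero reference is defined as 0 when the compared
  value is also 0, else an error is raised.

## Known limitations

* The reference day's published crossing times (7.0745 and 18.3312 h) are
  not recoverable to 0.01 h from the published polynomial coefficients,
  which are rounded to 5 significant figures; root-finding on them gives
  7.0527 and 18.3814 h. The integral DD is insensitive at the printed
  precision (0.3 DD either way).
* The oviposition gating rule (lag + first warm day) is a modelling choice;
  observed pre-oviposition behaviour was measured at constant temperatures
  only.
* Diapause, overwintering egg survival, density effects and photoperiod-
  dependent development are out of scope.
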