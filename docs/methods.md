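# Methods

## The model

The package estimates the parameters of the factorial net-energy predictor

    NE = NE_m · BW^0.75 + NE_g · ΔW        [kJ/d; BW in kg, ΔW in g/d]

from a restricted-feeding comparative-slaughter trial. The factorial method
assumes maintenance and growth costs are additive, that maintenance scales
with metabolic body weight BW^0.75, and that the energy cost per gram of
gain is constant over the age window considered. All parameters are
window-specific: the defaults and the bundled reference data describe
2-to-3-week-old growing ducks, and nothing in the chain models sexual
maturity, thermoregulation outside thermoneutrality, or activity.

Inputs are four tables (diet assay, per-group excreta assays, per-replicate
intake log, serial carcass records) with fixed units: MJ/kg for assay
energies, kJ for whole-body energies, g for masses. No unit autodetection
is attempted; silent unit mixing is the chief failure mode of energy
bookkeeping.

### Marker-based AME

`AME = GE_diet − GE_excreta · AIA_diet/AIA_excreta` relies on conservation
of the acid-insoluble-ash marker through the gut. AME is computed per
feeding-level group (digestibility rises slightly with restriction) and
the group-specific value feeds that group's MEI. Apparent metabolizability
is stored as a fraction and rendered as a percentage only in reports. A
negative computed AME — possible under heavy assay noise — is flagged and
warned about, not raised, so recovery studies survive extreme draws. The
excreta energy basis is "as assayed": the schema does not distinguish
dried-matter from air-dry bases, which is left to the user's assay
convention.

### Energy balance

Per replicate, over the balance period of `days` days:

- `MEI_total = ADFI × days × AME` (MJ/kg feed ≡ kJ/g);
- `RE_total = BE_final − BE_baseline`, with the baseline whole-body energy
  taken from the mean of the separately slaughtered baseline group
  (comparative slaughter estimates the starting state, it cannot observe
  it on the same bird);
- `HP = MEI − RE` — a definition, asserted exactly on every record, never
  approximated;
- the protein/fat partition applies the deposition equivalents 23.69 and
  39.22 kJ/g to the composition gains over the same period and the same
  metabolic-weight normalization.

Mean metabolic body weight over the period defaults to the midpoint
convention, `((BW_i + BW_f)/2 / 1000)^0.75`. A `daily-mean` switch instead
averages BW^0.75 over linearly interpolated daily weights; over the
two-week growth range of the reference trial the two differ by about 2%.
The midpoint convention is the one under which the simulator's generative
laws are exact (below), and is the package default.

If a carcass row supplies both whole-body energy and energy density they
must agree within 1% (they are mutually redundant); when energy is absent
it is computed as BW × density. The water+protein+fat closure check warns
above 100% and rejects above 105%: the fractions come from different
wet-chemistry assays and can overshoot closure on real carcasses — the
bundled 7-day baseline row itself sums to 103.42%.

### Regressions

A minimal OLS engine (one or two predictors plus intercept, optional
per-observation weights) backs the chain. Coefficients come from SVD least
squares; the test suite checks them against an independently written
explicit normal-equations inversion at 1e−9. R² uses the centred total sum
of squares; RMSE uses residual degrees of freedom n − p − 1 with p the
number of predictors. Condition numbers above 1e10 raise a rank error
(the message carries the condition number). No p-values are computed:
group-comparison inference is outside the estimation chain.

Maintenance requires ≥ 3 records spanning ≥ 2 MEI levels and positive HP
everywhere (the log transform is base 10 throughout; any other base breaks
the arithmetic 10^2.74 = 549.54). NE_m is the antilog of the log-HP
intercept; ME_m is the x-intercept −intercept/slope of the RE–MEI line;
K_m = NE_m/ME_m and K_g is the RE–MEI slope. Growth regresses whole-body
energy on body weight over **all** carcass records (baseline, mid-period
and final slaughters). Efficiencies take K_p = 1/b_p and K_f = 1/b_f from
MEI = b0 + b_p·RE_p + b_f·RE_f — the reciprocal convention of the Boekholt
partition model. Fitting defaults to unweighted replicate-level records; a
`replicate-count` weighting switch equalizes group contributions because
the reference design is unbalanced (10 ad-libitum vs 5 restricted
replicates) and the published fits' weighting is not stated.

### The bundled reference dataset

`netenergy.reference` transcribes the published group means of a Cherry
Valley duck trial (five feeding levels, 14-day balance, serial slaughters
at 7/14/21 d) as a degenerate one-replicate-per-group trial, together with
the published regression coefficients and parameter values. Restricted
groups' 21-d body weights were not printed and are reconstructed as
BW(7 d) + ADG × 14 from the published gains.

Two published numbers are internally inconsistent and are carried as
machine-readable flags rather than repaired silently:

- the 55%-level heat production (printed 835.19; the identity MEI − RE
  gives 875.18) — the pipeline recomputes HP from the identity and warns;
- K_f (printed 0.96; the reciprocal of its own printed coefficient 1.08 is
  0.926) — the reciprocal convention is retained.

The replicate-level observations behind the published n = 15 regressions
were never published, so refits on the group means deviate from the
published coefficients; `netenergy reproduce` reports those deviations,
and the desk checks only assert quantities that follow from printed inputs
by their defining arithmetic (antilog, x-intercept, ratio, reciprocal,
identity, marker formula, and the three-point growth slope).

## The simulator

`simulate_trial` emulates the reference design: graded intake levels
(1.00/0.85/0.75/0.65/0.55 × 113.47 g/d), 10/5/5/5/5 replicates, a 10-bird
baseline group, a 5-replicate mid-period slaughter in the ad-libitum line,
a 14-day period starting from a 171.12 g bird with 14.02% protein and
16.85% fat, AME 13.5 MJ/kg from a 16.90 MJ/kg diet with 0.26% AIA and 75.5%
mass digestibility. Defaults for the energy parameters are the reference
estimates (NE_m 549.54, K_m 0.8784, K_g 0.75, NE_g 10.41, K_p 0.60,
K_f 0.926).

Choices a reader should know:

- **Two generative HP modes.** The log-linear HP law and the linear RE law
  cannot both hold exactly; each mode makes one of them exactly
  recoverable. `linear_re` (default) grants exact K_g/ME_m (and, through
  the partition, K_p/K_f); `exponential` grants exact NE_m and log-slope.
  Under `linear_re` the log-extrapolated NE_m carries a ~2.5% upward
  model-discordance bias, asserted as a bias (bounded), never as equality.
- **Period-scale laws, daily bookkeeping.** The generative laws are imposed
  exactly on the balance-period aggregate per midpoint metabolic weight —
  the scale on which the pipeline estimates — and the daily trajectory
  (ΔW = RE/NE_g per day) distributes the totals. Imposing per-day laws
  instead would break exact recoverability, because the mean daily
  metabolic weight differs from the midpoint value by a level-dependent
  factor.
- **Replicate offsets.** A partition driven by MEI alone makes RE_p and
  RE_f exactly collinear, so the Boekholt fit would be rank-deficient on
  noiseless data. A deterministic zero-sum within-level offset pattern on
  RE, orthogonalized against [1, MEI] (amplitude 15 kJ·(kg^0.75)⁻¹·d⁻¹),
  emulates animal variation while leaving the RE–MEI fit exact; the
  partition then solves the RE-sum and Boekholt-plane constraints per
  replicate, keeping K_p/K_f exactly identifiable.
- **Partition geometry.** In `linear_re` mode the marginal fat share of
  retained energy is fixed by (K_g, K_p, K_f); the `fat_share_intercept`
  anchor (−285) sets its level so the fat share rises mildly with intake.
  A side effect is a flattened body-fat% gradient across feeding levels;
  the reference trial's composition orderings (fat% falls, protein% rises
  with restriction) are reproduced in `exponential` mode, where the fat
  share is a free level-dependent parameter (0.62 at ad libitum, slope
  0.22 per unit level).
- **Noise model.** Multiplicative log-normal, mean one, CV `noise_cv`, on
  assayed quantities only: diet GE/AIA once, excreta GE/AIA per assayed
  pool, carcass energy and composition fractions per record. Intakes are
  design-controlled and exact; body weights are weighed, not assayed. The
  group excreta value is the mean of `excreta_pools = 5` noisy pool draws,
  mirroring the metabolic experiment's five replicate pools per treatment.
  Water closes the composition to 100% minus a fixed 3% ash allowance.
  The default CV of 2% produces group-mean standard errors of the same
  order as the reference tables'; it is not calibrated to them.
- **Determinism.** Identical `SimParams` (including seed) give bit-identical
  tables; a seed is mandatory whenever noise is nonzero.

What passing recovery tests do **not** show: the simulator writes the
pipeline's own laws into the data (up to the documented mode discordance),
so recovery demonstrates correctness of the bookkeeping and estimation
code, not adequacy of the factorial model for real birds. Real trials add
between-bird variance in intake and maintenance, non-log-linear HP,
basis ambiguities in the assays, and composition closure errors, none of
which the generator emulates.

`recovery_study` refits `n_trials` simulated trials (seeds
`seed … seed + n_trials − 1`) and reports per parameter the truth, median
estimate and median absolute relative error; maintenance/growth estimates
are kept even when the partition fit of the same trial fails (its
predictors can be near-collinear under noise in `exponential` mode), and
failures are counted. At the default conditions (CV 2%, 200 trials) the
study runs in a few seconds; median relative errors are ≈ 0.4% for NE_g,
≈ 4% for K_g and ≈ 4.8% for NE_m — the NE_m figure includes the linear_re
mode's extrapolation bias and sits close to its 5% acceptance bound.

## Numerical notes

- Fixed-point solution of the period trajectory (final BW given the
  energy law) converges geometrically (contraction ≈ 0.27 at the default
  parameters); iteration stops at 1e−11 g. The offset-orthogonalization
  outer loop stops when offsets change by < 1e−12.
- CSV round-trips are exact: the writer emits shortest-round-trip float
  reprs and the reader parses with `float_precision="round_trip"` (the
  pandas fast path loses the last ulp).
- Parameter key-value output (`factorial.kv`) is full precision; display
  tables round to two decimals, matching the reference tables' precision.
- Degenerate inputs raise typed errors naming the offending row: zero
  marker, non-positive HP, mismatched balance periods, unknown group
  labels, collinear predictors (with condition number), too few records.

## Known limitations

- Single diet per trial; no nitrogen-corrected AMEn, no total-collection
  metabolizability, no external-marker variants.
- The requirement equation is valid only within the fitted weight/gain
  range; negative gains are out of scope by design.
- The published K_f = 0.96 cannot be reconstructed from the published
  regression; the package's K_f is the reciprocal-convention value.
- The degenerate group-mean reference trial cannot reproduce the published
  replicate-level regression coefficients and is not asserted to.
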