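# Methods

## Data model

The unit of replication is one sampling unit: by default a sediment core,
optionally pooled to one unit per survey date
(`pool_units_by_survey`; `unit_pooling: survey` in the CLI config). Units
carry a sampled area (m²), a cross-shore position measured seaward from
the 24-hr high-tide line, and a design label (`fixed` = constant sample
area, `proportional` = area scaled to intertidal width). A reference
sample is the set of units from one site × period; it reduces to the
incidence frequencies (R, S_obs, Y_i, Q_k) that all estimators consume.

Functional groups nest: low-dispersal wrack-associated species ⊂
wrack-associated species ⊂ all species, enforced at the trait level.
Where both sampling designs were run in one site × period, analysis keeps
the design with the larger cumulative area; an exact tie goes to the
fixed design (the design independent of beach width, generally preferred
for effort standardisation).

The wrack zone — the habitat strip relevant to wrack-associated fauna —
runs from the high-tide line down to the most seaward unit containing a
wrack-associated species. Wrack-group comparisons use wrack-zone
cumulative areas on both sides of the comparison by default
(`wrack_area_basis: total` switches to active-intertidal areas; the choice
is exposed because survey archives do not always record zone extents).

## Estimators

Interpolation uses the closed-form subset mean
S(t) = S_obs − Σ Q_k·C(R−k,t)/C(R,t). Binomial-coefficient ratios are
computed in log-gamma form, which (a) is numerically stable for large R
and (b) extends S(t) smoothly to non-integer t, needed because curves are
read at arbitrary cumulative areas. At integer t the log-gamma form is
exact (verified against exhaustive enumeration to 1e-10; see the oracle
suites).

The asymptotic estimate is Chao2 with the bias-corrected branch
Q1(Q1−1)/2 taken when duplicates are absent. Extrapolation follows the
standard incidence form and approaches S_obs + Q0̂ monotonically.

Variance: interpolated and observed points use the unconditional form
σ²(t) = Σ Q_k(1−α_kt)² − S(t)²/Ŝ, floored at zero; it treats the reference
sample as one draw from the assemblage, so the band stays open at full
effort — essential, because the two-period rule needs a non-degenerate
interval at and beyond t = R. For extrapolated points no single analytic
variance is adopted; instead a seeded species-level bootstrap (default
B = 200) resamples the estimated assemblage — detected species with
p̂_i = Y_i/R plus round(Q0̂) undetected species at p̂ = Q1/(R(Q0̂+Q1)) —
and the interval is the normal one around the point estimate. Confidence
bands are symmetric normal (z = 1.96 at the default 0.95 level) with the
lower bound floored at 0.

Effort maps to area as area = t·ā with ā the mean area per unit. With
heterogeneous unit areas this is the simplest monotone mapping; per-survey
pooling is the alternative route when survey-level areas are the
meaningful resolution.

Degenerate reference samples (no detections) yield an identically-zero
curve with zero-width bands rather than an error, so group-wise loops
never crash on an absent assemblage. Extrapolations beyond 3× the
reference effort proceed but are logged and recorded on the curve object:
out there the estimate is essentially the Chao2 asymptote, a lower bound.

## Two-period comparison

The earlier period contributes a fixed point (S_hist, A_hist): cumulative
observed richness and cumulative sampled area. The recent curve is read
at A_hist ("adjusted richness"), change is 100·(S_adj − S_hist)/S_hist
(NaN, reported as not estimable, for a zero baseline), and significance
follows the CI-position rule: S_hist above the band = significant
decrease, below = significant increase, on a bound = not significant
(conservative two-sided reading). No multiple-testing correction is
applied across sites or groups; summaries carry a standing caveat.
Stored percentages keep full precision; only human-readable summaries
round to whole percent.

This rule treats S_hist as error-free. That is defensible only when the
historical cumulative list is close to exhaustive for its assemblage —
the regime the change scenarios below are defined in — and is the main
structural limitation of the design: with a noisy historical baseline the
rule's false-positive rate rises well above nominal (we measured ~23%
under a skewed, half-sampled pool). Users with thin historical effort
should read "significant" as "outside the recent curve's band", not as a
calibrated two-sample test.

## Synthetic communities

Incidence is species-independent Bernoulli per unit — exactly the model
family the estimators assume — so passing coverage/power checks validates
the machinery, not field realism. Spatial zonation, species interactions,
temporal autocorrelation between surveys and abundance structure are all
deliberately absent; real beach data violate independence to an unknown
degree, and the checks say nothing about that.

Detection probabilities default to a geometric rank decay 0.7 → 0.03
("log-series-like": many rare, few common), which produces realistic
uniques/duplicates counts at R ≈ 40. Group structure defaults to a
wrack-associated fraction of 0.37 with 0.36 of those low-dispersal,
matching the observed composition of the study system. Change scenarios
remove a fraction of the wrack pool (survivor count rounded down), add
gained species, and/or rescale survivor detectability (clipped to (0,1]).

The two-period scenario family uses a *well-sampled* variant
(0.8 → 0.1): with R ≥ 40 units per period every species has detection
probability ≥ 0.98 per period, i.e. cumulative lists are near-complete,
which is the regime the CI-position rule presumes (above). Under these
frozen conditions the measured operating characteristics are: CI coverage
of true expected richness at t = R/2 ≈ 95% (skewed pool, 500 reps), null
false-positive rate ≈ 1–2% at R = 60 (200 reps), and detection of a 50%
wrack-pool loss as a significant decrease in ≈100% of replicates at
R = 40.

All generators are pure functions of (spec, seed); a master seed spawns
per-site child streams via hashed SeedSequence keys, so single sites
regenerate in isolation and bundles are byte-identical across reruns.

The 13-beach demonstration fixture matches the bundled effort table
exactly (per-site cumulative areas summing to 226.2 and 70.9 m²; 214 and
35 surveys), splitting each survey into 8 core-level units by default and
drawing species pools across the observed 11–64 range.

## Driver statistics

Mean grain size is the mass-weighted arithmetic mean over sieve classes
with arithmetic midpoints: open-ended top class at 1.5× the top aperture,
pan at half the smallest aperture. (Class-midpoint conventions differ
across grain-size tools; these are stated, simple choices.) Wrack cover
is the line-intercept sum per transect (m² per m of shoreline), averaged
over transects. Between-period tests use fall surveys (August–November
by default; the window is configurable to August–December) with one-way
fixed-effects ANOVA; a degenerate zero-within-variance case reports
F = ∞, p = 0 with a flag rather than failing. Richness–characteristic
relationships use simple OLS (statsmodels) with two-sided slope tests at
α = 0.05; sites missing a predictor are dropped with a warning, and
fewer than 3 remaining sites is an error.

## Numerical and interface choices

* Efforts within 1e-9 of R count as the observed point (mode
  `observed`), keeping rarefaction/extrapolation continuous at t = R.
* Bootstrap B has a floor of 50; below that the normal-SD interval is
  meaningless.
* The estimator core is exposed as the scikit-learn style
  `RarefactionExtrapolator` (`fit` on a units × species binary matrix,
  `predict` richness over an effort grid, `get_params`/`clone`
  compatible) so it composes with sklearn tooling; the module-level
  functions are the same code paths.
* All tabular I/O is plain CSV (UTF-8, header row); detection cells are
  parsed strictly as 0/1 and anything else is an error naming the cell.
* `beachdiv validate --scale` trims replicate counts for quick runs but
  leaves the pass bounds unchanged; at very small scales the
  Monte-Carlo bands (calibrated for the full replicate counts) can
  reject by chance.
* The OLS-recovery check reports a z-score (bias / Monte-Carlo SE) with
  a |z| ≤ 2 bound; under unbiasedness that bound itself fails for ~5% of
  seeds — expected behaviour of a two-sided Monte-Carlo assertion.

## Known limitations

* The bootstrap interval for extrapolated points is a pragmatic stand-in;
  no claim is made that it matches any particular legacy tool's internal
  formulas.
* Mean-unit-area scaling of the effort→area axis blurs heterogeneous
  unit areas; use survey-level pooling when that matters.
* The significance rule is not a two-sample test (see above); with weak
  historical effort its error rate is uncalibrated.
* Impact categories are user-supplied labels for stratified summaries,
  never inferred, and carry no causal claim.
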