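# beachdiv

Detecting multidecadal change in sandy-beach macroinvertebrate biodiversity
from unequal survey effort.

Long-term biodiversity comparisons on beaches rarely have matched designs:
a site may have been cored 50 times across the 1970s and only a handful of
times decades later, so raw cumulative species counts are incomparable.
`beachdiv` implements the incidence-based (sample-based)
rarefaction/extrapolation machinery that makes such comparisons honest —
species–area curves with unconditional 95% confidence limits, Chao2
asymptotic richness, area-adjusted two-period richness change with a
CI-position significance rule, functional-group decomposition
(wrack-associated and low-dispersal wrack-associated fauna), and the
accompanying environmental-driver statistics (grain size from sieve
fractions, line-intercept wrack cover, one-way ANOVA, OLS regressions).
A fully seeded synthetic-community generator provides ground-truthed data
for every stage, so the pipeline's operating characteristics (CI coverage,
false-positive rate, power) are measurable rather than assumed.

It is intended for community ecologists and monitoring programs comparing
presence/absence survey campaigns of unequal effort — and the estimator
core applies to any incidence data (the same machinery underlies
alpha-diversity rarefaction in microbiome work).

## The model

A *reference sample* is R replicated sampling units (sediment cores, or
pooled surveys) scored for presence of each species. With Q_k = number of
species found in exactly k units (Q1 "uniques", Q2 "duplicates"), expected
richness at reduced effort t ≤ R is

    S(t) = S_obs − Σ_k Q_k · C(R−k, t)/C(R, t),

the exact mean over all C(R, t) unit subsets (extended smoothly to real t
via log-gamma). Effort beyond R uses the Chao2 estimate of the undetected
complement, Q0̂ = ((R−1)/R)·Q1²/(2Q2) (bias-corrected Q1(Q1−1)/2 when
Q2 = 0):

    S(R + t*) = S_obs + Q0̂ · [1 − (1 − Q1/(Q1 + R·Q0̂))^{t*}],

rising monotonically to the asymptote Ŝ = S_obs + Q0̂. Interpolated points
carry the *unconditional* variance
σ²(t) = Σ_k Q_k(1 − α_kt)² − S(t)²/Ŝ, which does not collapse at t = R;
extrapolated points get a seeded species-level bootstrap band. Effort maps
to the area axis through the mean area per unit, and the earlier period's
cumulative richness/area point is judged against the recent curve's 95%
band: above the band = significant decline, below = significant gain.

## Worked example

One beach with a 30-species pool in which half the wrack-associated fauna
is lost between periods; 48 historical cores vs 40 recent cores of
0.05 m²:

```python
from beachdiv import (
    RarefactionExtrapolator, make_community, simulate_incidence,
    apply_change, ChangeScenario, historical_points_from_matrices,
    compare_periods, summarize_changes,
)
from beachdiv.change import ChangeConfig, format_summary
from beachdiv.synthetic import well_sampled_probs

pool = make_community("Dunes", 30, wrack_fraction=0.37,
                      detection_probs=well_sampled_probs(30), seed=5)
after = apply_change(pool, ChangeScenario(wrack_loss_fraction=0.5, seed=5))
hist = simulate_incidence(pool, R=48, unit_area=0.05, period="historical", seed=1)
recent = simulate_incidence(after, R=40, unit_area=0.05, period="recent", seed=2)

est = RarefactionExtrapolator(random_state=0).fit(recent)
print(f"recent reference sample: R={est.n_units_}, S_obs={est.s_obs_}, "
      f"Chao2 S_hat={est.s_hat_:.2f}")

traits = {**pool.traits(), **after.traits()}
points = historical_points_from_matrices({"Dunes": hist}, traits)
results = compare_periods(points, {"Dunes": recent}, traits, ChangeConfig(seed=0))
for r in results:
    print(f"{r.site} {r.group}: S_hist={r.S_hist} -> S_adj={r.S_adj:.2f} "
          f"[{r.ci_low:.2f}, {r.ci_high:.2f}]  change={r.pct_change:+.1f}% "
          f"({r.direction}{'*' if r.significant else ''})")
print(format_summary(summarize_changes(results)))
```

prints

```
recent reference sample: R=40, S_obs=24, Chao2 S_hat=25.95
Dunes overall: S_hist=30 -> S_adj=24.36 [22.15, 26.56]  change=-18.8% (decrease*)
Dunes wrack: S_hist=11 -> S_adj=5.00 [5.00, 5.00]  change=-54.5% (decrease*)
impact_category  group  n  mean_pct  incr  decr  none  signif
none  overall  1  -19%  0  1  0  1
none  wrack  1  -55%  0  1  0  1
sites where |wrack change| exceeds |overall change|: 1 (100%)
note: no multiple-testing correction is applied across sites/groups
```

The recent curve, read at the historical cumulative area (2.4 m² vs
2.0 m² sampled recently, a modest extrapolation), estimates 24.4 species
against 30 observed historically — a significant 19% overall decline —
while the wrack-associated group alone lost 55%, the engineered signal.
(The wrack band is zero-width here because every surviving wrack species
was detected repeatedly: no uniques, so the estimated assemblage has no
undetected complement.)

A shell workflow over CSV bundles is equivalent:

```bash
beachdiv simulate demo/ --seed 2          # synthetic 13-beach bundle
beachdiv curve   --bundle demo/ --out out/
beachdiv compare --bundle demo/ --out out/
beachdiv drivers --bundle demo/ --out out/
beachdiv validate --seed 1                # self-check suites
```

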