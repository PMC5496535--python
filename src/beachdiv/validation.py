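"""Self-validation suites: oracle, coverage, error-rate and recovery checks.

Each check regenerates its own synthetic data from a seed, runs the real
pipeline code, and reports the measured quantity together with the bound it
is expected to satisfy.  The interpolation check compares the closed-form
rarefaction against an independent exhaustive-enumeration oracle; the
stochastic checks measure frequentist operating characteristics (CI
coverage, null false-positive rate, power, estimator bias) under the
generator's stated scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .change import ChangeConfig, compare_periods, historical_points_from_matrices
from .drivers import ols_fit
from .estimation import rarefied_richness, richness_at_effort
from .incidence import summarize_incidence
from .synthetic import (
    ChangeScenario,
    apply_change,
    child_seed,
    default_detection_probs,
    expected_richness,
    make_community,
    simulate_incidence,
    well_sampled_probs,
)

__all__ = [
    "CheckResult",
    "brute_force_rarefaction",
    "interpolation_oracle_check",
    "coverage_check",
    "null_false_positive_check",
    "wrack_loss_power_check",
    "ols_recovery_check",
    "run_all_checks",
]


@dataclass(frozen=True)
class CheckResult:
    name: str
    value: float
    bound: str  # human-readable pass condition
    passed: bool
    n: int
    seed: int

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return f"[{status}] {self.name}: {self.value:.6g} (requires {self.bound}; n={self.n}, seed={self.seed})"


def brute_force_rarefaction(detections: np.ndarray, t: int) -> float:
    """Mean observed richness over all C(R, t) unit subsets (enumeration).

    Independent oracle for the closed-form interpolation: no incidence
    frequencies, no binomial identities — just the definition.
    """
    detections = np.asarray(detections, dtype=bool)
    R = detections.shape[1]
    vals = [
        int(detections[:, list(subset)].any(axis=1).sum())
        for subset in combinations(range(R), t)
    ]
    return float(np.mean(vals))


def interpolation_oracle_check(
    n_matrices: int = 50,
    max_R: int = 12,
    seed: int = 0,
    tol: float = 1e-10,
) -> CheckResult:
    """Closed-form rarefaction vs exhaustive subset averages.

    Random incidence matrices with R <= max_R units; every integer effort t
    is compared.  The two must agree to within ``tol``.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_matrices):
        R = int(rng.integers(2, max_R + 1))
        n_sp = int(rng.integers(1, 15))
        p = rng.uniform(0.05, 0.9, size=n_sp)
        det = rng.random((n_sp, R)) < p[:, None]
        if not det.any():
            continue
        spec_det = det[det.any(axis=1)]
        counts = spec_det.sum(axis=1).astype(int)
        Q = np.bincount(counts, minlength=R + 1)[1:]
        from .incidence import IncidenceSummary

        s = IncidenceSummary(
            R=R, S_obs=int(counts.size), Y=np.sort(counts), Q=Q.astype(int),
            A_total=float(R), a_bar=1.0,
        )
        for t in range(1, R + 1):
            worst = max(worst, abs(rarefied_richness(s, t) - brute_force_rarefaction(det, t)))
    return CheckResult(
        name="interpolation_oracle_max_abs_error",
        value=worst,
        bound=f"<= {tol:g}",
        passed=worst <= tol,
        n=n_matrices,
        seed=seed,
    )


def coverage_check(
    reps: int = 500,
    n_species: int = 40,
    R: int = 40,
    seed: int = 0,
    ci_level: float = 0.95,
) -> CheckResult:
    """Coverage of the unconditional CI at half the reference effort.

    Communities follow the skewed default pool (geometric decay 0.7->0.03);
    the target is the true expected richness of a t = R/2 sample,
    sum_i 1 - (1 - p_i)^t.  Nominal 95% coverage should land in [0.90,
    0.98] at Monte-Carlo scale.
    """
    spec = make_community(
        "cov", n_species, detection_probs=default_detection_probs(n_species),
        seed=child_seed(seed, "coverage-pool"),
    )
    t = R / 2
    truth = expected_richness(spec, t)
    hits = 0
    for rep in range(reps):
        m = simulate_incidence(spec, R, seed=child_seed(seed, "coverage", rep))
        s = summarize_incidence(m)
        pt = richness_at_effort(s, t, ci_level=ci_level)
        if pt.ci_low <= truth <= pt.ci_high:
            hits += 1
    rate = hits / reps
    return CheckResult(
        name="ci_coverage_at_half_effort",
        value=rate,
        bound="in [0.90, 0.98]",
        passed=0.90 <= rate <= 0.98,
        n=reps,
        seed=seed,
    )


def _two_period_rate(
    reps: int,
    R: int,
    seed: int,
    scenario: ChangeScenario | None,
    group: str,
    want: str,
) -> float:
    """Fraction of replicates whose site x group result matches ``want``.

    ``want`` is "significant" (any direction) or "significant_decrease".
    Runs the full pipeline: simulate both periods, derive historical
    points, compare on the recent curve.
    """
    n_species = 40
    hits = 0
    for rep in range(reps):
        spec1 = make_community(
            "sim", n_species,
            detection_probs=well_sampled_probs(n_species),
            seed=child_seed(seed, "pool", rep),
        )
        spec2 = apply_change(spec1, scenario) if scenario else spec1
        m1 = simulate_incidence(
            spec1, R, period="historical", seed=child_seed(seed, "hist", rep)
        )
        m2 = simulate_incidence(
            spec2, R, period="recent", seed=child_seed(seed, "rec", rep)
        )
        traits = {**spec1.traits(), **spec2.traits()}
        hist = historical_points_from_matrices(
            {"sim": m1}, traits, groups=(group,)
        )
        if not hist:
            continue
        res = compare_periods(
            hist, {"sim": m2}, traits,
            ChangeConfig(groups=(group,), seed=child_seed(seed, "cmp", rep)),
        )[0]
        if want == "significant":
            hits += res.significant
        else:
            hits += res.significant and res.direction == "decrease"
    return hits / reps


def null_false_positive_check(reps: int = 200, R: int = 60, seed: int = 0) -> CheckResult:
    """False-positive rate of the CI-position rule under no true change.

    Both periods draw from the same well-sampled community at equal large
    effort (R units per period); the nominal-95% rule should flag a
    significant change in at most 10% of replicates.
    """
    rate = _two_period_rate(reps, R, seed, None, "overall", "significant")
    return CheckResult(
        name="null_false_positive_rate",
        value=rate,
        bound="<= 0.10",
        passed=rate <= 0.10,
        n=reps,
        seed=seed,
    )


def wrack_loss_power_check(reps: int = 200, R: int = 40, seed: int = 0) -> CheckResult:
    """Power to flag a 50% loss of the wrack-associated pool as a decrease."""
    scenario = ChangeScenario(wrack_loss_fraction=0.5, seed=child_seed(seed, "loss"))
    rate = _two_period_rate(reps, R, seed, scenario, "wrack", "significant_decrease")
    return CheckResult(
        name="wrack_loss_detection_rate",
        value=rate,
        bound=">= 0.80",
        passed=rate >= 0.80,
        n=reps,
        seed=seed,
    )


def ols_recovery_check(
    reps: int = 200,
    n_sites: int = 13,
    beta0: float = 50.0,
    beta1: float = -60.0,
    sigma: float = 4.0,
    seed: int = 0,
) -> CheckResult:
    """Bias of the OLS slope on synthetic grain-size vs richness data.

    richness = beta0 + beta1 * grain + N(0, sigma) at n_sites beaches per
    replicate; the mean slope estimate should sit within 2 Monte-Carlo
    standard errors of the generating beta1.
    """
    rng = np.random.default_rng(seed)
    slopes = np.empty(reps)
    for rep in range(reps):
        grain = rng.uniform(0.14, 0.53, size=n_sites)
        y = beta0 + beta1 * grain + rng.normal(0, sigma, size=n_sites)
        slopes[rep] = ols_fit(grain, y).slope
    bias = float(slopes.mean() - beta1)
    mc_se = float(slopes.std(ddof=1) / np.sqrt(reps))
    z = bias / mc_se if mc_se > 0 else 0.0
    return CheckResult(
        name="ols_slope_bias_z",
        value=z,
        bound="|z| <= 2",
        passed=abs(z) <= 2,
        n=reps,
        seed=seed,
    )


def run_all_checks(seed: int = 0, scale: float = 1.0) -> list[CheckResult]:
    """Run every check, optionally at reduced replicate counts.

    ``scale`` multiplies replicate counts (minimum 50) so interactive runs
    can trade precision for speed; bounds are unchanged.
    """

    def n(x: int) -> int:
        return max(int(round(x * scale)), 50)

    return [
        interpolation_oracle_check(n_matrices=max(int(50 * scale), 5), seed=seed),
        coverage_check(reps=n(500), seed=seed),
        null_false_positive_check(reps=n(200), seed=seed),
        wrack_loss_power_check(reps=n(200), seed=seed),
        ols_recovery_check(reps=n(200), seed=seed),
    ]
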