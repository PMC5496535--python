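"""Sample-based rarefaction/extrapolation with unconditional confidence limits.

Given the incidence frequency counts of a reference sample of R units
(Q_k = number of species found in exactly k units), expected richness at a
reduced effort t <= R is

    S(t) = S_obs - sum_k Q_k * alpha_kt,   alpha_kt = C(R-k, t) / C(R, t),

the average observed richness over all C(R, t) subsets of t units.  Effort
beyond the reference sample uses the Chao2 estimate of the number of
undetected species,

    Q0_hat = (R-1)/R * Q1^2 / (2 Q2)            (Q2 > 0)
           = (R-1)/R * Q1 (Q1 - 1) / 2          (Q2 = 0, bias-corrected),

    S(R + t*) = S_obs + Q0_hat * [1 - (1 - Q1 / (Q1 + R * Q0_hat))^{t*}],

which rises monotonically from S_obs toward the asymptote
S_hat = S_obs + Q0_hat.  The *unconditional* variance of the interpolated
estimator,

    sigma^2(t) = sum_k Q_k (1 - alpha_kt)^2 - S(t)^2 / S_hat,

treats the reference sample as one draw from the assemblage, so the 95%
band does not collapse to zero at t = R; extrapolated points get their band
from a seeded species-level bootstrap.  Binomial coefficient ratios are
extended to non-integer t through log-gamma so curves can be read at
arbitrary cumulative areas.

The machinery is exposed both as plain functions over
:class:`~beachdiv.incidence.IncidenceSummary` and as the scikit-learn style
:class:`RarefactionExtrapolator`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .incidence import IncidenceMatrix, IncidenceSummary, SamplingUnit, summarize_incidence

__all__ = [
    "AsymptoticEstimate",
    "CurvePoint",
    "RarefactionCurve",
    "RarefactionExtrapolator",
    "chao2_asymptotic",
    "rarefied_richness",
    "extrapolated_richness",
    "richness_at_effort",
    "unconditional_variance",
    "bootstrap_ci",
    "build_curve",
    "effort_grid",
]

logger = logging.getLogger(__name__)

_OBS_TOL = 1e-9  # efforts within this of R count as the observed point


@dataclass(frozen=True)
class AsymptoticEstimate:
    """Chao2 asymptotic richness: S_hat = S_obs + Q0_hat."""

    S_hat: float
    Q0_hat: float
    form_used: str  # "standard" | "bias_corrected_Q2_zero"


@dataclass(frozen=True)
class CurvePoint:
    t: float
    area_m2: float
    S_t: float
    var_S: float
    ci_low: float
    ci_high: float
    mode: str  # "interpolated" | "observed" | "extrapolated"


@dataclass
class RarefactionCurve:
    """A species–area curve: richness vs effort with confidence bands."""

    summary: IncidenceSummary
    points: list[CurvePoint]
    asymptote: AsymptoticEstimate
    ci_level: float = 0.95
    warnings: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": [p.t for p in self.points],
                "area_m2": [p.area_m2 for p in self.points],
                "S": [p.S_t for p in self.points],
                "var": [p.var_S for p in self.points],
                "ci_low": [p.ci_low for p in self.points],
                "ci_high": [p.ci_high for p in self.points],
                "mode": [p.mode for p in self.points],
            }
        )


# ---------------------------------------------------------------------------
# estimator functions


def chao2_asymptotic(s: IncidenceSummary) -> AsymptoticEstimate:
    """Chao2 estimate of asymptotic richness from uniques and duplicates."""
    if s.R < 1:
        raise ValueError("chao2 requires R >= 1")
    q1, q2 = s.Q1, s.Q2
    factor = (s.R - 1) / s.R
    if q2 > 0:
        q0 = factor * q1 * q1 / (2.0 * q2)
        form = "standard"
    else:
        q0 = factor * q1 * (q1 - 1) / 2.0
        form = "bias_corrected_Q2_zero"
    return AsymptoticEstimate(S_hat=s.S_obs + q0, Q0_hat=q0, form_used=form)


def _alpha(R: int, k: np.ndarray, t: float) -> np.ndarray:
    """alpha_kt = C(R-k, t)/C(R, t), log-gamma form, valid for real t."""
    k = np.asarray(k)
    out = np.zeros(k.shape, dtype=float)
    ok = k <= R - t  # alpha is 0 once t exceeds R-k
    if np.any(ok):
        kk = k[ok]
        out[ok] = np.exp(
            gammaln(R - kk + 1)
            + gammaln(R - t + 1)
            - gammaln(R - kk - t + 1)
            - gammaln(R + 1)
        )
    return out


def rarefied_richness(s: IncidenceSummary, t: float) -> float:
    """Expected richness of a subsample of t units (0 <= t <= R).

    For integer t this equals the exhaustive mean of observed richness over
    all C(R, t) unit subsets; non-integer t follows the smooth log-gamma
    continuation of the binomial coefficients.
    """
    if t < 0 or t > s.R + _OBS_TOL:
        raise ValueError(
            f"rarefaction effort t={t} outside [0, R={s.R}]; "
            "use extrapolated_richness beyond R"
        )
    t = min(t, float(s.R))
    k = np.arange(1, s.R + 1)
    return float(s.S_obs - (s.Q * _alpha(s.R, k, t)).sum())


def extrapolated_richness(s: IncidenceSummary, t_star: float) -> float:
    """Expected richness t_star units *beyond* the reference sample."""
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    est = chao2_asymptotic(s)
    q1 = s.Q1
    if q1 == 0 or est.Q0_hat == 0:
        return float(s.S_obs)
    ratio = 1.0 - q1 / (q1 + s.R * est.Q0_hat)
    return float(s.S_obs + est.Q0_hat * (1.0 - ratio**t_star))


def unconditional_variance(s: IncidenceSummary, t: float) -> float:
    """Unconditional variance of the interpolated richness estimator.

    Treats the reference sample as a draw from the assemblage (using the
    Chao2 asymptote for the undetected complement), so the variance is
    positive even at full effort t = R.  Floored at 0.
    """
    est = chao2_asymptotic(s)
    if est.S_hat <= 0:
        return 0.0
    t = min(t, float(s.R))
    k = np.arange(1, s.R + 1)
    a = _alpha(s.R, k, t)
    s_t = s.S_obs - (s.Q * a).sum()
    var = float((s.Q * (1.0 - a) ** 2).sum() - s_t * s_t / est.S_hat)
    return max(var, 0.0)


def _bootstrap_summaries(
    s: IncidenceSummary, B: int, seed: int
) -> list[IncidenceSummary | None]:
    """B bootstrap reference samples from the estimated assemblage.

    The assemblage contains each detected species with incidence
    probability Y_i / R plus round(Q0_hat) undetected species, each with
    probability Q1 / (R * (Q0_hat + Q1)); each replicate redraws R units.
    """
    est = chao2_asymptotic(s)
    probs = list(s.Y / s.R)
    n0 = int(round(est.Q0_hat))
    if n0 > 0 and s.Q1 > 0:
        probs += [s.Q1 / (s.R * (est.Q0_hat + s.Q1))] * n0
    p = np.asarray(probs)
    if p.size == 0:
        return [None] * B
    rng = np.random.default_rng(seed)
    out: list[IncidenceSummary | None] = []
    for _ in range(B):
        det = rng.random((p.size, s.R)) < p[:, None]
        counts = det.sum(axis=1)
        out.append(_summary_from_counts(counts[counts > 0], s.R, s.A_total))
    return out


def _bootstrap_interval(
    summaries: list[IncidenceSummary | None],
    point: float,
    t: float,
    ci_level: float,
) -> tuple[float, float, float]:
    vals = np.array([richness_value(b, t) if b is not None else 0.0 for b in summaries])
    sd = float(vals.std(ddof=1))
    z = norm.ppf(0.5 + ci_level / 2.0)
    return sd * sd, max(point - z * sd, 0.0), point + z * sd


def bootstrap_ci(
    s: IncidenceSummary,
    t: float,
    B: int = 200,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Species-level bootstrap variance and normal CI at effort t.

    B reference samples of R units are regenerated from the estimated
    assemblage (see :func:`_bootstrap_summaries`) and richness recomputed
    at t; the CI is the normal interval (point estimate ± z * SD).
    """
    if B < 50:
        raise ValueError("bootstrap requires B >= 50")
    point = richness_value(s, t)
    summaries = _bootstrap_summaries(s, B, seed)
    if all(b is None for b in summaries):
        return 0.0, point, point
    return _bootstrap_interval(summaries, point, t, ci_level)


def _summary_from_counts(counts: np.ndarray, R: int, A_total: float):
    if counts.size == 0:
        return None
    Q = np.bincount(counts, minlength=R + 1)[1:]
    return IncidenceSummary(
        R=R,
        S_obs=int(counts.size),
        Y=np.sort(counts),
        Q=Q.astype(int),
        A_total=A_total,
        a_bar=A_total / R,
    )


def richness_value(s: IncidenceSummary, t: float) -> float:
    """Richness at arbitrary effort t >= 0 (rarefied or extrapolated)."""
    if t < 0:
        raise ValueError("effort must be >= 0")
    if t <= s.R + _OBS_TOL:
        return rarefied_richness(s, min(t, float(s.R)))
    return extrapolated_richness(s, t - s.R)


def richness_at_effort(
    s: IncidenceSummary,
    t: float,
    ci_level: float = 0.95,
    bootstrap_B: int = 200,
    seed: int = 0,
) -> CurvePoint:
    """Richness with CI at any effort; dispatches on t vs R.

    Interpolated/observed points (t <= R) use the analytic unconditional
    variance; extrapolated points (t > R) use the seeded species-level
    bootstrap.
    """
    if t < 0:
        raise ValueError("effort must be >= 0")
    z = norm.ppf(0.5 + ci_level / 2.0)
    if abs(t - s.R) <= _OBS_TOL:
        mode, t_eval = "observed", float(s.R)
    elif t < s.R:
        mode, t_eval = "interpolated", t
    else:
        mode, t_eval = "extrapolated", t
    if mode == "extrapolated":
        s_t = extrapolated_richness(s, t_eval - s.R)
        var, lo, hi = bootstrap_ci(s, t_eval, B=bootstrap_B, seed=seed, ci_level=ci_level)
    else:
        s_t = rarefied_richness(s, t_eval)
        var = unconditional_variance(s, t_eval)
        sd = np.sqrt(var)
        lo, hi = max(s_t - z * sd, 0.0), s_t + z * sd
    return CurvePoint(
        t=float(t),
        area_m2=float(t * s.a_bar),
        S_t=s_t,
        var_S=var,
        ci_low=lo,
        ci_high=hi,
        mode=mode,
    )


def effort_grid(R: int, t_max: float | None = None, num: int = 40) -> np.ndarray:
    """Default effort grid: integers 1..R, then extrapolation up to t_max."""
    grid = np.arange(1, R + 1, dtype=float)
    if t_max is not None and t_max > R:
        extra = np.linspace(R, t_max, num=num, endpoint=True)[1:]
        grid = np.concatenate([grid, extra])
    return grid


def build_curve(
    m: IncidenceMatrix,
    grid=None,
    ci_level: float = 0.95,
    bootstrap_B: int = 200,
    seed: int = 0,
    warn_factor: float = 3.0,
) -> RarefactionCurve:
    """Build the species–area curve for one reference sample.

    ``grid`` is an iterable of efforts in sampling units; by default the
    integers 1..R.  Extrapolation beyond ``warn_factor`` x R is permitted
    but logged (long extrapolations lean entirely on the Chao2 asymptote).
    """
    if m.n_units == 0:
        raise ValueError("cannot build a curve from an empty matrix")
    s = summarize_incidence(m)
    if grid is None:
        grid = effort_grid(s.R)
    grid = np.asarray(list(grid), dtype=float)
    curve_warnings: list[str] = []
    t_big = grid.max() if grid.size else 0.0
    if t_big > warn_factor * s.R:
        msg = (
            f"extrapolating to t={t_big:.2f}, more than {warn_factor:g}x the "
            f"reference effort R={s.R}; the estimate leans on the Chao2 asymptote"
        )
        logger.warning(msg)
        curve_warnings.append(msg)
    # one shared set of bootstrap replicates serves every extrapolated point
    shared = (
        _bootstrap_summaries(s, bootstrap_B, seed)
        if (grid > s.R + _OBS_TOL).any()
        else None
    )
    points = []
    for t in np.sort(grid):
        if shared is not None and t > s.R + _OBS_TOL:
            point = extrapolated_richness(s, t - s.R)
            if all(b is None for b in shared):
                var, lo, hi = 0.0, point, point
            else:
                var, lo, hi = _bootstrap_interval(shared, point, t, ci_level)
            points.append(
                CurvePoint(
                    t=float(t),
                    area_m2=float(t * s.a_bar),
                    S_t=point,
                    var_S=var,
                    ci_low=lo,
                    ci_high=hi,
                    mode="extrapolated",
                )
            )
        else:
            points.append(
                richness_at_effort(
                    s, t, ci_level=ci_level, bootstrap_B=bootstrap_B, seed=seed
                )
            )
    return RarefactionCurve(
        summary=s,
        points=points,
        asymptote=chao2_asymptotic(s),
        ci_level=ci_level,
        warnings=curve_warnings,
    )


# ---------------------------------------------------------------------------
# scikit-learn style estimator


class RarefactionExtrapolator(BaseEstimator):
    """Incidence-based rarefaction/extrapolation as a sklearn-style estimator.

    Fit on a binary unit-by-species matrix (rows are sampling units, columns
    species, sklearn orientation); predict expected richness at arbitrary
    sampling efforts, with unconditional confidence bands.

    Parameters
    ----------
    ci_level : float, default 0.95
        Confidence level for the bands.
    bootstrap_B : int, default 200
        Bootstrap replicates for extrapolated-point intervals.
    random_state : int, default 0
        Seed for the bootstrap.
    warn_factor : float, default 3.0
        Extrapolations beyond ``warn_factor * R`` units are logged.

    Attributes
    ----------
    summary_ : IncidenceSummary
        Incidence frequency counts of the fitted reference sample.
    s_obs_ : int
        Observed richness.
    s_hat_ : float
        Chao2 asymptotic richness.
    q0_hat_ : float
        Estimated number of undetected species.
    n_units_ : int
        Reference effort R.

    Examples
    --------
    >>> import numpy as np
    >>> X = np.array([[1, 1, 0], [1, 0, 1], [1, 0, 0], [0, 1, 0]])
    >>> est = RarefactionExtrapolator().fit(X)
    >>> est.s_obs_
    3
    >>> float(est.predict([4])[0])
    3.0
    """

    def __init__(
        self,
        ci_level: float = 0.95,
        bootstrap_B: int = 200,
        random_state: int = 0,
        warn_factor: float = 3.0,
    ):
        self.ci_level = ci_level
        self.bootstrap_B = bootstrap_B
        self.random_state = random_state
        self.warn_factor = warn_factor

    def fit(self, X, y=None, areas=None):
        """Fit on a (n_units, n_species) binary matrix or an IncidenceMatrix.

        ``areas`` gives per-unit sampled areas in m² (scalar or length
        n_units); default 1 m² per unit.
        """
        if not (0 < self.ci_level < 1):
            raise ValueError("ci_level must be in (0, 1)")
        if self.bootstrap_B < 50:
            raise ValueError("bootstrap_B must be >= 50")
        if isinstance(X, IncidenceMatrix):
            matrix = X
        else:
            X = np.asarray(X)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional (units x species)")
            if not np.isin(X, (0, 1)).all():
                raise ValueError("X must be a binary incidence matrix")
            n_units = X.shape[0]
            if areas is None:
                areas = np.ones(n_units)
            else:
                areas = np.broadcast_to(np.asarray(areas, dtype=float), (n_units,))
            units = [
                SamplingUnit(
                    unit_id=f"u{j}", site="-", period="recent", area_m2=float(areas[j])
                )
                for j in range(n_units)
            ]
            matrix = IncidenceMatrix(
                species_ids=[f"sp{i}" for i in range(X.shape[1])],
                units=units,
                detections=X.T.astype(bool),
            )
        self.matrix_ = matrix
        self.summary_ = summarize_incidence(matrix)
        asym = chao2_asymptotic(self.summary_)
        self.asymptote_ = asym
        self.s_obs_ = self.summary_.S_obs
        self.s_hat_ = asym.S_hat
        self.q0_hat_ = asym.Q0_hat
        self.n_units_ = self.summary_.R
        return self

    def predict(self, T) -> np.ndarray:
        """Expected richness at each effort in T (sampling units)."""
        check_is_fitted(self, "summary_")
        T = np.asarray(T, dtype=float).ravel()
        return np.array([richness_value(self.summary_, t) for t in T])

    def predict_interval(self, T) -> list[CurvePoint]:
        """CurvePoints (richness, variance, CI, mode) at each effort in T."""
        check_is_fitted(self, "summary_")
        T = np.asarray(T, dtype=float).ravel()
        return [
            richness_at_effort(
                self.summary_,
                t,
                ci_level=self.ci_level,
                bootstrap_B=self.bootstrap_B,
                seed=self.random_state,
            )
            for t in T
        ]

    def curve(self, grid=None) -> RarefactionCurve:
        """Full species–area curve over an effort grid (default 1..R)."""
        check_is_fitted(self, "summary_")
        return build_curve(
            self.matrix_,
            grid=grid,
            ci_level=self.ci_level,
            bootstrap_B=self.bootstrap_B,
            seed=self.random_state,
            warn_factor=self.warn_factor,
        )
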