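"""Individual-level dose-response modeling and analytic power for binary-outcome MR.

The dose-response fit remodels the case/control logistic regression on a
restricted cubic spline of the weighted genetic score (Harrell
parameterization: linear beyond the boundary knots), reports odds-ratio
curves against a reference score value, linear-trend tests on both the
exposure-allele count and the score value, and quintile-stratified odds
ratios (low = Q1, intermediate = Q2-4, high = Q5).

Analytic power uses the normal approximation for a binary outcome:

    power = Phi( |log OR| * sqrt(N R^2 K (1-K)) - z_{1-alpha/2} )

with N the total sample size, K the case fraction, R^2 the exposure variance
explained by the instrument, and OR the assumed odds ratio per exposure unit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .instruments import ScoreDefinition, weighted_score
from .sumstats_io import CohortMatrix

#: Harrell's recommended knot placement quantiles by knot count
KNOT_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


@dataclass
class PowerConfig:
    """Inputs to the analytic power approximation."""

    n_total: int
    case_fraction: float
    r2: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0,1)")
        if not 0 < self.r2 < 1:
            raise ValueError("r2 must lie in (0,1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")


@dataclass
class DoseResponseFit:
    """Spline dose-response curve, trend tests and quintile-stratified ORs."""

    knots: np.ndarray
    grid: np.ndarray
    or_curve: np.ndarray
    or_lo: np.ndarray
    or_hi: np.ndarray
    reference: float
    trend_p_alleles: float
    trend_p_score: float
    strata_or: dict[str, tuple[float, float, float]] = field(default_factory=dict)


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted-cubic-spline design columns (Harrell form, K-1 columns).

    Column 0 is x itself; columns 1..K-2 are the truncated-cubic terms
    constrained to be linear beyond the boundary knots, scaled by the squared
    boundary span for numerical balance.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    K = len(t)
    if K < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    span2 = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(K - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + pos3(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / span2)
    return np.column_stack(cols)


def trend_test(x: np.ndarray, y: np.ndarray) -> float:
    """Logistic score (Cochran-Armitage-type) test for linear trend in risk."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    xc = x - x.mean()
    U = float(xc @ (y - ybar))
    V = float(ybar * (1.0 - ybar) * (xc @ xc))
    z = U / math.sqrt(V)
    return float(max(2.0 * stats.norm.sf(abs(z)), 1e-300))


def _fit_logit(X: np.ndarray, y: np.ndarray):
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            model = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise ValueError(
            "separation detected in the logistic fit; penalized regression is "
            "out of scope — coarsen the model or enlarge the cohort") from exc
    if not model.mle_retvals.get("converged", True) or np.any(np.abs(model.params) > 50):
        raise ValueError("logistic fit did not converge (possible separation)")
    return model


def fit_dose_response(cohort: CohortMatrix, score: ScoreDefinition,
                      n_knots: int = 4, grid_size: int = 101,
                      reference: float | None = None) -> DoseResponseFit:
    """Dose-response of disease odds on the weighted score via spline logistic fit.

    Knots sit at the standard quantiles for ``n_knots`` (e.g. 0.05/0.35/0.65/
    0.95 for four); the odds-ratio curve is normalized to 1 at the reference
    score (the median by default). ``n_knots=0`` degenerates to the ordinary
    linear logistic fit. Requires at least 50 cases.
    """
    values = weighted_score(cohort, score)
    y = cohort.phenotype.astype(float)
    if y.sum() < 50:
        raise ValueError(f"need >= 50 cases for a dose-response fit, got {int(y.sum())}")

    if reference is None:
        reference = float(np.median(values))
    grid = np.linspace(values.min(), values.max(), grid_size)

    if n_knots == 0:
        knots = np.empty(0)
        B = values[:, None]
        B_grid, B_ref = grid[:, None], np.array([[reference]])
    else:
        if n_knots not in KNOT_QUANTILES:
            raise ValueError(f"supported knot counts: 0, {sorted(KNOT_QUANTILES)}")
        knots = np.quantile(values, KNOT_QUANTILES[n_knots])
        if len(np.unique(knots)) < n_knots:
            raise ValueError("degenerate score distribution: knots are not distinct")
        B = rcs_basis(values, knots)
        B_grid = rcs_basis(grid, knots)
        B_ref = rcs_basis(np.array([reference]), knots)

    X = sm.add_constant(B)
    model = _fit_logit(X, y)
    coef = model.params[1:]
    cov = np.asarray(model.cov_params())[1:, 1:]

    D = B_grid - B_ref  # intercept cancels in the OR contrast
    log_or = D @ coef
    var = np.einsum("ij,jk,ik->i", D, cov, D)
    half = stats.norm.ppf(0.975) * np.sqrt(np.maximum(var, 0.0))

    allele_count = cohort.dosages[:, [cohort.snp_ids.index(s) for s in score.snp_ids]].sum(axis=1)
    fit = DoseResponseFit(
        knots=knots,
        grid=grid,
        or_curve=np.exp(log_or),
        or_lo=np.exp(log_or - half),
        or_hi=np.exp(log_or + half),
        reference=reference,
        trend_p_alleles=trend_test(allele_count, y),
        trend_p_score=trend_test(values, y),
    )

    # quintile strata: low = Q1 (reference), intermediate = Q2-4, high = Q5
    q = np.quantile(values, [0.2, 0.8])
    stratum = np.where(values <= q[0], 0, np.where(values > q[1], 2, 1))
    dummies = np.column_stack([np.ones_like(y), (stratum == 1).astype(float),
                               (stratum == 2).astype(float)])
    strat_model = _fit_logit(dummies, y)
    params = strat_model.params
    ses = np.sqrt(np.diag(strat_model.cov_params()))
    z = stats.norm.ppf(0.975)
    fit.strata_or = {
        "low": (1.0, 1.0, 1.0),
        "intermediate": (math.exp(params[1]), math.exp(params[1] - z * ses[1]),
                         math.exp(params[1] + z * ses[1])),
        "high": (math.exp(params[2]), math.exp(params[2] - z * ses[2]),
                 math.exp(params[2] + z * ses[2])),
    }
    return fit


def mr_power(config: PowerConfig) -> float:
    """Analytic power of a two-sided test for a binary-outcome MR association."""
    ncp = abs(math.log(config.odds_ratio)) * math.sqrt(
        config.n_total * config.r2
        * config.case_fraction * (1.0 - config.case_fraction))
    z_crit = stats.norm.ppf(1.0 - config.alpha / 2.0)
    return float(stats.norm.cdf(ncp - z_crit))
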