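"""Causal-effect estimators and pleiotropy diagnostics for harmonized instruments.

Every estimator consumes an :class:`~drugtarget_mr.instruments.InstrumentSet`
oriented to exposure-lowering alleles, so pooled effects are log-odds of the
outcome per 1 mmol/L decrease in LDL cholesterol; odds ratios are exp(beta)
with delta-method CIs on the log scale.

The correlated-variant IVW uses generalized weighted least squares of the
outcome effects on the exposure effects with weight matrix
Omega^{-1}, Omega_jk = sy_j sy_k rho_jk; with identity correlation this is
exactly ratio-space inverse-variance pooling. Egger regression and the
multivariable model use the same correlation-aware GLS (identity rho recovers
the textbook estimators). The maximum-likelihood and MR-PRESSO procedures
assume independent instruments, the setting where they are applied here
(a polygenic score pruned to r^2 < 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .instruments import InstrumentSet
from .sumstats_io import LDMatrix

Z975 = stats.norm.ppf(0.975)

#: condition-number ceiling for the GLS weight matrix
OMEGA_COND_MAX = 1e8


@dataclass
class MREstimate:
    """A pooled causal estimate scaled per 1 mmol/L exposure decrease."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    Q: float = math.nan
    Q_pval: float = math.nan
    I2: float = math.nan

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")
        if not self.se > 0:
            raise ValueError("se must be > 0")
        if not math.isnan(self.Q) and self.Q < -1e-12:
            raise ValueError("Q must be non-negative")
        if not math.isnan(self.I2) and not 0 <= self.I2 <= 1:
            raise ValueError("I2 must lie in [0,1]")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class EggerResult:
    """Egger slope (causal estimate) plus the directional-pleiotropy intercept test."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float
    bootstrap: bool = False
    n_boot: int = 0
    seed: int | None = None
    slope_bootstrap_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not self.intercept_se > 0:
            raise ValueError("intercept_se must be > 0")


@dataclass
class PressoResult:
    """Global heterogeneity test, per-SNP outlier p-values, corrected estimate."""

    global_rss: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_ids: list[str]
    corrected: MREstimate
    n_sim: int
    seed: int | None


@dataclass
class TraitAssociation:
    """Pooled score effect on a candidate risk-factor trait with a pleiotropy flag."""

    estimate: MREstimate
    pleiotropy_flag: bool
    alpha: float = 0.05


def _finish(method: str, beta: float, se: float, k: int,
            Q: float = math.nan, df: int | None = None) -> MREstimate:
    pval = float(max(2.0 * stats.norm.sf(abs(beta / se)), 1e-300))
    Q_pval = math.nan
    I2 = math.nan
    if df is not None and df >= 1 and not math.isnan(Q):
        Q = max(Q, 0.0)
        Q_pval = float(stats.chi2.sf(Q, df))
        I2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    return MREstimate(method, float(beta), float(se), float(beta - Z975 * se),
                      float(beta + Z975 * se), pval, k, Q, Q_pval, I2)


def _omega(iset: InstrumentSet) -> np.ndarray:
    omega = np.outer(iset.sy, iset.sy) * iset.rho.r
    if np.linalg.cond(omega) > OMEGA_COND_MAX:
        raise np.linalg.LinAlgError(
            "GLS weight matrix is ill-conditioned (condition number > 1e8); "
            "prune the instrument panel to weaker LD")
    return omega


# ---------------------------------------------------------------------------
# ratio and IVW estimators
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sx: float, by: float, sy: float,
               second_order: bool = False) -> MREstimate:
    """Single-SNP causal estimate theta = by/bx.

    The default SE is the first-order delta approximation sy/bx; with
    ``second_order`` the term by^2 sx^2 / bx^4 is added (negligible for the
    strong instruments targeted here, F >> 10).
    """
    if bx <= 0:
        raise ValueError("bx must be > 0 (orient the instrument to the lowering allele)")
    theta = by / bx
    var = (sy / bx) ** 2
    if second_order:
        var += by**2 * sx**2 / bx**4
    return _finish("wald_ratio", theta, math.sqrt(var), k=1, Q=0.0, df=None)


def ivw(iset: InstrumentSet, effects: str = "fixed") -> MREstimate:
    """Correlation-adjusted inverse-variance weighted estimate.

    GLS of by on bx without intercept under Omega = outer(sy, sy) * rho.
    ``effects="multiplicative_random"`` inflates the SE by max(1, sqrt(Q/(k-1)))
    leaving the point estimate unchanged.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects mode {effects!r}")
    k = len(iset)
    if k == 0:
        raise ValueError("empty instrument set")
    omega = _omega(iset)
    oi_bx = np.linalg.solve(omega, iset.bx)
    denom = float(iset.bx @ oi_bx)
    beta = float(oi_bx @ iset.by) / denom
    se = denom**-0.5
    resid = iset.by - beta * iset.bx
    Q = float(resid @ np.linalg.solve(omega, resid))
    if effects == "multiplicative_random" and k >= 2:
        se *= max(1.0, math.sqrt(Q / (k - 1)))
    label = "ivw_fixed" if effects == "fixed" else "ivw_mre"
    return _finish(label, beta, se, k, Q=Q, df=k - 1 if k >= 2 else None)


# ---------------------------------------------------------------------------
# Egger regression
# ---------------------------------------------------------------------------

def _egger_fit(bx, by, omega) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([np.ones_like(bx), bx])
    oi_X = np.linalg.solve(omega, X)
    xtwx = X.T @ oi_X
    cov = np.linalg.inv(xtwx)
    coef = cov @ (oi_X.T @ by)
    return coef, cov


def egger(iset: InstrumentSet, bootstrap: dict | None = None) -> EggerResult:
    """Correlation-aware Egger regression: by on bx WITH intercept, weights Omega^{-1}.

    The slope is the pleiotropy-robust causal estimate (InSIDE assumption);
    an intercept different from zero indicates directional pleiotropy.
    Standard errors carry the multiplicative overdispersion factor
    max(1, sqrt(Q/(k-2))) and inference uses the t distribution with k-2
    degrees of freedom, so the intercept test stays near-nominal when
    balanced pleiotropy inflates residual variance beyond the outcome SEs.
    ``bootstrap={"reps": R, "seed": s}`` resamples SNPs with replacement and
    adds a percentile CI for the slope.
    """
    k = len(iset)
    if k < 3:
        raise ValueError(f"Egger regression needs k >= 3 instruments, got {k}")
    omega = _omega(iset)
    coef, cov = _egger_fit(iset.bx, iset.by, omega)
    resid = iset.by - coef[0] - coef[1] * iset.bx
    Q = float(resid @ np.linalg.solve(omega, resid))
    scale = max(1.0, math.sqrt(Q / (k - 2)))
    tdist = stats.t(df=k - 2)
    tq = float(tdist.ppf(0.975))
    slope_se = scale * math.sqrt(cov[1, 1])
    slope = MREstimate(
        "egger", float(coef[1]), slope_se,
        float(coef[1] - tq * slope_se), float(coef[1] + tq * slope_se),
        float(max(2.0 * tdist.sf(abs(coef[1]) / slope_se), 1e-300)),
        k, Q=max(Q, 0.0), Q_pval=float(stats.chi2.sf(max(Q, 0.0), k - 2)),
        I2=max(0.0, (Q - (k - 2)) / Q) if Q > 0 else 0.0,
    )
    intercept_se = scale * math.sqrt(cov[0, 0])
    result = EggerResult(
        slope=slope,
        intercept=float(coef[0]),
        intercept_se=intercept_se,
        intercept_pval=float(2.0 * tdist.sf(abs(coef[0]) / intercept_se)),
    )
    if bootstrap is not None:
        reps, seed = int(bootstrap["reps"]), bootstrap.get("seed")
        rng = np.random.default_rng(seed)
        slopes = []
        while len(slopes) < reps:
            idx = rng.integers(0, k, size=k)
            if len(set(iset.bx[idx])) < 2:
                continue  # degenerate resample cannot identify a slope
            sub_omega = (np.outer(iset.sy[idx], iset.sy[idx])
                         * iset.rho.r[np.ix_(idx, idx)])
            sub_omega += 1e-12 * np.eye(k)  # duplicated SNPs make Omega singular
            c, _ = _egger_fit(iset.bx[idx], iset.by[idx], sub_omega)
            slopes.append(c[1])
        lo, hi = np.percentile(slopes, [2.5, 97.5])
        result.bootstrap = True
        result.n_boot = reps
        result.seed = seed
        result.slope_bootstrap_ci = (float(lo), float(hi))
    return result


# ---------------------------------------------------------------------------
# weighted median
# ---------------------------------------------------------------------------

def _weighted_median(theta: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(theta)
    t, w = theta[order], weights[order] / weights.sum()
    p = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, p, t))


def weighted_median(iset: InstrumentSet, n_boot: int = 5000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median causal estimate (consistent if >= 50% of weight is valid).

    Per-SNP ratios are ordered and the inverse-variance-weighted cumulative
    distribution is interpolated at 0.5; the SE comes from a parametric
    bootstrap of (bx, by) around their observed values.
    """
    if len(iset) < 3:
        raise ValueError(f"weighted median needs k >= 3 instruments, got {len(iset)}")
    theta, theta_se = iset.wald
    w = theta_se**-2
    est = _weighted_median(theta, w)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = rng.normal(iset.bx, iset.sx)
        by_b = rng.normal(iset.by, iset.sy)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_b = by_b / bx_b
            w_b = (iset.sy / np.abs(bx_b)) ** -2
        boots[b] = _weighted_median(t_b, w_b)
    se = float(boots.std(ddof=1))
    return _finish("weighted_median", est, se, len(iset))


# ---------------------------------------------------------------------------
# profile maximum likelihood
# ---------------------------------------------------------------------------

def max_likelihood(iset: InstrumentSet) -> MREstimate:
    """Profile-likelihood causal estimate under bivariate-normal measurement error.

    Observed (bx_j, by_j) are modeled as normal around (xi_j, beta * xi_j)
    with SDs (sx_j, sy_j); the nuisance xi_j are profiled out analytically,
    leaving l(beta) = -1/2 sum (by_j - beta bx_j)^2 / (sy_j^2 + beta^2 sx_j^2).
    The SE comes from the observed (profile) information. Reduces to IVW as
    sx -> 0; assumes independent instruments.
    """
    if len(iset) == 0:
        raise ValueError("empty instrument set")
    bx, sx, by, sy = iset.bx, iset.sx, iset.by, iset.sy

    def nll(beta: float) -> float:
        return float(0.5 * np.sum((by - beta * bx) ** 2 / (sy**2 + beta**2 * sx**2)))

    start = ivw(InstrumentSet(iset.snp_ids, bx, sx, by, sy,
                              LDMatrix.identity(iset.snp_ids))).beta
    spans = [1.0, 5.0, 25.0]
    res = None
    for span in spans:
        res = optimize.minimize_scalar(
            nll, bracket=(start - span, start, start + span), method="brent",
            options={"xtol": 1e-10})
        if res.success:
            break
    if res is None or not res.success:
        raise RuntimeError(f"profile-likelihood optimizer failed: {res}")
    beta = float(res.x)
    h = 1e-4 * (1.0 + abs(beta))
    info = (nll(beta + h) - 2.0 * nll(beta) + nll(beta - h)) / h**2
    if info <= 0:
        raise RuntimeError("non-positive observed information at the optimum")
    return _finish("max_likelihood", beta, info**-0.5, len(iset))


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out independence-IVW slopes, one per left-out SNP (vectorized)."""
    s_xy = np.sum(w * bx * by, axis=-1, keepdims=True)
    s_xx = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (s_xy - w * bx * by) / (s_xx - w * bx * bx)


def mr_presso(iset: InstrumentSet, n_sim: int = 5000, seed: int | None = None,
              outlier_alpha: float | None = None) -> PressoResult:
    """MR-PRESSO: global residual test, per-SNP outliers, outlier-corrected IVW.

    The observed statistic is the weighted leave-one-out residual sum of
    squares; its null distribution is simulated by drawing (bx*, by*) from the
    fitted no-pleiotropy model. Per-SNP outlier p-values are Bonferroni
    thresholded at ``outlier_alpha`` (default 0.05/k); the corrected estimate
    is IVW on the surviving SNPs. Deterministic given the seed.
    """
    k = len(iset)
    if k < 4:
        raise ValueError(f"MR-PRESSO needs k >= 4 instruments, got {k}")
    if outlier_alpha is None:
        outlier_alpha = 0.05 / k
    bx, sx, by, sy = iset.bx, iset.sx, iset.by, iset.sy
    w = sy**-2

    beta_loo = _loo_slopes(bx, by, w)
    resid_obs = by - beta_loo * bx
    rss_obs = float(np.sum(w * resid_obs**2))

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(bx_star * beta_loo, sy, size=(n_sim, k))
    beta_loo_star = _loo_slopes(bx_star, by_star, w)
    resid_star = by_star - beta_loo_star * bx_star
    rss_star = np.sum(w * resid_star**2, axis=1)

    global_pval = float((1 + np.sum(rss_star >= rss_obs)) / (n_sim + 1))
    per_snp = (1 + np.sum(resid_star**2 >= resid_obs**2, axis=0)) / (n_sim + 1)
    outlier_pvals = {s: float(p) for s, p in zip(iset.snp_ids, per_snp)}
    outlier_ids = [s for s, p in outlier_pvals.items() if p < outlier_alpha]

    keep = [s for s in iset.snp_ids if s not in outlier_ids]
    if not keep:
        raise ValueError("all SNPs flagged as outliers; no valid instruments remain")
    corrected = ivw(iset.subset(keep))
    return PressoResult(rss_obs, global_pval, outlier_pvals, outlier_ids,
                        corrected, n_sim, seed)


# ---------------------------------------------------------------------------
# multivariable GLS and risk-factor screening
# ---------------------------------------------------------------------------

def multivariable_ivw(bx_matrix: np.ndarray, sy: np.ndarray, by: np.ndarray,
                      rho: LDMatrix | np.ndarray | None = None,
                      labels: list[str] | None = None) -> list[MREstimate]:
    """Joint GLS of by on several exposures' SNP effects (no intercept).

    Column 0 is conventionally the primary exposure; its estimate is the
    pleiotropy-adjusted causal effect, with one MREstimate per column.
    """
    B = np.asarray(bx_matrix, dtype=float)
    k, q = B.shape
    if not k > q or q < 2:
        raise ValueError(f"need k > q >= 2 (got k={k}, q={q})")
    # an all-zero covariate column is a nested model: it contributes nothing
    # and gets a null estimate, rather than failing the rank check
    nonzero = [j for j in range(q) if np.any(B[:, j] != 0.0)]
    Bz = B[:, nonzero]
    if np.linalg.matrix_rank(Bz) < Bz.shape[1]:
        raise np.linalg.LinAlgError("exposure-effect matrix is rank-deficient")
    sy = np.asarray(sy, dtype=float)
    by = np.asarray(by, dtype=float)
    r = rho.r if isinstance(rho, LDMatrix) else (np.eye(k) if rho is None else np.asarray(rho))
    omega = np.outer(sy, sy) * r
    oi_B = np.linalg.solve(omega, Bz)
    cov = np.linalg.inv(Bz.T @ oi_B)
    coef = cov @ (oi_B.T @ by)
    resid = by - Bz @ coef
    Q = float(resid @ np.linalg.solve(omega, resid))
    labels = labels or [f"exposure{j}" for j in range(q)]
    estimates: list[MREstimate] = []
    df = k - Bz.shape[1]
    pos = {j: i for i, j in enumerate(nonzero)}
    for j in range(q):
        if j in pos:
            i = pos[j]
            estimates.append(_finish(f"mvmr[{labels[j]}]", coef[i],
                                     math.sqrt(cov[i, i]), k, Q=Q, df=df))
        else:
            estimates.append(_finish(f"mvmr[{labels[j]}]", 0.0, math.inf, k,
                                     Q=Q, df=df))
    return estimates


def score_trait_association(iset: InstrumentSet, alpha: float = 0.05) -> TraitAssociation:
    """Pooled effect of a score on a candidate risk factor, per 1 mmol/L.

    A strictly sub-``alpha`` p-value flags the trait as a horizontal-pleiotropy
    pathway, feeding the covariate list of the multivariable model.
    """
    est = ivw(iset)
    return TraitAssociation(estimate=est, pleiotropy_flag=bool(est.pval < alpha),
                            alpha=alpha)
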