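"""Synthetic cohorts and two-sample GWAS with known causal architecture.

The generator emulates the study design the pipeline targets: an LDL-like
quantitative exposure driven by a handful of LD-correlated cis variants with
per-allele effects of roughly 0.03-0.08 mmol/L, and a case-control binary
outcome generated from a logistic model whose linear predictor contains the
causal exposure effect plus optional direct (pleiotropic) SNP effects.
Dosages come from a Gaussian-copula construction: two latent multivariate
normal haplotypes are thresholded at each allele frequency and summed, with
the latent correlation calibrated numerically so the dosage correlation hits
the target LD. Summary statistics are per-SNP univariate regressions, linear
for the exposure and logistic maximum likelihood for the outcome, matching
the scales of the GWAS inputs the estimators expect.

One global seed expands into per-component seeds through a fixed
``numpy.random.SeedSequence`` spawning rule, so every stochastic output is
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .sumstats_io import CohortMatrix, LDMatrix, VariantAssociation

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_ld_dosages",
    "simulate_two_sample_gwas",
    "simulate_cohort",
    "linear_gwas",
    "logistic_gwas",
]

# Default per-allele exposure effects (mmol/L) mirror the cis-score magnitudes
# of the packaged HMGCR variant table; the residual exposure SD of 0.85 mmol/L
# is a typical population SD for LDL cholesterol.
_DEFAULT_BETAS = (-0.073, -0.057, -0.042, -0.035)
_DEFAULT_MAF = (0.35, 0.12, 0.22, 0.16)


@dataclass
class SimulationConfig:
    """Causal architecture and cohort design for one simulated study.

    ``causal_beta`` is the outcome log-odds per 1 mmol/L exposure *increase*;
    the default corresponds to an odds ratio of 0.57 per 1 mmol/L decrease.
    ``baseline_prevalence`` is the marginal disease prevalence of the simulated
    population (the genetic contribution to the linear predictor is centered
    at its expectation). The default outcome cohort of 4,913 at prevalence
    0.101 emulates a 497-case / 4,416-control case-control collection.
    """

    m_snps: int = 4
    maf: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_MAF))
    ld_r: LDMatrix | None = None
    exposure_betas: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_BETAS))
    exposure_noise_sd: float = 0.85
    causal_beta: float = -math.log(0.57)
    direct_effects: np.ndarray | None = None
    baseline_prevalence: float = 0.101
    n_exposure_cohort: int = 50_000
    n_outcome_cohort: int = 4_913
    n_cases: int | None = None
    n_controls: int | None = None
    seed: int = 0
    snp_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        self.exposure_betas = np.asarray(self.exposure_betas, dtype=float)
        if self.direct_effects is None:
            self.direct_effects = np.zeros(self.m_snps)
        self.direct_effects = np.asarray(self.direct_effects, dtype=float)
        if self.snp_ids is None:
            self.snp_ids = [f"snp{i + 1:03d}" for i in range(self.m_snps)]
        if self.ld_r is None:
            self.ld_r = LDMatrix.identity(self.snp_ids)
        for name, arr in (("maf", self.maf), ("exposure_betas", self.exposure_betas),
                          ("direct_effects", self.direct_effects)):
            if len(arr) != self.m_snps:
                raise ValueError(f"{name} has length {len(arr)}, expected m_snps={self.m_snps}")
        if len(self.ld_r) != self.m_snps:
            raise ValueError("ld_r panel size does not match m_snps")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if not 0 < self.baseline_prevalence < 1:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if self.exposure_noise_sd <= 0:
            raise ValueError("exposure_noise_sd must be > 0")
        if (self.n_cases is None) != (self.n_controls is None):
            raise ValueError("set both n_cases and n_controls, or neither")


@dataclass
class SimulatedStudy:
    """Two-sample summary statistics plus the individual-level outcome cohort."""

    exposure_sumstats: list[VariantAssociation]
    outcome_sumstats: list[VariantAssociation]
    cohort: CohortMatrix
    truth: SimulationConfig


# ---------------------------------------------------------------------------
# Gaussian-copula dosages
# ---------------------------------------------------------------------------

def _bvn_cdf(t1: float, t2: float, rho: float) -> float:
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(stats.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([t1, t2]))


def _latent_corr(target: float, p1: float, p2: float) -> float:
    """Latent normal correlation giving dosage (= indicator) correlation ``target``."""
    if target == 0.0:
        return 0.0
    t1, t2 = stats.norm.ppf(p1), stats.norm.ppf(p2)
    denom = math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))

    def gap(rho: float) -> float:
        return (_bvn_cdf(t1, t2, rho) - p1 * p2) / denom - target

    lo, hi = -0.9999, 0.9999
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValueError(
            f"target dosage correlation {target:.3f} unattainable for "
            f"allele frequencies ({p1:.3f}, {p2:.3f})"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _nearest_psd(a: np.ndarray, tol: float = 0.1) -> np.ndarray:
    """Eigenvalue-clipped correlation matrix; errors if the repair moves it too far."""
    vals, vecs = np.linalg.eigh(a)
    if vals.min() >= -1e-10:
        return a
    repaired = (vecs * np.maximum(vals, 1e-10)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    if np.max(np.abs(repaired - a)) > tol:
        raise ValueError("LD matrix is not positive semi-definite within repair tolerance")
    return repaired


def simulate_ld_dosages(n: int, maf: np.ndarray, ld_r: LDMatrix,
                        seed: int | np.random.SeedSequence) -> np.ndarray:
    """Draw an n x m matrix of {0,1,2} dosages with target MAF and dosage LD.

    Two latent haplotypes per individual are drawn from a multivariate normal
    whose correlation is calibrated pairwise so thresholded-indicator (hence
    dosage) correlations hit ``ld_r``; a SNP with maf 0 yields an all-zero
    column. Deterministic given the seed.
    """
    maf = np.asarray(maf, dtype=float)
    m = len(maf)
    if len(ld_r) != m:
        raise ValueError("ld_r panel size does not match maf length")
    latent = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            target = ld_r.r[i, j]
            if target != 0.0 and maf[i] > 0 and maf[j] > 0:
                latent[i, j] = latent[j, i] = _latent_corr(target, maf[i], maf[j])
    latent = _nearest_psd(latent)
    identity = np.array_equal(latent, np.eye(m))
    chol = None if identity else np.linalg.cholesky(latent + 1e-10 * np.eye(m))

    rng = np.random.default_rng(seed)
    thresholds = stats.norm.ppf(maf)  # maf 0 -> -inf -> indicator never fires
    dosages = np.zeros((n, m))
    for _ in range(2):  # two independent haplotypes
        z = rng.standard_normal((n, m))
        if chol is not None:
            z = z @ chol.T
        dosages += (z < thresholds).astype(float)
    return dosages


# ---------------------------------------------------------------------------
# per-SNP association scans
# ---------------------------------------------------------------------------

def linear_gwas(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple linear regression of y on each SNP: (beta, se, pval)."""
    n = len(y)
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xc.T @ yc / sxx
        sse = np.maximum(yc @ yc - beta**2 * sxx, 0.0)
        se = np.sqrt(sse / (n - 2) / sxx)
    pval = 2.0 * stats.t.sf(np.abs(beta / se), df=n - 2)
    return beta, se, np.maximum(pval, 1e-300)


def logistic_gwas(G: np.ndarray, y: np.ndarray, max_iter: int = 40,
                  tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column logistic regression MLE (intercept + dosage), vectorized Newton.

    Returns per-SNP (log-odds beta, se, Wald p). Fits all columns
    simultaneously; each column's 2-parameter Newton system is solved in
    closed form per iteration.
    """
    n, m = G.shape
    ybar = y.mean()
    a = np.full(m, logit(ybar))
    b = np.zeros(m)
    yy = y[:, None].astype(float)
    for _ in range(max_iter):
        p = expit(a + G * b)
        w = p * (1.0 - p)
        r = yy - p
        g1 = r.sum(axis=0)
        g2 = np.einsum("ij,ij->j", r, G)
        h11 = w.sum(axis=0)
        h12 = np.einsum("ij,ij->j", w, G)
        h22 = np.einsum("ij,ij,ij->j", w, G, G)
        det = h11 * h22 - h12**2
        da = (h22 * g1 - h12 * g2) / det
        db = (h11 * g2 - h12 * g1) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    se = np.sqrt(h11 / det)
    pval = 2.0 * stats.norm.sf(np.abs(b / se))
    return b, se, np.maximum(pval, 1e-300)


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------

def _spawn(config: SimulationConfig) -> dict[str, np.random.SeedSequence]:
    """Fixed seed-splitting rule: one child stream per stochastic component."""
    kids = np.random.SeedSequence(config.seed).spawn(4)
    return {
        "exposure_dosages": kids[0],
        "exposure_noise": kids[1],
        "outcome_dosages": kids[2],
        "outcome_phenotype": kids[3],
    }


def _records(config: SimulationConfig, beta, se, pval, eaf, n,
             trait_kind: str) -> list[VariantAssociation]:
    return [
        VariantAssociation(
            snp_id=config.snp_ids[j],
            chrom="1",
            pos=1_000_000 + 10_000 * j,
            effect_allele="A",
            other_allele="G",
            eaf=float(eaf[j]),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pval[j]),
            n=int(n),
            trait_kind=trait_kind,
        )
        for j in range(config.m_snps)
    ]


def _draw_outcome(config: SimulationConfig,
                  seeds: dict[str, np.random.SeedSequence]) -> CohortMatrix:
    """Individual-level outcome cohort under the logistic disease model.

    Prospective sampling of ``n_outcome_cohort`` individuals at the baseline
    prevalence by default; when ``n_cases``/``n_controls`` are set, a large
    population is simulated at that prevalence and the designed numbers of
    cases and controls are sampled from it (study-base sampling).
    """
    k = config.baseline_prevalence
    # center the genetic contribution so the marginal prevalence is K
    mean_exposure = float(2 * config.maf @ config.exposure_betas)
    mean_direct = float(2 * config.maf @ config.direct_effects)
    intercept = logit(k) - config.causal_beta * mean_exposure - mean_direct

    rng_pheno = np.random.default_rng(seeds["outcome_phenotype"])
    dosage_seeds = seeds["outcome_dosages"].spawn(64)

    def draw(n: int, chunk_idx: int) -> tuple[np.ndarray, np.ndarray]:
        G = simulate_ld_dosages(n, config.maf, config.ld_r, dosage_seeds[chunk_idx])
        exposure = G @ config.exposure_betas + rng_pheno.normal(
            0.0, config.exposure_noise_sd, size=n)
        eta = intercept + config.causal_beta * exposure + G @ config.direct_effects
        y = rng_pheno.random(n) < expit(eta)
        return G, y.astype(int)

    if config.n_cases is None:
        G, y = draw(config.n_outcome_cohort, 0)
    else:
        need_cases, need_controls = config.n_cases, config.n_controls
        chunk = int(1.3 * max(need_cases / k, need_controls / (1 - k))) + 1000
        got_cases = got_controls = 0
        parts_G, parts_y = [], []
        for idx in range(64):
            Gc, yc = draw(chunk, idx)
            parts_G.append(Gc)
            parts_y.append(yc)
            got_cases += int(yc.sum())
            got_controls += int(len(yc) - yc.sum())
            if got_cases >= need_cases and got_controls >= need_controls:
                break
        else:
            raise RuntimeError("failed to realize the designed case/control counts")
        G_all = np.vstack(parts_G)
        y_all = np.concatenate(parts_y)
        case_idx = np.flatnonzero(y_all == 1)[:need_cases]
        ctrl_idx = np.flatnonzero(y_all == 0)[:need_controls]
        keep = np.concatenate([case_idx, ctrl_idx])
        keep = keep[rng_pheno.permutation(len(keep))]
        G, y = G_all[keep], y_all[keep]

    if y.sum() < 10 or (len(y) - y.sum()) < 10:
        raise ValueError(
            f"realized only {int(y.sum())} cases / {int(len(y) - y.sum())} controls; "
            "increase n_outcome_cohort or the baseline prevalence"
        )
    sample_ids = [f"id{i + 1:06d}" for i in range(len(y))]
    return CohortMatrix(G, y, list(config.snp_ids), sample_ids)


def simulate_cohort(config: SimulationConfig) -> CohortMatrix:
    """The individual-level outcome cohort alone (same seed path as the study)."""
    return _draw_outcome(config, _spawn(config))


def simulate_two_sample_gwas(config: SimulationConfig) -> SimulatedStudy:
    """Simulate exposure and outcome cohorts and their per-SNP summary statistics.

    The exposure cohort yields per-SNP linear-regression betas (mmol/L per
    allele); the outcome cohort yields per-SNP logistic-regression log-odds.
    The truth (the config) is retained for oracle checks.
    """
    seeds = _spawn(config)

    X = simulate_ld_dosages(config.n_exposure_cohort, config.maf, config.ld_r,
                            seeds["exposure_dosages"])
    rng = np.random.default_rng(seeds["exposure_noise"])
    exposure = X @ config.exposure_betas + rng.normal(
        0.0, config.exposure_noise_sd, size=config.n_exposure_cohort)
    eb, es, ep = linear_gwas(X, exposure)
    exposure_records = _records(config, eb, es, ep, X.mean(axis=0) / 2.0,
                                config.n_exposure_cohort, "quantitative")

    cohort = _draw_outcome(config, seeds)
    ob, os_, op = logistic_gwas(cohort.dosages, cohort.phenotype)
    outcome_records = _records(config, ob, os_, op, cohort.dosages.mean(axis=0) / 2.0,
                               len(cohort.phenotype), "binary")

    return SimulatedStudy(exposure_records, outcome_records, cohort, config)
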