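"""End-to-end orchestration of the drug-target MR analysis plan.

For every genetic score the pipeline (1) harmonizes each outcome cohort's
per-SNP effects to the score's exposure-lowering alleles, (2) pools them
across cohorts by fixed-effect meta-analysis, (3) estimates the causal
effect with the correlation-adjusted IVW model — fixed effects for cis
drug-target scores, multiplicative random effects for the polygenic score —
and (4) runs the requested sensitivity models. Primary-score significance
uses alpha_primary; secondary scores use the Bonferroni-corrected
alpha_primary / (number of secondary tests). Subgroup runs filter outcome
cohorts by ancestry label, and single-SNP refits re-enter the same path with
k = 1. Failures in any stage are recorded per score and stage; the other
scores' results are still emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mr_core
from .instruments import InstrumentSet, ScoreDefinition, harmonize, meta_analyze_fixed
from .sumstats_io import LDMatrix, VariantAssociation, config_hash
from .mr_core import MREstimate

logger = logging.getLogger("drugtarget_mr")


@dataclass
class OutcomeCohort:
    """One outcome GWAS: per-SNP log-odds records plus an ancestry label."""

    label: str
    ancestry: str
    records: list[VariantAssociation]


@dataclass
class AnalysisPlan:
    """Which scores to run, how to judge significance, and which sensitivity models."""

    scores: dict[str, ScoreDefinition]
    primary: str
    secondary: list[str]
    alpha_primary: float = 0.05
    sensitivity: dict = field(default_factory=lambda: {
        "egger": False, "median": False, "ml": False, "presso": False,
    })
    subgroup_ancestries: list[str] = field(default_factory=list)
    single_snp_refits: list[str] = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.primary in self.secondary:
            raise ValueError("the primary score cannot also be secondary")
        unknown = [s for s in [self.primary, *self.secondary] if s not in self.scores]
        if unknown:
            raise ValueError(f"plan references undefined score(s): {unknown}")

    @property
    def alpha_secondary(self) -> float:
        return self.alpha_primary / max(1, len(self.secondary))


@dataclass
class ReportBundle:
    """Machine-readable pipeline output: tidy tables plus a run log."""

    results: pd.DataFrame
    sensitivity: pd.DataFrame
    persnp: pd.DataFrame
    log: list[str]
    failures: list[dict]

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(out / "results.tsv", sep="\t", index=False,
                            float_format="%.6g")
        self.sensitivity.to_csv(out / "sensitivity.tsv", sep="\t", index=False,
                                float_format="%.6g")
        self.persnp.to_csv(out / "persnp.tsv", sep="\t", index=False,
                           float_format="%.6g")
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def pooled_outcome_records(score: ScoreDefinition,
                           exposure: list[VariantAssociation],
                           cohorts: list[OutcomeCohort]) -> list[VariantAssociation]:
    """Per-SNP fixed-effect meta-analysis of outcome effects across cohorts.

    Each cohort's records are first oriented to the score's counted
    (exposure-lowering) alleles via harmonization; SNPs present in at least
    one cohort are pooled.
    """
    oriented: dict[str, list[VariantAssociation]] = {s: [] for s in score.snp_ids}
    for cohort in cohorts:
        try:
            iset = harmonize(score, exposure, cohort.records)
        except KeyError:
            # cohort covers only part of the panel: harmonize SNP by SNP
            iset = None
        if iset is not None:
            per_cohort = {s: i for i, s in enumerate(iset.snp_ids)}
        for j, snp in enumerate(score.snp_ids):
            rec = None
            if iset is not None and snp in per_cohort:
                i = per_cohort[snp]
                exp_rec = next(e for e in exposure if e.snp_id == snp)
                rec = VariantAssociation(
                    snp_id=snp, chrom=exp_rec.chrom, pos=exp_rec.pos,
                    effect_allele=score.effect_alleles[j],
                    other_allele=score.other_alleles[j],
                    eaf=None, beta=float(iset.by[i]), se=float(iset.sy[i]),
                    pval=float(max(2 * _norm_sf(abs(iset.by[i] / iset.sy[i])), 1e-300)),
                    n=None, trait_kind="binary",
                )
            elif iset is None:
                sub = subset_score(score, [snp])
                try:
                    one = harmonize(sub, exposure, cohort.records)
                except (KeyError, ValueError):
                    continue
                exp_rec = next(e for e in exposure if e.snp_id == snp)
                rec = VariantAssociation(
                    snp_id=snp, chrom=exp_rec.chrom, pos=exp_rec.pos,
                    effect_allele=sub.effect_alleles[0],
                    other_allele=sub.other_alleles[0],
                    eaf=None, beta=float(one.by[0]), se=float(one.sy[0]),
                    pval=float(max(2 * _norm_sf(abs(one.by[0] / one.sy[0])), 1e-300)),
                    n=None, trait_kind="binary",
                )
            if rec is not None:
                oriented[snp].append(rec)
    return [meta_analyze_fixed(recs) for recs in oriented.values() if recs]


def _norm_sf(z: float) -> float:
    from scipy import stats

    return float(stats.norm.sf(z))


def subset_score(score: ScoreDefinition, snp_ids: list[str]) -> ScoreDefinition:
    idx = [score.snp_ids.index(s) for s in snp_ids]
    return ScoreDefinition(
        name=f"{score.name}[{','.join(snp_ids)}]" if len(snp_ids) < len(score) else score.name,
        snp_ids=[score.snp_ids[i] for i in idx],
        weights=score.weights[idx],
        effect_alleles=[score.effect_alleles[i] for i in idx],
        other_alleles=[score.other_alleles[i] for i in idx],
        region=score.region,
    )


def build_instrument_set(score: ScoreDefinition,
                         exposure: list[VariantAssociation],
                         cohorts: list[OutcomeCohort],
                         ld: LDMatrix | None = None) -> InstrumentSet:
    """Meta-analyze the cohorts and harmonize against the exposure records."""
    pooled = pooled_outcome_records(score, exposure, cohorts)
    return harmonize(score, exposure, pooled, ld=ld)


def _estimate_row(score_name: str, analysis: str, est: MREstimate,
                  alpha: float | None) -> dict:
    row = {
        "score": score_name,
        "analysis": analysis,
        "method": est.method,
        "k": est.k,
        "beta": est.beta,
        "se": est.se,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "odds_ratio": est.odds_ratio,
        "or_low": est.or_ci[0],
        "or_high": est.or_ci[1],
        "pval": est.pval,
        "Q": est.Q,
        "Q_pval": est.Q_pval,
        "I2": est.I2,
    }
    if alpha is not None:
        row["alpha"] = alpha
        row["significant"] = bool(est.pval < alpha)
    return row


def run_pipeline(plan: AnalysisPlan,
                 exposure: list[VariantAssociation],
                 cohorts: list[OutcomeCohort],
                 ld: LDMatrix | None = None) -> ReportBundle:
    """Execute the full analysis plan; see the module docstring for the stages."""
    log: list[str] = []
    failures: list[dict] = []
    results_rows: list[dict] = []
    sens_rows: list[dict] = []
    persnp_rows: list[dict] = []

    plan_fingerprint = config_hash({
        "scores": {n: list(s.snp_ids) for n, s in plan.scores.items()},
        "primary": plan.primary,
        "secondary": plan.secondary,
        "alpha_primary": plan.alpha_primary,
        "seeds": {k: int(v) for k, v in plan.seeds.items()},
    })
    log.append(f"plan hash: {plan_fingerprint}")
    for name, seed in sorted(plan.seeds.items()):
        log.append(f"seed[{name}] = {seed}")

    score_names = [plan.primary, *plan.secondary,
                   *[n for n in plan.scores if n not in (plan.primary, *plan.secondary)]]

    for score_name in score_names:
        score = plan.scores[score_name]
        analysis = ("primary" if score_name == plan.primary
                    else "secondary" if score_name in plan.secondary else "other")
        alpha = (plan.alpha_primary if analysis == "primary"
                 else plan.alpha_secondary if analysis == "secondary" else None)
        is_polygenic = score.region is None
        effects = "multiplicative_random" if is_polygenic else "fixed"

        try:
            iset = build_instrument_set(score, exposure, cohorts, ld)
        except Exception as exc:
            failures.append({"score": score_name, "stage": "harmonize", "error": str(exc)})
            log.append(f"{score_name}: harmonize FAILED: {exc}")
            continue

        try:
            est = mr_core.ivw(iset, effects=effects)
        except Exception as exc:
            failures.append({"score": score_name, "stage": "ivw", "error": str(exc)})
            log.append(f"{score_name}: ivw FAILED: {exc}")
            continue
        results_rows.append(_estimate_row(score_name, analysis, est, alpha))
        log.append(f"{score_name}: {est.method} OR={est.odds_ratio:.3f} "
                   f"({est.or_ci[0]:.3f}-{est.or_ci[1]:.3f}) p={est.pval:.3g}")

        theta, theta_se = iset.wald
        for s, t, t_se in zip(iset.snp_ids, theta, theta_se):
            persnp_rows.append({
                "score": score_name, "snp": s, "theta": float(t), "se": float(t_se),
                "or": float(np.exp(t)),
                "or_low": float(np.exp(t - 1.959964 * t_se)),
                "or_high": float(np.exp(t + 1.959964 * t_se)),
            })

        # sensitivity models on request, each guarded per stage
        sens = plan.sensitivity
        seed = plan.seeds.get(score_name, plan.seeds.get("global"))

        def _try(stage: str, fn):
            try:
                return fn()
            except Exception as exc:
                failures.append({"score": score_name, "stage": stage, "error": str(exc)})
                log.append(f"{score_name}: {stage} FAILED: {exc}")
                return None

        if sens.get("egger"):
            egg = _try("egger", lambda: mr_core.egger(iset))
            if egg is not None:
                row = _estimate_row(score_name, "sensitivity", egg.slope, None)
                row.update(intercept=egg.intercept, intercept_se=egg.intercept_se,
                           intercept_pval=egg.intercept_pval)
                sens_rows.append(row)
        if sens.get("median"):
            med = _try("weighted_median",
                       lambda: mr_core.weighted_median(iset, n_boot=sens.get("median_boot", 2000),
                                                       seed=seed))
            if med is not None:
                sens_rows.append(_estimate_row(score_name, "sensitivity", med, None))
        if sens.get("ml"):
            ml = _try("max_likelihood", lambda: mr_core.max_likelihood(iset))
            if ml is not None:
                sens_rows.append(_estimate_row(score_name, "sensitivity", ml, None))
        if sens.get("presso"):
            pres = _try("mr_presso",
                        lambda: mr_core.mr_presso(iset, n_sim=sens.get("presso_sim", 2000),
                                                  seed=seed))
            if pres is not None:
                row = _estimate_row(score_name, "sensitivity", pres.corrected, None)
                row["method"] = "mr_presso_corrected"
                row.update(presso_global_pval=pres.global_pval,
                           presso_outliers=",".join(pres.outlier_ids) or "none")
                sens_rows.append(row)

        # subgroup runs restricted by ancestry label
        for ancestry in plan.subgroup_ancestries:
            subset = [c for c in cohorts if c.ancestry == ancestry]
            if not subset:
                continue
            sub_est = _try(f"subgroup[{ancestry}]",
                           lambda: mr_core.ivw(build_instrument_set(score, exposure,
                                                                    subset, ld),
                                               effects=effects))
            if sub_est is not None:
                row = _estimate_row(score_name, f"subgroup[{ancestry}]", sub_est, None)
                sens_rows.append(row)

        # single-SNP refits re-enter the same path with k = 1
        for snp in plan.single_snp_refits:
            if snp not in score.snp_ids:
                continue
            refit = _try(f"refit[{snp}]",
                         lambda: mr_core.ivw(build_instrument_set(
                             subset_score(score, [snp]), exposure, cohorts, ld)))
            if refit is not None:
                row = _estimate_row(score_name, f"single_snp[{snp}]", refit, None)
                sens_rows.append(row)

    results = pd.DataFrame(results_rows)
    sensitivity = pd.DataFrame(sens_rows)
    persnp = pd.DataFrame(persnp_rows)
    return ReportBundle(results, sensitivity, persnp, log, failures)
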