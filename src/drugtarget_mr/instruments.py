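"""Instrument selection, allele harmonization, meta-analysis and score weights.

Orientation convention: every score stores positive exposure-lowering weight
magnitudes together with the allele whose inheritance lowers the exposure.
Harmonized instrument sets therefore carry bx > 0 (mmol/L of LDL lowering per
counted allele) and sign-consistent outcome effects, so pooled causal
estimates are natively scaled per 1 mmol/L exposure decrease. LD signs are
flipped alongside whenever the counted allele switches relative to the
exposure file's coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats_io import (
    COMPLEMENT,
    GeneRegion,
    CohortMatrix,
    LDMatrix,
    ValidationError,
    VariantAssociation,
)

logger = logging.getLogger("drugtarget_mr")

#: genome-wide significance threshold for exposure associations
GENOME_WIDE_P = 5e-8
#: maximum pairwise r^2 within a cis score
CIS_R2_PRUNE = 0.2
#: maximum pairwise r^2 within the polygenic score (effectively independent)
POLYGENIC_R2_PRUNE = 0.001
#: minimum r^2 for proxy substitution
PROXY_R2_MIN = 0.9


@dataclass
class ScoreDefinition:
    """A weighted genetic score oriented to exposure-lowering alleles.

    ``weights`` are positive per-allele LDL-lowering magnitudes (mmol/L);
    ``effect_alleles[j]`` is the counted (lowering) allele of ``snp_ids[j]``.
    """

    name: str
    snp_ids: list[str]
    weights: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    region: GeneRegion | None = None
    orientation: str = "lowering"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError(f"score {self.name}: duplicate SNPs")
        if not (len(self.snp_ids) == len(self.weights)
                == len(self.effect_alleles) == len(self.other_alleles)):
            raise ValidationError(f"score {self.name}: inconsistent field lengths")
        if np.any(self.weights < 0):
            raise ValidationError(
                f"score {self.name}: weights must be positive lowering magnitudes")

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class InstrumentSet:
    """Harmonized exposure + outcome effects for a score's SNPs.

    bx > 0 holds exposure-lowering magnitudes (mmol/L per counted allele);
    by is the outcome log-odds per counted allele under the same orientation;
    rho is the LD correlation with signs consistent with the counted alleles.
    """

    snp_ids: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    rho: LDMatrix

    def __post_init__(self) -> None:
        for name in ("bx", "sx", "by", "sy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.snp_ids)
        if not all(len(getattr(self, f)) == k for f in ("bx", "sx", "by", "sy")):
            raise ValidationError("instrument arrays must share one length")
        if np.any(self.bx <= 0):
            raise ValidationError("bx must be strictly positive after orientation")
        if np.any(self.sx <= 0) or np.any(self.sy <= 0):
            raise ValidationError("standard errors must be positive")
        if self.rho.snp_ids != list(self.snp_ids):
            raise ValidationError("rho panel must match the instrument panel in order")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def wald(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP ratio estimates theta_j = by/bx with first-order SEs sy/bx."""
        return self.by / self.bx, self.sy / self.bx

    def subset(self, keep: list[str]) -> "InstrumentSet":
        idx = [self.snp_ids.index(s) for s in keep]
        return InstrumentSet(
            [self.snp_ids[i] for i in idx],
            self.bx[idx], self.sx[idx], self.by[idx], self.sy[idx],
            self.rho.submatrix(keep),
        )


@dataclass
class FStatResult:
    """Per-SNP instrument-strength F statistics with a weak-instrument flag."""

    per_snp: dict[str, float]
    min_f: float
    p_threshold_bound: float
    weak: list[str] = field(default_factory=list)

    @property
    def all_strong(self) -> bool:
        return not self.weak


# ---------------------------------------------------------------------------
# selection and proxies
# ---------------------------------------------------------------------------

def select_instruments(exposure: list[VariantAssociation],
                       region: GeneRegion | None,
                       p_thresh: float = GENOME_WIDE_P,
                       r2_prune: float = CIS_R2_PRUNE,
                       ld: LDMatrix | list[LDMatrix] | None = None,
                       name: str | None = None) -> ScoreDefinition:
    """Greedy cis (or polygenic) instrument selection.

    Candidates inside the region window (if any) with p < ``p_thresh`` are
    ranked by ascending p (ties broken by snp_id) and accepted greedily iff
    their r^2 with every already-accepted SNP is <= ``r2_prune`` in EVERY
    supplied LD matrix. Polygenic mode: region None with a near-zero prune
    threshold. No candidate passing p is a warning, not an error.
    """
    ld_list = [ld] if isinstance(ld, LDMatrix) else list(ld or [])
    candidates = [
        v for v in exposure
        if (region is None or region.contains(v.chrom, v.pos)) and v.pval < p_thresh
    ]
    score_name = name or (region.name if region else "score")
    if not candidates:
        logger.warning("score %s: no candidate passes p < %g", score_name, p_thresh)
        return ScoreDefinition(score_name, [], np.empty(0), [], [], region)

    for mat in ld_list:
        missing = [v.snp_id for v in candidates if v.snp_id not in mat]
        if missing:
            raise KeyError(f"SNP(s) absent from LD matrix: {', '.join(missing)}")

    accepted: list[VariantAssociation] = []
    for v in sorted(candidates, key=lambda v: (v.pval, v.snp_id)):
        ok = all(
            mat.loc(v.snp_id, kept.snp_id) ** 2 <= r2_prune
            for mat in ld_list for kept in accepted
        )
        if ok:
            accepted.append(v)

    lowering = [v if v.beta <= 0 else v.flipped() for v in accepted]
    return ScoreDefinition(
        name=score_name,
        snp_ids=[v.snp_id for v in lowering],
        weights=np.array([-v.beta for v in lowering]),
        effect_alleles=[v.effect_allele for v in lowering],
        other_alleles=[v.other_allele for v in lowering],
        region=region,
    )


def find_proxy(target: str, candidates: list[str], ld: LDMatrix,
               r2_min: float = PROXY_R2_MIN) -> str | None:
    """Best proxy for ``target``: highest r^2 >= ``r2_min`` among candidates.

    Ties are broken by lexicographically smallest snp_id; None when no
    candidate qualifies.
    """
    if target not in ld:
        raise KeyError(f"target SNP {target} absent from LD matrix")
    best: tuple[float, str] | None = None
    for cand in candidates:
        if cand == target:
            continue
        r2 = ld.loc(target, cand) ** 2
        if r2 < r2_min:
            continue
        if best is None or r2 > best[0] + 1e-15 or (abs(r2 - best[0]) <= 1e-15 and cand < best[1]):
            best = (r2, cand)
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# cross-cohort meta-analysis
# ---------------------------------------------------------------------------

def meta_analyze_fixed(per_cohort: list[VariantAssociation]) -> VariantAssociation:
    """Fixed-effect inverse-variance pooling of one SNP across cohorts.

    All records must share snp_id and identically harmonized alleles.
    """
    if not per_cohort:
        raise ValueError("no records to meta-analyze")
    first = per_cohort[0]
    for rec in per_cohort[1:]:
        if rec.snp_id != first.snp_id:
            raise ValidationError(
                f"cannot pool different SNPs: {first.snp_id} vs {rec.snp_id}")
        if (rec.effect_allele, rec.other_allele) != (first.effect_allele, first.other_allele):
            raise ValidationError(
                f"{first.snp_id}: allele mismatch across cohorts "
                f"({first.effect_allele}/{first.other_allele} vs "
                f"{rec.effect_allele}/{rec.other_allele}); harmonize first")
    w = np.array([1.0 / r.se**2 for r in per_cohort])
    b = np.array([r.beta for r in per_cohort])
    beta = float(w @ b / w.sum())
    se = float(w.sum() ** -0.5)
    pval = float(max(2.0 * stats.norm.sf(abs(beta / se)), 1e-300))
    ns = [r.n for r in per_cohort if r.n is not None]
    eafs = [r.eaf for r in per_cohort if r.eaf is not None]
    return VariantAssociation(
        snp_id=first.snp_id, chrom=first.chrom, pos=first.pos,
        effect_allele=first.effect_allele, other_allele=first.other_allele,
        eaf=float(np.mean(eafs)) if eafs else None,
        beta=beta, se=se, pval=pval,
        n=int(sum(ns)) if ns else None,
        trait_kind=first.trait_kind,
    )


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _orient_to(counted: str, other: str, rec: VariantAssociation) -> float:
    """rec.beta expressed per ``counted`` allele; matches direct or by strand complement."""
    pairs = {
        (rec.effect_allele, rec.other_allele): rec.beta,
        (rec.other_allele, rec.effect_allele): -rec.beta,
        (COMPLEMENT[rec.effect_allele], COMPLEMENT[rec.other_allele]): rec.beta,
        (COMPLEMENT[rec.other_allele], COMPLEMENT[rec.effect_allele]): -rec.beta,
    }
    key = (counted, other)
    if key not in pairs:
        raise ValidationError(
            f"{rec.snp_id}: irreconcilable alleles {rec.effect_allele}/{rec.other_allele} "
            f"vs {counted}/{other}")
    return pairs[key]


def harmonize(score: ScoreDefinition,
              exposure: list[VariantAssociation],
              outcome: list[VariantAssociation],
              eaf_palindrome_band: float = 0.08,
              ld: LDMatrix | None = None) -> InstrumentSet:
    """Align exposure and outcome records to the score's lowering alleles.

    Alleles are matched directly or via strand complement; outcome betas flip
    sign when the outcome's effect allele is the counted allele's partner.
    Palindromic (A/T, C/G) SNPs are dropped when the EAF is missing or within
    ``eaf_palindrome_band`` of 0.5 (strand unresolvable). The attached LD
    submatrix has signs flipped wherever the counted allele differs from the
    exposure file's effect allele.
    """
    exp_by_id = {r.snp_id: r for r in exposure}
    out_by_id = {r.snp_id: r for r in outcome}

    kept, bx, sx, by, sy, flip_sign = [], [], [], [], [], []
    for j, snp in enumerate(score.snp_ids):
        if snp not in exp_by_id:
            raise KeyError(f"{snp}: missing from exposure records")
        if snp not in out_by_id:
            raise KeyError(f"{snp}: missing from outcome records (find a proxy first)")
        counted, other = score.effect_alleles[j], score.other_alleles[j]
        e, o = exp_by_id[snp], out_by_id[snp]

        if e.is_palindromic or o.is_palindromic:
            rec = e if e.is_palindromic else o
            eaf = rec.eaf
            ambiguous = eaf is None or abs(eaf - 0.5) <= eaf_palindrome_band
            if ambiguous:
                logger.info("%s: palindromic with ambiguous EAF (%s); dropped", snp, eaf)
                continue

        beta_x = _orient_to(counted, other, e)
        beta_y = _orient_to(counted, other, o)
        if beta_x > 0:
            # the stored counted allele must lower the exposure; flip both
            counted, other = other, counted
            beta_x, beta_y = -beta_x, -beta_y
        if beta_x == 0:
            raise ValidationError(f"{snp}: null exposure effect cannot be oriented")
        kept.append(snp)
        bx.append(-beta_x)
        sx.append(e.se)
        by.append(beta_y)
        sy.append(o.se)
        flip_sign.append(counted != e.effect_allele and counted != COMPLEMENT[e.effect_allele])

    if not kept:
        raise ValidationError(f"score {score.name}: no SNP survived harmonization")

    if ld is None:
        rho = LDMatrix.identity(kept)
    else:
        rho = ld.submatrix(kept)
        signs = np.where(np.array(flip_sign), -1.0, 1.0)
        rho = LDMatrix(kept, rho.r * np.outer(signs, signs))
    return InstrumentSet(kept, np.array(bx), np.array(sx), np.array(by), np.array(sy), rho)


# ---------------------------------------------------------------------------
# scores and instrument strength
# ---------------------------------------------------------------------------

def weighted_score(cohort: CohortMatrix, score: ScoreDefinition) -> np.ndarray:
    """Per-individual genetically proxied LDL reduction (mmol/L).

    value_i = sum_j dosage_ij * weight_j, with dosages counted on the lowering
    allele. Missing score SNPs are an error (no implicit imputation).
    """
    missing = [s for s in score.snp_ids if s not in cohort.snp_ids]
    if missing:
        raise KeyError(f"score SNP(s) absent from cohort: {', '.join(missing)}")
    idx = [cohort.snp_ids.index(s) for s in score.snp_ids]
    return cohort.dosages[:, idx] @ score.weights


def f_statistic(record_or_set: VariantAssociation | InstrumentSet,
                p_thresh: float = GENOME_WIDE_P) -> float | FStatResult:
    """Instrument-strength F = (beta/se)^2.

    For a single record: the scalar F. For an InstrumentSet: per-SNP Fs, the
    set minimum, the bound implied by the selection p-threshold, and flags for
    SNPs with F <= 10 (strict inequality required to pass).
    """
    if isinstance(record_or_set, VariantAssociation):
        return float((record_or_set.beta / record_or_set.se) ** 2)
    iset = record_or_set
    per = {s: float(f) for s, f in zip(iset.snp_ids, (iset.bx / iset.sx) ** 2)}
    weak = [s for s, f in per.items() if f <= 10.0]
    return FStatResult(
        per_snp=per,
        min_f=min(per.values()),
        p_threshold_bound=float(stats.chi2.isf(p_thresh, df=1)),
        weak=weak,
    )
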