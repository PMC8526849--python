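"""Per-SNP colocalization of two traits' signals via approximate Bayes factors.

For each variant, the Wakefield approximate Bayes factor against the null is
computed from the association z-score, the sampling variance V = se^2 and a
prior effect variance W: with r = W/(V+W),

    log ABF = 1/2 [ log(1 - r) + z^2 r ].

Conditional on the region containing exactly one causal variant shared by
both traits, the posterior probability that SNP j is that variant is the
softmax of the joint (summed) per-SNP log Bayes factors under equal per-SNP
priors. Full multi-hypothesis region posteriors are out of scope; this module
reports the per-SNP shared-variant posterior (PPA) only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax

from .sumstats_io import ValidationError, VariantAssociation

#: default prior effect SDs: 0.20 per SD for a quantitative trait,
#: 0.15 on the log-odds scale for a binary trait
PRIOR_SD_QUANTITATIVE = 0.20
PRIOR_SD_BINARY = 0.15

#: reporting threshold for noteworthy shared variants
PPA_THRESHOLD = 0.01


@dataclass
class ColocResult:
    """Per-SNP log ABFs for the two traits and shared-variant posteriors."""

    snp_ids: list[str]
    labf_trait1: np.ndarray
    labf_trait2: np.ndarray
    ppa: np.ndarray
    W1: float
    W2: float
    threshold: float = PPA_THRESHOLD

    def __post_init__(self) -> None:
        if abs(float(self.ppa.sum()) - 1.0) > 1e-9:
            raise ValidationError("per-SNP posteriors must sum to 1")
        if np.any(self.ppa < 0) or np.any(self.ppa > 1):
            raise ValidationError("posteriors must lie in [0,1]")

    @property
    def flagged(self) -> dict[str, float]:
        """SNPs whose shared-variant posterior exceeds the reporting threshold."""
        return {
            s: float(p) for s, p in zip(self.snp_ids, self.ppa) if p > self.threshold
        }

    @property
    def top(self) -> tuple[str, float]:
        i = int(np.argmax(self.ppa))
        return self.snp_ids[i], float(self.ppa[i])


def log_abf(beta: float | np.ndarray, se: float | np.ndarray,
            W: float) -> float | np.ndarray:
    """Wakefield log approximate Bayes factor for association versus the null."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("se must be > 0")
    if W <= 0:
        raise ValidationError("prior variance W must be > 0")
    V = se**2
    z = np.asarray(beta, dtype=float) / se
    r = W / (V + W)
    out = 0.5 * (np.log1p(-r) + z**2 * r)
    return float(out) if out.ndim == 0 else out


def per_snp_ppa(region1: list[VariantAssociation],
                region2: list[VariantAssociation],
                W1: float = PRIOR_SD_QUANTITATIVE**2,
                W2: float = PRIOR_SD_BINARY**2,
                threshold: float = PPA_THRESHOLD) -> ColocResult:
    """Shared-causal-variant posterior for every SNP of a harmonized region.

    Both traits must cover the identical SNP panel; records are aligned by
    snp_id. The joint per-SNP evidence is labf1 + labf2 and the posterior is
    its softmax over the region.
    """
    ids1 = {r.snp_id for r in region1}
    ids2 = {r.snp_id for r in region2}
    if ids1 != ids2:
        only1 = sorted(ids1 - ids2)
        only2 = sorted(ids2 - ids1)
        raise ValidationError(
            f"SNP panels differ: only in trait 1: {only1}; only in trait 2: {only2}")
    snp_ids = [r.snp_id for r in region1]
    by_id2 = {r.snp_id: r for r in region2}

    l1 = np.array([log_abf(r.beta, r.se, W1) for r in region1])
    l2 = np.array([log_abf(by_id2[s].beta, by_id2[s].se, W2) for s in snp_ids])
    ppa = np.exp(log_softmax(l1 + l2))
    return ColocResult(snp_ids, l1, l2, ppa, W1, W2, threshold)
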