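"""Shared fixtures: small hand-built records, instrument sets and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from drugtarget_mr import (
    CohortMatrix,
    InstrumentSet,
    LDMatrix,
    VariantAssociation,
)


def make_variant(snp_id="rs1", chrom="5", pos=74_656_539, ea="T", oa="C",
                 eaf=0.39, beta=-0.073, se=0.0038, pval=1e-50, n=188_578,
                 trait_kind="quantitative") -> VariantAssociation:
    return VariantAssociation(snp_id, chrom, pos, ea, oa, eaf, beta, se, pval, n,
                              trait_kind)


def make_iset(bx, by, sy, sx=None, rho=None, ids=None) -> InstrumentSet:
    bx = np.asarray(bx, dtype=float)
    k = len(bx)
    ids = ids or [f"s{i}" for i in range(k)]
    sx = np.full(k, 1e-8) if sx is None else np.asarray(sx, dtype=float)
    rho = LDMatrix.identity(ids) if rho is None else LDMatrix(ids, rho)
    return InstrumentSet(ids, bx, sx, np.asarray(by, dtype=float),
                         np.asarray(sy, dtype=float), rho)


@pytest.fixture
def two_snp_iset() -> InstrumentSet:
    """The independent 2-SNP worked example."""
    return make_iset(bx=[0.1, 0.1], by=[-0.05, -0.03], sy=[0.02, 0.01])


@pytest.fixture
def small_cohort() -> CohortMatrix:
    rng = np.random.default_rng(99)
    n, m = 400, 3
    dos = rng.integers(0, 3, size=(n, m)).astype(float)
    y = rng.integers(0, 2, size=n)
    return CohortMatrix(dos, y, [f"s{i}" for i in range(m)],
                        [f"id{i}" for i in range(n)])
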