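"""Readers, writers and validation for GWAS summary statistics, LD matrices and cohorts.

All positions are 1-based hg19 coordinates. Summary-statistic files are
tab-delimited with the canonical header ``SNP CHR BP EA OA EAF BETA SE P N``;
a built-in synonym table maps common alternative spellings, and any header
that is neither canonical nor a known synonym is a format error rather than
a guess. Rows violating typed invariants are rejected with a per-row report.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("drugtarget_mr")

VALID_ALLELES = frozenset("ACGT")

#: complementary-strand base pairing
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]

# header synonym table; keys are lower-cased observed headers
COLUMN_SYNONYMS = {
    "snp": "SNP", "rsid": "SNP", "markername": "SNP", "variant_id": "SNP",
    "chr": "CHR", "chrom": "CHR", "chromosome": "CHR",
    "bp": "BP", "pos": "BP", "position": "BP", "base_pair_location": "BP",
    "ea": "EA", "effect_allele": "EA", "a1": "EA",
    "oa": "OA", "other_allele": "OA", "non_effect_allele": "OA", "a2": "OA",
    "eaf": "EAF", "effect_allele_frequency": "EAF", "freq": "EAF", "af": "EAF",
    "beta": "BETA", "effect": "BETA", "b": "BETA",
    "se": "SE", "standard_error": "SE", "stderr": "SE",
    "p": "P", "pval": "P", "pvalue": "P", "p_value": "P",
    "n": "N", "sample_size": "N",
}


class SumstatsFormatError(ValueError):
    """A file does not conform to the expected layout (e.g. missing column)."""


class ValidationError(ValueError):
    """Typed-invariant violations, reported per offending row/entry."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantAssociation:
    """One SNP's per-allele association with one trait.

    ``beta`` is the per-effect-allele effect: mmol/L for a quantitative
    exposure such as LDL cholesterol, log-odds for a binary outcome.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None
    trait_kind: str = "quantitative"

    def __post_init__(self) -> None:
        self.effect_allele = self.effect_allele.upper()
        self.other_allele = self.other_allele.upper()
        problems = _variant_problems(self)
        if problems:
            raise ValidationError(f"{self.snp_id}: " + "; ".join(problems))

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def flipped(self) -> "VariantAssociation":
        """The same association expressed on the other allele."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
        )


def _variant_problems(v: VariantAssociation) -> list[str]:
    problems = []
    if v.effect_allele not in VALID_ALLELES or v.other_allele not in VALID_ALLELES:
        problems.append(f"alleles must be A/C/G/T, got {v.effect_allele}/{v.other_allele}")
    elif v.effect_allele == v.other_allele:
        problems.append("effect allele equals other allele")
    if not (isinstance(v.pos, (int, np.integer)) and v.pos >= 1):
        problems.append(f"position must be a 1-based integer, got {v.pos}")
    if not (v.se > 0 and math.isfinite(v.se)):
        problems.append(f"se must be > 0, got {v.se}")
    if v.eaf is not None and not (0.0 <= v.eaf <= 1.0):
        problems.append(f"eaf must lie in [0,1], got {v.eaf}")
    if not (0.0 < v.pval <= 1.0):
        problems.append(f"p-value must lie in (0,1], got {v.pval}")
    if v.n is not None and v.n < 1:
        problems.append(f"n must be >= 1, got {v.n}")
    if not math.isfinite(v.beta):
        problems.append(f"beta must be finite, got {v.beta}")
    return problems


@dataclass
class GeneRegion:
    """A gene's hg19 footprint plus the cis window flank (bp, default 100 kb)."""

    name: str
    chrom: str
    start: int
    end: int
    flank: int = 100_000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.name}: start {self.start} > end {self.end}")
        if self.flank < 0:
            raise ValidationError(f"{self.name}: flank must be >= 0")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank), self.end + self.flank

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.window
        return str(chrom) == str(self.chrom) and lo <= pos <= hi


class LDMatrix:
    """Signed pairwise correlation r among an ordered variant panel."""

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        snp_ids = list(snp_ids)
        if r.ndim != 2 or r.shape[0] != r.shape[1] or r.shape[0] != len(snp_ids):
            raise ValidationError("LD matrix must be square and match the SNP panel")
        if len(set(snp_ids)) != len(snp_ids):
            raise ValidationError("duplicate SNP ids in LD panel")
        if r.size:
            if np.max(np.abs(r - r.T)) > 1e-8:
                raise ValidationError("LD matrix is asymmetric beyond 1e-8 tolerance")
            if np.any(np.abs(r) > 1 + 1e-8):
                bad = np.max(np.abs(r))
                raise ValidationError(
                    f"LD correlations must satisfy |r| <= 1, max |r| = {bad}")
            r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
            np.fill_diagonal(r, 1.0)
        self.snp_ids = snp_ids
        self.r = r
        self._index = {s: i for i, s in enumerate(snp_ids)}

    @property
    def r2(self) -> np.ndarray:
        return self.r**2

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def __len__(self) -> int:
        return len(self.snp_ids)

    def loc(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"SNP {exc.args[0]} absent from LD matrix") from None

    def submatrix(self, snp_ids: Sequence[str]) -> "LDMatrix":
        missing = [s for s in snp_ids if s not in self._index]
        if missing:
            raise KeyError(f"SNPs absent from LD matrix: {', '.join(missing)}")
        idx = [self._index[s] for s in snp_ids]
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(list(snp_ids), np.eye(len(snp_ids)))


@dataclass
class CohortMatrix:
    """Individual-level dosages (n x m, counted alleles in [0,2]) plus binary phenotype."""

    dosages: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.phenotype = np.asarray(self.phenotype)
        n, m = self.dosages.shape
        if len(self.phenotype) != n or len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValidationError("cohort dimensions are inconsistent")
        if np.any(self.dosages < 0) or np.any(self.dosages > 2):
            raise ValidationError("dosages must lie in [0,2]")
        if not np.isin(self.phenotype, (0, 1)).all():
            raise ValidationError("phenotype values must be 0/1")
        self.phenotype = self.phenotype.astype(int)

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int(len(self.phenotype) - self.phenotype.sum())


# ---------------------------------------------------------------------------
# summary-statistics IO
# ---------------------------------------------------------------------------

def _canonicalize_columns(columns: Iterable[str]) -> dict[str, str]:
    mapping = {}
    for col in columns:
        key = col.strip().lower()
        if col in CANONICAL_COLUMNS:
            mapping[col] = col
        elif key in COLUMN_SYNONYMS:
            mapping[col] = COLUMN_SYNONYMS[key]
        else:
            raise SumstatsFormatError(
                f"unrecognized column {col!r}; known headers: "
                + ", ".join(CANONICAL_COLUMNS)
            )
    return mapping


def read_sumstats(path, trait_kind: str = "quantitative") -> list[VariantAssociation]:
    """Read a tab-delimited summary-statistics file into validated records.

    EAF and N may be "NA"; every other field is mandatory. All rows failing an
    invariant are reported together with their (0-based) row indices.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df = df.rename(columns=_canonicalize_columns(df.columns))
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[VariantAssociation] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = VariantAssociation(
                snp_id=str(getattr(row, "SNP")),
                chrom=str(getattr(row, "CHR")),
                pos=int(getattr(row, "BP")),
                effect_allele=str(getattr(row, "EA")),
                other_allele=str(getattr(row, "OA")),
                eaf=_parse_optional_float(getattr(row, "EAF")),
                beta=float(getattr(row, "BETA")),
                se=float(getattr(row, "SE")),
                pval=float(getattr(row, "P")),
                n=_parse_optional_int(getattr(row, "N")),
                trait_kind=trait_kind,
            )
        except (ValidationError, ValueError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
            continue
        records.append(rec)
    if errors:
        raise ValidationError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    return records


def _parse_optional_float(x) -> float | None:
    if x is None or (isinstance(x, float) and math.isnan(x)) or str(x).upper() in ("NA", "NAN", ""):
        return None
    return float(x)


def _parse_optional_int(x) -> int | None:
    v = _parse_optional_float(x)
    return None if v is None else int(v)


def write_sumstats(records: Sequence[VariantAssociation], path) -> None:
    """Write records as canonical TSV: 6 significant digits, p in scientific notation."""
    rows = []
    for v in records:
        rows.append({
            "SNP": v.snp_id,
            "CHR": v.chrom,
            "BP": v.pos,
            "EA": v.effect_allele,
            "OA": v.other_allele,
            "EAF": "NA" if v.eaf is None else f"{v.eaf:.6g}",
            "BETA": f"{v.beta:.6g}",
            "SE": f"{v.se:.6g}",
            "P": f"{v.pval:.6e}",
            "N": "NA" if v.n is None else str(v.n),
        })
    pd.DataFrame(rows, columns=CANONICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# LD IO
# ---------------------------------------------------------------------------

def read_ld_matrix(path) -> LDMatrix:
    """Read an LD matrix from square (header = SNP ids) or long (snp_a, snp_b, r) TSV.

    Long-layout pairs not listed default to r = 0; the diagonal is forced to 1.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lowered = [c.strip().lower() for c in df.columns]
    if lowered[:3] == ["snp_a", "snp_b", "r"]:
        df.columns = ["snp_a", "snp_b", "r"] + list(df.columns[3:])
        snp_ids = sorted(set(df["snp_a"]).union(df["snp_b"]))
        index = {s: i for i, s in enumerate(snp_ids)}
        r = np.eye(len(snp_ids))
        for a, b, val in df[["snp_a", "snp_b", "r"]].itertuples(index=False):
            val = float(val)
            if abs(val) > 1:
                raise ValidationError(f"|r| > 1 for pair ({a}, {b}): {val}")
            r[index[a], index[b]] = val
            r[index[b], index[a]] = val
        np.fill_diagonal(r, 1.0)
        return LDMatrix(snp_ids, r)
    # square layout: first column holds row SNP ids
    df = df.set_index(df.columns[0])
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path, layout: str = "square") -> None:
    if layout == "square":
        df = pd.DataFrame(ld.r, index=pd.Index(ld.snp_ids, name="SNP"), columns=ld.snp_ids)
        df.to_csv(path, sep="\t", float_format="%.10g")
    elif layout == "long":
        rows = [
            {"snp_a": a, "snp_b": b, "r": f"{ld.r[i, j]:.10g}"}
            for i, a in enumerate(ld.snp_ids)
            for j, b in enumerate(ld.snp_ids)
            if i < j
        ]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown LD layout {layout!r}")


# ---------------------------------------------------------------------------
# cohort IO
# ---------------------------------------------------------------------------

def read_cohort(dosage_path, phenotype_path) -> CohortMatrix:
    """Read a sample x SNP dosage table and a sample -> {0,1} phenotype table.

    Samples are aligned by id; samples lacking a phenotype are excluded with a
    logged count.
    """
    dos = pd.read_csv(dosage_path, sep="\t", comment="#")
    dos = dos.set_index(dos.columns[0])
    phe = pd.read_csv(phenotype_path, sep="\t", comment="#")
    phe = phe.set_index(phe.columns[0]).iloc[:, 0]

    shared = [s for s in dos.index if s in phe.index]
    if not shared:
        raise ValidationError("no overlapping samples between dosage and phenotype files")
    dropped = len(dos) - len(shared)
    if dropped:
        logger.warning("excluded %d sample(s) with no phenotype record", dropped)
    return CohortMatrix(
        dosages=dos.loc[shared].to_numpy(dtype=float),
        phenotype=phe.loc[shared].to_numpy(),
        snp_ids=list(dos.columns),
        sample_ids=[str(s) for s in shared],
    )


def write_cohort(cohort: CohortMatrix, dosage_path, phenotype_path) -> None:
    pd.DataFrame(
        cohort.dosages, index=pd.Index(cohort.sample_ids, name="sample_id"),
        columns=cohort.snp_ids,
    ).to_csv(dosage_path, sep="\t", float_format="%.6g")
    pd.DataFrame(
        {"phenotype": cohort.phenotype},
        index=pd.Index(cohort.sample_ids, name="sample_id"),
    ).to_csv(phenotype_path, sep="\t")


# ---------------------------------------------------------------------------
# configuration & logging
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a declarative YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SumstatsFormatError("configuration file must contain a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable sha256 fingerprint of a configuration mapping."""
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def log_run(cfg: dict, seeds: dict | None = None) -> str:
    """Echo the configuration hash and RNG seeds; returns the hash."""
    h = config_hash(cfg)
    logger.info("run config hash: %s", h)
    for name, seed in (seeds or {}).items():
        logger.info("seed[%s] = %s", name, seed)
    return h
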