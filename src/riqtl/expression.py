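"""Expression quantification and strain-level Pearson correlation.

TPM (transcripts per million) length-normalizes read counts so that every
sample's gene-level values sum to exactly 1,000,000; the analysis scale is
log2(TPM + 1). Two per-gene selection criteria live here: mean expression
at or above a threshold (default 2, applied on the declared scale of the
matrix handed in) and a nominally significant (P < 0.05, two-sided, no
multiple-testing correction — deliberate and documented) Pearson correlation
with the phenotype across strain means.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, DomainError, InputError

SCALES = ("counts", "tpm", "log2_tpm_plus1")
TPM_TOTAL = 1_000_000.0


@dataclass
class CorrelationResult:
    name_a: str
    name_b: str
    n: int
    r: float
    p: float
    at_floor: bool = False  # |r| = 1: p reported as the distribution floor


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Counts (genes x strains) + lengths (bp) -> TPM matrix summing to 1e6/sample."""
    counts = counts.astype(float)
    lengths = pd.Series(gene_lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise InputError(f"gene lengths missing for {missing[:10]}")
    if (lengths <= 0).any():
        raise DomainError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise DomainError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise DegenerateInputError(
            f"all-zero count column(s) {zero[:10]}: TPM normalization undefined"
        )
    out = rate.div(totals, axis=1) * TPM_TOTAL
    out.attrs["scale"] = "tpm"
    return out


def log2p1(tpm_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1); requires a TPM-scale (non-negative) matrix."""
    vals = tpm_matrix.to_numpy(dtype=float)
    if (vals < 0).any():
        raise DomainError("log2(TPM+1) requires non-negative input")
    out = pd.DataFrame(
        np.log2(vals + 1.0), index=tpm_matrix.index, columns=tpm_matrix.columns
    )
    out.attrs["scale"] = "log2_tpm_plus1"
    return out


def pearson(x, y, name_a: str = "x", name_b: str = "y") -> CorrelationResult:
    """Sample Pearson r on pairwise-complete values with a two-sided t-test p.

    p = 2 * P(T_{n-2} > |r| * sqrt((n-2)/(1-r^2))). A perfect correlation has
    no finite t; its p is reported as the smallest positive float and flagged.
    """
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        x = x.reindex(common)
        y = y.reindex(common)
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    n = xv.shape[0]
    if n < 3:
        raise DegenerateInputError("Pearson correlation needs at least 3 complete pairs")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("zero variance: correlation undefined")
    r = float(xc @ yc) / np.sqrt(sxx * syy)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(name_a, name_b, n, r, float(np.finfo(float).tiny), True)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(name_a, name_b, n, r, p)


def correlate_matrix(
    expr: pd.DataFrame, phenotype: pd.Series, trait_name: str | None = None
) -> pd.DataFrame:
    """Per-gene Pearson r/p against one phenotype; columns gene, n, r, p."""
    trait_name = trait_name or str(phenotype.name or "trait")
    rows = []
    for gene_id, row in expr.iterrows():
        res = pearson(row, phenotype, name_a=str(gene_id), name_b=trait_name)
        rows.append({"gene_id": str(gene_id), "n": res.n, "r": res.r, "p": res.p})
    return pd.DataFrame(rows)


def expression_criterion(expr: pd.DataFrame, threshold: float = 2.0) -> pd.Series:
    """True for genes whose mean over strains is >= threshold (inclusive)."""
    return expr.mean(axis=1) >= threshold


def correlation_criterion(
    expr: pd.DataFrame, phenotype: pd.Series, alpha: float = 0.05
) -> pd.Series:
    """True for genes with Pearson p strictly below alpha (no correction)."""
    corr = correlate_matrix(expr, phenotype)
    flags = pd.Series(corr["p"].to_numpy() < alpha, index=corr["gene_id"])
    flags.index.name = "gene_id"
    return flags
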