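"""Cis-eQTL classification.

A gene's expression trait is scanned with the same mixed model as any other
phenotype; the gene is called *cis*-regulated when the genome-wide
maximum-LRS marker exceeds LRS 14 (strict) and lies on the gene's own
chromosome within a 5 Mb window flanking the gene body
([start - 5, end + 5] Mb). An alternative ``scope='local'`` reading takes
the maximum only over markers inside that window.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import GenotypeMatrix
from .lmm import ScanResult, scan_trait


@dataclass
class CisCall:
    gene_id: str
    max_lrs: float
    max_lrs_marker_id: str
    max_lrs_marker_mb: float
    max_lrs_marker_chr: str
    is_cis: bool


def cis_call_from_scan(
    gene: pd.Series,
    scan: ScanResult,
    window_mb: float = 5.0,
    lrs_threshold: float = 14.0,
    scope: str = "genome",
) -> CisCall:
    """Apply the distance + LRS rule to an existing expression scan.

    ``gene`` needs fields gene_id, chromosome, start_mb, end_mb. LRS ties are
    broken toward the marker nearest the gene midpoint (markers on other
    chromosomes count as infinitely far).
    """
    t = scan.table
    if scope == "local":
        t = t[
            (t["chromosome"].astype(str) == str(gene["chromosome"]))
            & (t["position_mb"] >= float(gene["start_mb"]) - window_mb)
            & (t["position_mb"] <= float(gene["end_mb"]) + window_mb)
        ]
        if t.empty:
            raise DegenerateInputError(
                f"no markers within {window_mb} Mb of gene {gene['gene_id']}"
            )
    elif scope != "genome":
        raise ValueError(f"unknown scope {scope!r}")

    lrs = t["lrs"].to_numpy(dtype=float)
    top = np.flatnonzero(lrs >= lrs.max() - 1e-12)
    if len(top) > 1:
        mid = 0.5 * (float(gene["start_mb"]) + float(gene["end_mb"]))
        same = t.iloc[top]["chromosome"].astype(str).to_numpy() == str(gene["chromosome"])
        dist = np.abs(t.iloc[top]["position_mb"].to_numpy(dtype=float) - mid)
        dist = np.where(same, dist, np.inf)
        best = top[int(np.argmin(dist))]
    else:
        best = int(top[0])
    row = t.iloc[best]
    max_lrs = float(row["lrs"])
    mb = float(row["position_mb"])
    chrom = str(row["chromosome"])
    is_cis = (
        max_lrs > lrs_threshold
        and chrom == str(gene["chromosome"])
        and float(gene["start_mb"]) - window_mb <= mb <= float(gene["end_mb"]) + window_mb
    )
    return CisCall(
        gene_id=str(gene["gene_id"]),
        max_lrs=max_lrs,
        max_lrs_marker_id=str(row["marker"]),
        max_lrs_marker_mb=mb,
        max_lrs_marker_chr=chrom,
        is_cis=bool(is_cis),
    )


def classify_cis(
    gene: pd.Series,
    expr_trait: pd.Series,
    genotypes: GenotypeMatrix,
    window_mb: float = 5.0,
    lrs_threshold: float = 14.0,
    scope: str = "genome",
    loco: bool = True,
    maf_min: float = 0.05,
) -> CisCall:
    """Scan one gene's expression trait and classify it as cis/not-cis."""
    if str(gene["chromosome"]) not in set(map(str, genotypes.chromosome)):
        raise DegenerateInputError(
            f"gene chromosome {gene['chromosome']!r} absent from genotype map"
        )
    scan = scan_trait(
        expr_trait,
        genotypes,
        loco=loco,
        maf_min=maf_min,
        trait_name=f"expr:{gene['gene_id']}",
    )
    return cis_call_from_scan(
        gene, scan, window_mb=window_mb, lrs_threshold=lrs_threshold, scope=scope
    )


def classify_cis_table(
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    genotypes: GenotypeMatrix,
    **kwargs,
) -> pd.DataFrame:
    """Classify every gene of ``genes`` that has an expression row."""
    rows = []
    for _, gene in genes.iterrows():
        gid = str(gene["gene_id"])
        if gid not in expr.index:
            continue
        call = classify_cis(gene, expr.loc[gid], genotypes, **kwargs)
        rows.append(
            {
                "gene_id": call.gene_id,
                "max_lrs": call.max_lrs,
                "max_lrs_marker": call.max_lrs_marker_id,
                "max_lrs_marker_mb": call.max_lrs_marker_mb,
                "max_lrs_marker_chr": call.max_lrs_marker_chr,
                "is_cis": call.is_cis,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "max_lrs",
            "max_lrs_marker",
            "max_lrs_marker_mb",
            "max_lrs_marker_chr",
            "is_cis",
        ],
    )
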