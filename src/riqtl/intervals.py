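"""Peak calling and 1.5-LOD support intervals.

One peak per chromosome (the maximal-LRS marker) is reported whenever its
-log10 p reaches the suggestive threshold; it is classed *significant* at
-log10 p >= 4 and *suggestive* in [3, 4). The support interval walks outward
from the peak in each direction and ends at the last marker whose LOD is
still within ``lod_drop`` (default 1.5) of the peak LOD — the inner-marker
convention: the first marker that falls below the drop is excluded.
Chromosome ends truncate the walk.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import order_chromosomes
from .lmm import ScanResult


@dataclass
class QTLInterval:
    chromosome: str
    peak_marker_id: str
    peak_mb: float
    peak_lrs: float
    peak_lod: float
    classification: str  # 'significant' or 'suggestive'
    lower_mb: float
    upper_mb: float
    gene_ids_inside: list = field(default_factory=list)


def call_peaks(
    scan: ScanResult,
    suggestive: float = 3.0,
    significant: float = 4.0,
    lod_drop: float = 1.5,
) -> list[QTLInterval]:
    """At most one QTL per chromosome, with 1.5-LOD support bounds."""
    df = scan.table
    if df.empty:
        return []
    out: list[QTLInterval] = []
    for chrom in order_chromosomes(df["chromosome"]):
        sub = df[df["chromosome"].astype(str) == chrom].sort_values("position_mb")
        lrs = sub["lrs"].to_numpy(dtype=float)
        lod = sub["lod"].to_numpy(dtype=float)
        mb = sub["position_mb"].to_numpy(dtype=float)
        nlp = sub["neg_log10_p"].to_numpy(dtype=float)
        peak = int(np.argmax(lrs))  # first max = lowest Mb on ties
        if nlp[peak] < suggestive:
            continue
        cls = "significant" if nlp[peak] >= significant else "suggestive"
        floor = lod[peak] - lod_drop
        left = peak
        while left - 1 >= 0 and lod[left - 1] >= floor:
            left -= 1
        right = peak
        while right + 1 < len(lod) and lod[right + 1] >= floor:
            right += 1
        out.append(
            QTLInterval(
                chromosome=chrom,
                peak_marker_id=str(sub["marker"].iloc[peak]),
                peak_mb=float(mb[peak]),
                peak_lrs=float(lrs[peak]),
                peak_lod=float(lod[peak]),
                classification=cls,
                lower_mb=float(mb[left]),
                upper_mb=float(mb[right]),
            )
        )
    return out


def genes_in_interval(interval: QTLInterval, genes: pd.DataFrame) -> list[str]:
    """Gene ids whose [start_mb, end_mb] overlaps the interval (any overlap)."""
    g = genes[genes["chromosome"].astype(str) == str(interval.chromosome)]
    hit = g[(g["start_mb"] <= interval.upper_mb) & (g["end_mb"] >= interval.lower_mb)]
    hit = hit.sort_values(["start_mb", "gene_id"])
    return hit["gene_id"].astype(str).tolist()


def attach_genes(intervals: list[QTLInterval], genes: pd.DataFrame) -> list[QTLInterval]:
    for iv in intervals:
        iv.gene_ids_inside = genes_in_interval(iv, genes)
    return intervals


def intervals_frame(intervals: list[QTLInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chr": iv.chromosome,
                "peak_marker": iv.peak_marker_id,
                "peak_mb": iv.peak_mb,
                "peak_lrs": iv.peak_lrs,
                "peak_lod": iv.peak_lod,
                "class": iv.classification,
                "lo_mb": iv.lower_mb,
                "hi_mb": iv.upper_mb,
                "n_genes": len(iv.gene_ids_inside),
            }
            for iv in intervals
        ]
    )


def write_intervals(intervals: list[QTLInterval], path) -> None:
    intervals_frame(intervals).to_csv(path, sep="\t", index=False, float_format="%.10g")
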