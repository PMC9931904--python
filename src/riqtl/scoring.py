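"""Five-criterion additive candidate-gene scoring.

Each gene inside a QTL support interval is scored on five binary criteria
with unequal weights: heart expression (1), protein-altering coding variant
(2), cis-regulation (2), phenotype correlation (2), functional relevance (3).
The weighted flags are summed to a total in [0, 10]; genes totalling >= 6
(above the midpoint 5 of the score range) are selected as candidates.
Weights and the cutoff are configurable; these defaults are the published
convention this package reproduces.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import chrom_sort_key
from .io import DAMAGING_VARIANT_CLASSES

DEFAULT_WEIGHTS: dict[str, int] = {
    "expression": 1,
    "variant": 2,
    "cis": 2,
    "correlation": 2,
    "function": 3,
}
DEFAULT_CUTOFF = 6

CRITERIA = ("expression", "variant", "cis", "correlation", "function")


@dataclass
class CandidateScore:
    gene_id: str
    symbol: str
    chromosome: str
    start_mb: float
    score_expression: int
    score_variant: int
    score_cis: int
    score_correlation: int
    score_function: int
    total: int
    selected: bool


def score_gene(
    expression: bool,
    variant: bool,
    cis: bool,
    correlation: bool,
    function: bool,
    weights: Mapping[str, int] = DEFAULT_WEIGHTS,
    cutoff: int = DEFAULT_CUTOFF,
    gene_id: str = "",
    symbol: str = "",
    chromosome: str = "",
    start_mb: float = float("nan"),
) -> CandidateScore:
    """Weighted components and total for one gene's five criterion flags."""
    comp = {
        "expression": int(bool(expression)) * int(weights["expression"]),
        "variant": int(bool(variant)) * int(weights["variant"]),
        "cis": int(bool(cis)) * int(weights["cis"]),
        "correlation": int(bool(correlation)) * int(weights["correlation"]),
        "function": int(bool(function)) * int(weights["function"]),
    }
    total = sum(comp.values())
    return CandidateScore(
        gene_id=gene_id,
        symbol=symbol,
        chromosome=chromosome,
        start_mb=start_mb,
        score_expression=comp["expression"],
        score_variant=comp["variant"],
        score_cis=comp["cis"],
        score_correlation=comp["correlation"],
        score_function=comp["function"],
        total=total,
        selected=total >= cutoff,
    )


def _as_flag_map(flags) -> dict[str, bool]:
    if isinstance(flags, pd.Series):
        return {str(k): bool(v) for k, v in flags.items()}
    if isinstance(flags, pd.DataFrame):  # cis-call table
        return {str(r["gene_id"]): bool(r["is_cis"]) for _, r in flags.iterrows()}
    return {str(k): bool(v) for k, v in dict(flags).items()}


def assemble_scores(
    interval_genes: pd.DataFrame,
    expression_flags,
    variant_table: pd.DataFrame,
    cis_calls,
    correlation_flags,
    functional_set: Iterable[str],
    weights: Mapping[str, int] = DEFAULT_WEIGHTS,
    cutoff: int = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Score every interval gene; ranked by (total desc, chromosome, position).

    ``interval_genes`` is a gene table restricted to QTL intervals;
    ``variant_table`` contributes a flag when a gene has at least one
    protein-altering consequence; ``functional_set`` is the user-supplied
    functional-relevance gene-id list. Flags keyed by genes outside the
    interval list are ignored with a warning.
    """
    gene_ids = set(interval_genes["gene_id"].astype(str))
    expr = _as_flag_map(expression_flags)
    cis = _as_flag_map(cis_calls)
    corr = _as_flag_map(correlation_flags)
    functional = {str(g) for g in functional_set}
    damaging = variant_table[
        variant_table["consequence"].isin(DAMAGING_VARIANT_CLASSES)
    ]
    variant_genes = set(damaging["gene_id"].astype(str))

    stray = (set(expr) | set(cis) | set(corr)) - gene_ids
    if stray:
        warnings.warn(
            f"{len(stray)} flagged gene(s) not in any QTL interval; ignored",
            stacklevel=2,
        )

    rows = []
    for _, g in interval_genes.iterrows():
        gid = str(g["gene_id"])
        sc = score_gene(
            expression=expr.get(gid, False),
            variant=gid in variant_genes,
            cis=cis.get(gid, False),
            correlation=corr.get(gid, False),
            function=gid in functional,
            weights=weights,
            cutoff=cutoff,
            gene_id=gid,
            symbol=str(g.get("symbol", gid)),
            chromosome=str(g["chromosome"]),
            start_mb=float(g.get("start_mb", float("nan"))),
        )
        rows.append(vars(sc))
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "symbol",
            "chromosome",
            "start_mb",
            "score_expression",
            "score_variant",
            "score_cis",
            "score_correlation",
            "score_function",
            "total",
            "selected",
        ],
    )
    if out.empty:
        return out
    out["_ck"] = [chrom_sort_key(c) for c in out["chromosome"]]
    out = (
        out.sort_values(["total", "_ck", "start_mb"], ascending=[False, True, True])
        .drop(columns="_ck")
        .reset_index(drop=True)
    )
    return out


def category_counts(scores: pd.DataFrame) -> dict:
    """Per-chromosome and overall criterion tallies plus the all-five count."""
    flags = pd.DataFrame(
        {
            "chromosome": scores["chromosome"].astype(str),
            "expression": scores["score_expression"] > 0,
            "variant": scores["score_variant"] > 0,
            "cis": scores["score_cis"] > 0,
            "correlation": scores["score_correlation"] > 0,
            "function": scores["score_function"] > 0,
        }
    )
    flags["all_five"] = flags[list(CRITERIA)].all(axis=1)

    def tally(df: pd.DataFrame) -> dict:
        return {
            "n_genes": int(len(df)),
            **{c: int(df[c].sum()) for c in CRITERIA},
            "all_five": int(df["all_five"].sum()),
        }

    per_chrom = {
        chrom: tally(sub)
        for chrom, sub in flags.groupby("chromosome", sort=False)
    }
    per_chrom = dict(sorted(per_chrom.items(), key=lambda kv: chrom_sort_key(kv[0])))
    return {"overall": tally(flags), "per_chromosome": per_chrom}


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.10g")
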