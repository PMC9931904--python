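"""End-to-end orchestration: simulate/read -> scan -> peaks -> criteria -> score.

A run is fully described by a :class:`RunConfig` (loadable from YAML); its
outputs are a per-marker scan table, a QTL interval table, per-gene criterion
tables, the ranked candidate report, Figure-style category counts, and a
manifest recording the config hash, input checksums, library versions and
per-stage row counts. Identical config + inputs give byte-identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .cis import classify_cis_table
from .errors import RiqtlError
from .expression import correlation_criterion, expression_criterion
from .intervals import attach_genes, call_peaks, write_intervals
from .lmm import scan_trait, write_scan
from .scoring import (
    DEFAULT_CUTOFF,
    DEFAULT_WEIGHTS,
    assemble_scores,
    category_counts,
    write_scores,
)
from .simulate import SimConfig, simulate_all

log = logging.getLogger("riqtl")


@dataclass
class Thresholds:
    suggestive: float = 3.0
    significant: float = 4.0
    lod_drop: float = 1.5
    cis_window_mb: float = 5.0
    cis_lrs: float = 14.0
    expr_threshold: float = 2.0
    corr_alpha: float = 0.05
    score_cutoff: int = DEFAULT_CUTOFF
    maf: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise RiqtlError(f"threshold {name} must be positive")


@dataclass
class RunConfig:
    out_dir: str = "riqtl_run"
    trait: str = "Cu"
    loco: bool = True
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    # either simulate ...
    simulate: bool = True
    sim: SimConfig | None = None
    # ... or point at existing files
    genotypes: str | None = None
    phenotypes: str | None = None
    expression: str | None = None
    genes: str | None = None
    variants: str | None = None
    functional: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.thresholds, dict):
            self.thresholds = Thresholds(**self.thresholds)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if self.simulate and self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str, manifest: dict, t0: float, **counts) -> None:
    dt = time.perf_counter() - t0
    manifest["stages"].append({"stage": name, "seconds": round(dt, 3), **counts})
    log.info("stage %-12s %6.2fs %s", name, dt, counts)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns paths and in-memory results."""
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "versions": _versions(),
        "stages": [],
        "inputs": {},
    }

    # -- stage: inputs ------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulate:
        sim = simulate_all(config.sim)
        inp = out / "inputs"
        inp.mkdir(exist_ok=True)
        gio.write_genotypes(sim["genotypes"], inp / "genotypes.tsv")
        gio.write_phenotypes(sim["phenotypes"], inp / "phenotypes.csv")
        gio.write_expression(sim["expression"], inp / "expression.tsv")
        gio.write_genes(sim["genes"], inp / "genes.tsv")
        gio.write_variants(sim["variants"], inp / "variants.tsv")
        gio.write_functional(sim["functional"], inp / "functional.txt")
        gio.write_ground_truth(sim["ground_truth"].to_dict(), inp / "ground_truth.json")
        paths = {
            "genotypes": inp / "genotypes.tsv",
            "phenotypes": inp / "phenotypes.csv",
            "expression": inp / "expression.tsv",
            "genes": inp / "genes.tsv",
            "variants": inp / "variants.tsv",
            "functional": inp / "functional.txt",
        }
    else:
        needed = ("genotypes", "phenotypes", "expression", "genes", "variants", "functional")
        missing = [k for k in needed if getattr(config, k) is None]
        if missing:
            raise RiqtlError(f"inputs stage: missing input paths {missing}")
        paths = {k: Path(getattr(config, k)) for k in needed}

    try:
        geno = gio.read_genotypes(paths["genotypes"])
        pheno = gio.read_phenotypes(paths["phenotypes"])
        expr = gio.read_expression(paths["expression"])
        genes = gio.read_genes(paths["genes"])
        variants = gio.read_variants(paths["variants"])
        functional = gio.read_functional(paths["functional"])
    except RiqtlError as e:
        raise RiqtlError(f"inputs stage: {e}") from e
    manifest["inputs"] = {k: {"path": str(p), "sha256": _sha256(p)} for k, p in paths.items()}
    if config.trait not in pheno.columns:
        raise RiqtlError(
            f"inputs stage: trait {config.trait!r} not in {paths['phenotypes']}"
        )
    _stage("inputs", manifest, t0, strains=geno.n_strains, markers=geno.n_markers,
           genes=len(genes))

    # -- stage: scan --------------------------------------------------------
    t0 = time.perf_counter()
    try:
        scan = scan_trait(
            pheno[config.trait],
            geno,
            loco=config.loco,
            maf_min=th.maf,
            suggestive=th.suggestive,
            significant=th.significant,
            trait_name=config.trait,
        )
    except RiqtlError as e:
        raise RiqtlError(f"scan stage ({paths['genotypes']}): {e}") from e
    write_scan(scan, out / "scan.tsv")
    _stage("scan", manifest, t0, markers_tested=len(scan.table))

    # -- stage: peaks -------------------------------------------------------
    t0 = time.perf_counter()
    qtls = call_peaks(
        scan, suggestive=th.suggestive, significant=th.significant, lod_drop=th.lod_drop
    )
    attach_genes(qtls, genes)
    write_intervals(qtls, out / "qtls.tsv")
    interval_gene_ids = sorted({g for iv in qtls for g in iv.gene_ids_inside})
    interval_genes = genes[genes["gene_id"].astype(str).isin(interval_gene_ids)]
    _stage("peaks", manifest, t0, qtls=len(qtls), interval_genes=len(interval_genes))

    # -- stage: criteria ----------------------------------------------------
    t0 = time.perf_counter()
    expr_iv = expr.loc[expr.index.intersection(interval_genes["gene_id"].astype(str))]
    shared = gio.align_strains(
        geno.strain_ids, pheno.index, expr.columns, context="genotype/phenotype/expression"
    ) if len(expr_iv) else list(geno.strain_ids)
    expr_flags = expression_criterion(expr_iv, threshold=th.expr_threshold)
    corr_flags = (
        correlation_criterion(
            expr_iv[shared], pheno[config.trait].reindex(shared), alpha=th.corr_alpha
        )
        if len(expr_iv)
        else pd.Series(dtype=bool)
    )
    cis_calls = classify_cis_table(
        interval_genes,
        expr_iv,
        geno,
        window_mb=th.cis_window_mb,
        lrs_threshold=th.cis_lrs,
        loco=config.loco,
        maf_min=th.maf,
    )
    cis_calls.to_csv(out / "cis.tsv", sep="\t", index=False, float_format="%.10g")
    _stage(
        "criteria", manifest, t0,
        expressed=int(expr_flags.sum()),
        correlated=int(corr_flags.sum()),
        cis=int(cis_calls["is_cis"].sum()) if len(cis_calls) else 0,
    )

    # -- stage: score -------------------------------------------------------
    t0 = time.perf_counter()
    scores = assemble_scores(
        interval_genes,
        expr_flags,
        variants,
        cis_calls,
        corr_flags,
        functional,
        weights=DEFAULT_WEIGHTS,
        cutoff=th.score_cutoff,
    )
    write_scores(scores, out / "candidates.tsv")
    counts = category_counts(scores) if len(scores) else {"overall": {}, "per_chromosome": {}}
    with open(out / "category_counts.json", "w") as fh:
        json.dump(counts, fh, indent=2, sort_keys=True)
    _stage("score", manifest, t0, scored=len(scores),
           selected=int(scores["selected"].sum()) if len(scores) else 0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "out_dir": out,
        "scan": scan,
        "qtls": qtls,
        "scores": scores,
        "category_counts": counts,
        "manifest": manifest,
    }


def _versions() -> dict:
    import numpy, scipy, pandas  # noqa: PLC0415

    return {
        "riqtl": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
    }
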