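"""Synthetic two-founder recombinant-inbred (RI) panel with known ground truth.

The generator emulates a BXD-like panel: each strain's chromosome is a fixed
homozygous mosaic of two founder genomes ("B" and "D"). Recombination
breakpoints follow a Poisson process at rate

    (chromosome_length_cm / 100) * map_expansion_factor

per chromosome — the Haldane map expectation with the standard ~4x map
expansion of sib-mated RI lines as the default. Phenotypes combine planted
additive marker effects (in phenotype-SD units), a polygenic term drawn from
the realized kinship scaled to a target heritability, and i.i.d. noise;
replicate animals are drawn around strain means and averaged, because the
downstream scan operates on strain means. Expression traits are generated
directly on the log2(TPM+1)-like scale: per-gene baseline + optional additive
cis effect from the marker nearest the gene + noise. Annotations (gene
coordinates, coding-variant rows, functional-relevance list) are sparse
random subsets; every planted phenotype QTL also receives one fully loaded
"causal" gene (cis effect, variant, functional membership, high baseline) so
end-to-end candidate recovery can be checked against ground truth.

Every output is a pure function of the config (including its seed): reruns
are byte-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import rng_stream
from .errors import ConfigError, InputError
from .io import GenotypeMatrix
from .lmm import compute_kinship

_STREAM_GENO = 0
_STREAM_PHENO = 1
_STREAM_EXPR = 2
_STREAM_ANNOT = 3


@dataclass
class PlantedQTL:
    chromosome: str
    position_mb: float
    effect_sd: float  # additive effect in phenotype-SD units (allele D minus B)
    trait: str = "Cu"


@dataclass
class SimConfig:
    """All knobs of the synthetic panel; seed fully determines every output."""

    n_strains: int = 70
    n_chromosomes: int = 5
    markers_per_chromosome: int = 1000
    chromosome_length_cm: float = 100.0
    map_expansion_factor: float = 4.0
    mb_per_cm: float = 2.0  # genetic-to-physical scale used for the marker map
    planted_qtls: list[PlantedQTL] = field(
        default_factory=lambda: [PlantedQTL("1", 100.0, 1.5, "Cu")]
    )
    n_genes: int = 2000
    cis_eqtl_fraction: float = 0.15
    coding_variant_fraction: float = 0.13
    functional_fraction: float = 0.12
    heritability_polygenic: float = 0.30
    noise_sd: float | None = None  # None: fills the variance budget to 1
    replicates_per_strain: int = 4
    missing_fraction: float = 0.0
    intercept: float = 5.4
    expr_baseline_mean: float = 5.0
    expr_baseline_sd: float = 1.5
    expr_noise_sd: float = 0.5
    cis_effect_sd: float = 1.5  # cis effect in units of expr_noise_sd
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_qtls = [
            q if isinstance(q, PlantedQTL)
            else PlantedQTL(**q) if isinstance(q, dict)
            else PlantedQTL(*q)
            for q in self.planted_qtls
        ]
        for name in ("n_strains", "n_chromosomes", "markers_per_chromosome"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.chromosome_length_cm <= 0:
            raise ConfigError("chromosome_length_cm must be positive")
        if self.map_expansion_factor < 0:
            raise ConfigError("map_expansion_factor must be non-negative")
        for name in (
            "cis_eqtl_fraction",
            "coding_variant_fraction",
            "functional_fraction",
            "missing_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.heritability_polygenic < 1.0:
            raise ConfigError("heritability_polygenic must be in [0, 1)")
        if self.replicates_per_strain <= 0:
            raise ConfigError("replicates_per_strain must be positive")
        # variance budget: polygenic share + planted additive shares (each
        # e^2 * p(1-p) with p = 0.5) must leave room for noise
        if self.heritability_polygenic + self.qtl_variance_share() > 1.0:
            raise ConfigError(
                "heritability_polygenic + planted QTL variance share exceeds 1"
            )

    def qtl_variance_share(self) -> float:
        return sum(0.25 * q.effect_sd**2 for q in self.planted_qtls)

    def resolved_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return float(self.noise_sd)
        resid = 1.0 - self.heritability_polygenic - self.qtl_variance_share()
        return float(np.sqrt(max(resid, 0.01)))

    @property
    def chromosome_length_mb(self) -> float:
        return self.chromosome_length_cm * self.mb_per_cm

    def chromosome_names(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_qtls"] = [asdict(q) for q in self.planted_qtls]
        return d


@dataclass
class GroundTruth:
    """What was planted, so downstream recovery can be checked."""

    qtl_markers: dict = field(default_factory=dict)  # trait -> [marker ids]
    qtl_positions: dict = field(default_factory=dict)  # trait -> [(chrom, mb, effect)]
    causal_gene_ids: list = field(default_factory=list)
    cis_gene_effects: dict = field(default_factory=dict)  # gene -> effect (expr SD)
    criterion_flags: dict = field(default_factory=dict)  # gene -> planted flags

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        self.qtl_markers.update(other.qtl_markers)
        self.qtl_positions.update(other.qtl_positions)
        self.causal_gene_ids = sorted(set(self.causal_gene_ids) | set(other.causal_gene_ids))
        self.cis_gene_effects.update(other.cis_gene_effects)
        for g, flags in other.criterion_flags.items():
            self.criterion_flags.setdefault(g, {}).update(flags)
        return self

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Alternating founder-block mosaics with Poisson breakpoints."""
    rng = rng_stream(config.seed, _STREAM_GENO)
    L_mb = config.chromosome_length_mb
    M = config.markers_per_chromosome
    rate = (config.chromosome_length_cm / 100.0) * config.map_expansion_factor

    marker_pos = (np.arange(M) + 0.5) * (L_mb / M)
    chroms, positions, marker_ids = [], [], []
    for c in config.chromosome_names():
        chroms.extend([c] * M)
        positions.extend(marker_pos)
        marker_ids.extend(f"c{c}m{i + 1:04d}" for i in range(M))

    calls = np.empty((config.n_strains, config.n_chromosomes * M), dtype="<U1")
    founders = np.array(["B", "D"])
    for s in range(config.n_strains):
        for ci in range(config.n_chromosomes):
            n_bp = rng.poisson(rate)
            bps = np.sort(rng.uniform(0.0, L_mb, size=n_bp))
            start = rng.integers(0, 2)
            block = (np.searchsorted(bps, marker_pos, side="right") + start) % 2
            calls[s, ci * M : (ci + 1) * M] = founders[block]

    if config.missing_fraction > 0:
        mask = rng.random(calls.shape) < config.missing_fraction
        calls[mask] = "U"

    return GenotypeMatrix(
        strain_ids=[f"RIS{i + 1:03d}" for i in range(config.n_strains)],
        marker_ids=marker_ids,
        chromosome=np.asarray(chroms),
        position_mb=np.asarray(positions),
        calls=calls,
    )


def _marker_grid(config: SimConfig) -> np.ndarray:
    """Deterministic marker positions shared by all chromosomes."""
    M = config.markers_per_chromosome
    return (np.arange(M) + 0.5) * (config.chromosome_length_mb / M)


def _nearest_marker(geno: GenotypeMatrix, chrom: str, position_mb: float) -> int:
    on = np.flatnonzero(geno.chromosome == str(chrom))
    if len(on) == 0:
        raise ConfigError(f"planted chromosome {chrom!r} not in genotype map")
    j = on[int(np.argmin(np.abs(geno.position_mb[on] - position_mb)))]
    return int(j)


# ---------------------------------------------------------------------------
# phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(
    genotypes: GenotypeMatrix, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Strain-mean trait table (plus replicate n/SEM columns) and ground truth.

    Per-animal values are drawn around strain means with SD
    ``noise_sd * sqrt(replicates)`` and averaged, so strain means carry
    residual noise of SD ``noise_sd`` regardless of the replicate count.
    """
    rng = rng_stream(config.seed, _STREAM_PHENO)
    n = genotypes.n_strains
    L_mb = config.chromosome_length_mb
    truth = GroundTruth()

    traits = sorted({q.trait for q in config.planted_qtls}) or ["Cu"]
    numeric = genotypes.numeric()

    # one polygenic draw and one noise draw per trait, from the realized kinship
    K = compute_kinship(genotypes).values
    diag_mean = float(np.trace(K) / n)
    s, U = np.linalg.eigh(K / diag_mean if diag_mean > 0 else K)
    s = np.clip(s, 0.0, None)
    h2 = config.heritability_polygenic
    noise_sd = config.resolved_noise_sd()
    R = config.replicates_per_strain

    cols = {}
    for trait in traits:
        qtls = [q for q in config.planted_qtls if q.trait == trait]
        fixed = np.zeros(n)
        markers, placed = [], []
        for q in qtls:
            if not 0.0 <= q.position_mb <= L_mb:
                raise ConfigError(
                    f"planted position {q.position_mb} Mb outside chromosome "
                    f"{q.chromosome} span [0, {L_mb}]"
                )
            j = _nearest_marker(genotypes, q.chromosome, q.position_mb)
            fixed += q.effect_sd * numeric[:, j]
            markers.append(genotypes.marker_ids[j])
            placed.append([str(q.chromosome), float(q.position_mb), float(q.effect_sd)])
        polygenic = np.sqrt(h2) * (U @ (np.sqrt(s) * rng.standard_normal(n)))
        strain_mean = config.intercept + fixed + polygenic
        animals = strain_mean[:, None] + rng.normal(
            0.0, noise_sd * np.sqrt(R), size=(n, R)
        )
        cols[trait] = animals.mean(axis=1)
        cols[f"{trait}__n"] = np.full(n, R, dtype=float)
        cols[f"{trait}__sem"] = animals.std(axis=1, ddof=1) / np.sqrt(R) if R > 1 else np.zeros(n)
        truth.qtl_markers[trait] = markers
        truth.qtl_positions[trait] = placed

    pheno = pd.DataFrame(cols, index=pd.Index(genotypes.strain_ids, name="strain"))
    return pheno, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_VARIANT_CHOICES = ("non-synonymous", "frameshift", "stop gain", "stop loss")


def simulate_annotations(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, set[str], GroundTruth]:
    """Gene table, coding-variant table, functional list, ground truth.

    Genes are placed uniformly over the simulated chromosomes. One extra
    "causal" gene is planted at each distinct planted-QTL position, carrying
    a coding variant and functional membership.
    """
    if config.n_genes <= 0:
        raise ConfigError("n_genes must be positive")
    rng = rng_stream(config.seed, _STREAM_ANNOT)
    L_mb = config.chromosome_length_mb
    chrom_names = config.chromosome_names()
    truth = GroundTruth()

    n = config.n_genes
    chrom = rng.integers(0, config.n_chromosomes, size=n)
    start = rng.uniform(0.0, L_mb - 0.5, size=n)
    length = rng.uniform(0.005, 0.2, size=n)  # 5-200 kb gene bodies
    rows = [
        {
            "gene_id": f"G{i + 1:05d}",
            "symbol": f"Gene{i + 1}",
            "chromosome": chrom_names[chrom[i]],
            "start_mb": float(start[i]),
            "end_mb": float(start[i] + length[i]),
        }
        for i in range(n)
    ]
    seen = set()
    for q in config.planted_qtls:
        key = (str(q.chromosome), round(float(q.position_mb), 6))
        if key in seen:
            continue
        seen.add(key)
        gid = f"GCAUSAL_{q.trait}_{q.chromosome}"
        # center the causal gene on the marker nearest the planted position,
        # so its cis marker is exactly the phenotype QTL marker
        grid = _marker_grid(config)
        anchor = float(grid[int(np.argmin(np.abs(grid - float(q.position_mb))))])
        rows.append(
            {
                "gene_id": gid,
                "symbol": f"Causal{q.trait}{q.chromosome}",
                "chromosome": str(q.chromosome),
                "start_mb": max(anchor - 0.05, 0.0),
                "end_mb": min(anchor + 0.05, L_mb),
            }
        )
        truth.causal_gene_ids.append(gid)
    genes = pd.DataFrame(rows)

    variant_mask = rng.random(n) < config.coding_variant_fraction
    functional_mask = rng.random(n) < config.functional_fraction
    variant_ids = [rows[i]["gene_id"] for i in range(n) if variant_mask[i]]
    functional_ids = {rows[i]["gene_id"] for i in range(n) if functional_mask[i]}
    variant_ids += truth.causal_gene_ids
    functional_ids |= set(truth.causal_gene_ids)

    variants = pd.DataFrame(
        {
            "gene_id": variant_ids,
            "consequence": rng.choice(_VARIANT_CHOICES, size=len(variant_ids)),
        }
    )
    for gid in genes["gene_id"]:
        truth.criterion_flags.setdefault(gid, {})
        truth.criterion_flags[gid]["variant"] = gid in set(variant_ids)
        truth.criterion_flags[gid]["function"] = gid in functional_ids
    return genes, variants, functional_ids, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix,
    annotation: pd.DataFrame,
    config: SimConfig,
    causal_gene_ids: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, GroundTruth]:
    """log2(TPM+1)-like expression matrix with planted cis effects.

    A ``cis_eqtl_fraction`` of genes (always including any listed causal
    genes) get an additive effect of the dosage at the marker nearest the
    gene midpoint, sized ``cis_effect_sd`` in units of the expression noise
    SD. Values are clipped at 0 to stay on a log-like non-negative scale.
    """
    bad = set(annotation["chromosome"].astype(str)) - set(map(str, genotypes.chromosome))
    if bad:
        raise InputError(f"annotation chromosomes {sorted(bad)} absent from genotypes")
    rng = rng_stream(config.seed, _STREAM_EXPR)
    numeric = genotypes.numeric()
    truth = GroundTruth()

    gene_ids = annotation["gene_id"].astype(str).tolist()
    n_genes = len(gene_ids)
    n = genotypes.n_strains
    baseline = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd, size=n_genes)
    is_cis = rng.random(n_genes) < config.cis_eqtl_fraction
    causal = set(map(str, causal_gene_ids))
    is_cis |= np.asarray([g in causal for g in gene_ids])

    # causal genes are planted to satisfy every criterion: keep their
    # baseline clear of the mean-expression threshold
    for i, g in enumerate(gene_ids):
        if g in causal:
            baseline[i] = max(baseline[i], 4.0)

    values = np.empty((n_genes, n))
    mids = 0.5 * (
        annotation["start_mb"].to_numpy(dtype=float)
        + annotation["end_mb"].to_numpy(dtype=float)
    )
    effect = config.cis_effect_sd * config.expr_noise_sd
    for i, gid in enumerate(gene_ids):
        mean_i = baseline[i]
        row = np.full(n, mean_i)
        if is_cis[i]:
            j = _nearest_marker(
                genotypes, str(annotation["chromosome"].iloc[i]), float(mids[i])
            )
            row = row + effect * numeric[:, j]
            truth.cis_gene_effects[gid] = float(config.cis_effect_sd)
        row = row + rng.normal(0.0, config.expr_noise_sd, size=n)
        values[i] = np.clip(row, 0.0, None)
        truth.criterion_flags.setdefault(gid, {})
        truth.criterion_flags[gid]["cis"] = bool(is_cis[i])
        truth.criterion_flags[gid]["expression"] = bool(mean_i >= 2.0)

    expr = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=genotypes.strain_ids)
    expr.attrs["scale"] = "log2_tpm_plus1"
    return expr, truth


def simulate_all(config: SimConfig):
    """Run all four generators in dependency order; returns a dict of outputs."""
    geno = simulate_genotypes(config)
    pheno, t1 = simulate_phenotype(geno, config)
    genes, variants, functional, t2 = simulate_annotations(config)
    expr, t3 = simulate_expression(
        geno, genes, config, causal_gene_ids=tuple(t2.causal_gene_ids)
    )
    truth = GroundTruth().merge(t1).merge(t2).merge(t3)
    return {
        "genotypes": geno,
        "phenotypes": pheno,
        "genes": genes,
        "variants": variants,
        "functional": functional,
        "expression": expr,
        "ground_truth": truth,
    }
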