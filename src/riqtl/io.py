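"""Readers, writers and validated in-memory containers for every pipeline table.

File dialects
-------------
* genotypes -- GeneNetwork-style TSV: columns ``Chr, Locus[, cM], Mb`` followed
  by one column per strain holding single-character calls ``B/D/H/U``
  (maternal-founder homozygote, paternal-founder homozygote, heterozygote,
  unknown).
* phenotypes -- CSV with a ``strain`` column and one column per trait; optional
  per-trait ``<trait>__n`` and ``<trait>__sem`` replicate summaries.
* expression -- TSV, rows = genes, columns = ``gene_id`` then strains; an
  optional leading ``# scale: <counts|tpm|log2_tpm_plus1>`` comment records the
  unit; the reader may also be told explicitly.
* genes -- BED-like TSV ``gene_id, symbol, chromosome, start_mb, end_mb``
  (1-based inclusive megabase coordinates; no strand).
* variants -- TSV ``gene_id, consequence`` with a closed consequence
  vocabulary (non-synonymous, frameshift, stop gain, stop loss, other).
* functional -- plain text, one gene id per line; duplicates collapsed.

All numeric columns are written with 17 significant digits so that a
write -> read round trip reproduces the object bit-for-bit.
"""
from __future__ import annotations

import io as _stdio
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, order_chromosomes
from .errors import AlignmentError, ParseError, SchemaError

CALL_CODES = ("B", "D", "H", "U")
#: numeric view of a call: founder B -> 0, founder D -> 1, het -> 0.5
CALL_NUMERIC = {"B": 0.0, "D": 1.0, "H": 0.5}

VARIANT_CLASSES = ("non-synonymous", "frameshift", "stop gain", "stop loss", "other")
#: consequence classes counted as protein-altering by the scoring module
DAMAGING_VARIANT_CLASSES = frozenset(
    {"non-synonymous", "frameshift", "stop gain", "stop loss"}
)

_FLOAT_FMT = "%.17g"


@dataclass
class GenotypeMatrix:
    """Strains x markers call matrix with its marker map.

    ``calls`` holds single-character codes; :meth:`numeric` exposes the
    0/1/0.5 dosage view with unknown calls imputed to the column mean.
    """

    strain_ids: list[str]
    marker_ids: list[str]
    chromosome: np.ndarray  # (m,) str
    position_mb: np.ndarray  # (m,) float
    calls: np.ndarray  # (n_strains, m) '<U1'

    def __post_init__(self) -> None:
        self.strain_ids = [str(s) for s in self.strain_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.chromosome = np.asarray(self.chromosome, dtype=str)
        self.position_mb = np.asarray(self.position_mb, dtype=float)
        self.calls = np.asarray(self.calls, dtype="<U1")
        n, m = self.calls.shape
        if n != len(self.strain_ids) or m != len(self.marker_ids):
            raise ParseError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.marker_ids)} markers"
            )
        if len(set(self.marker_ids)) != m:
            dupes = sorted({x for x in self.marker_ids if self.marker_ids.count(x) > 1})
            raise ParseError(f"duplicate marker ids: {dupes[:10]}")
        if len(set(self.strain_ids)) != n:
            raise ParseError("duplicate strain ids")
        bad = ~np.isin(self.calls, CALL_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"unknown call code {self.calls[i, j]!r} at marker "
                f"{self.marker_ids[j]!r}, strain {self.strain_ids[i]!r}"
            )
        for chrom in set(self.chromosome):
            pos = self.position_mb[self.chromosome == chrom]
            if not np.all(np.diff(pos) > 0):
                raise ParseError(
                    f"marker positions not strictly increasing on chromosome {chrom}"
                )

    # -- views -------------------------------------------------------------
    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosomes(self) -> list[str]:
        return order_chromosomes(self.chromosome)

    def numeric(self) -> np.ndarray:
        """Float dosage matrix in [0, 1]; U imputed to the column mean.

        A column that is entirely U imputes to 0.5 (no information either way).
        """
        num = np.empty(self.calls.shape, dtype=float)
        for code, val in CALL_NUMERIC.items():
            num[self.calls == code] = val
        unknown = self.calls == "U"
        if unknown.any():
            num[unknown] = np.nan
            col_mean = np.nanmean(
                np.where(unknown, np.nan, num), axis=0, keepdims=True
            )
            col_mean = np.where(np.isnan(col_mean), 0.5, col_mean)
            num = np.where(unknown, np.broadcast_to(col_mean, num.shape), num)
        return num

    def subset_strains(self, strain_ids) -> "GenotypeMatrix":
        idx = [self.strain_ids.index(str(s)) for s in strain_ids]
        return GenotypeMatrix(
            strain_ids=[self.strain_ids[i] for i in idx],
            marker_ids=list(self.marker_ids),
            chromosome=self.chromosome.copy(),
            position_mb=self.position_mb.copy(),
            calls=self.calls[idx, :].copy(),
        )

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            strain_ids=list(self.strain_ids),
            marker_ids=[m for m, k in zip(self.marker_ids, mask) if k],
            chromosome=self.chromosome[mask],
            position_mb=self.position_mb[mask],
            calls=self.calls[:, mask],
        )

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chromosome": self.chromosome,
                "position_mb": self.position_mb,
            }
        )

    def __eq__(self, other) -> bool:  # round-trip identity support
        return (
            isinstance(other, GenotypeMatrix)
            and self.strain_ids == other.strain_ids
            and self.marker_ids == other.marker_ids
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position_mb, other.position_mb)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, dialect: str = "genonet") -> GenotypeMatrix:
    """Parse a genotype TSV; report offending rows with line numbers."""
    if dialect != "genonet":
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    if not lines:
        raise SchemaError(f"{path}: empty genotype file")
    header = lines[0].split("\t")
    if header[:2] != ["Chr", "Locus"]:
        raise SchemaError(f"{path}: header must start with 'Chr\\tLocus', got {header[:2]}")
    has_cm = len(header) > 2 and header[2] == "cM"
    mb_col = 3 if has_cm else 2
    if len(header) <= mb_col or header[mb_col] != "Mb":
        raise SchemaError(f"{path}: missing 'Mb' column in header")
    strains = header[mb_col + 1 :]
    if not strains:
        raise SchemaError(f"{path}: no strain columns")

    marker_ids, chroms, pos, calls, problems = [], [], [], [], []
    for lineno, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != len(header):
            problems.append(f"line {lineno}: expected {len(header)} fields, got {len(parts)}")
            continue
        chrom, locus = parts[0], parts[1]
        try:
            mb = float(parts[mb_col])
        except ValueError:
            problems.append(f"line {lineno}: non-numeric Mb {parts[mb_col]!r}")
            continue
        row = parts[mb_col + 1 :]
        bad = [(s, c) for s, c in zip(strains, row) if c not in CALL_CODES]
        if bad:
            s, c = bad[0]
            problems.append(
                f"line {lineno}: unknown call {c!r} at marker {locus!r}, strain {s!r}"
            )
            continue
        marker_ids.append(locus)
        chroms.append(chrom)
        pos.append(mb)
        calls.append(row)
    if problems:
        raise ParseError(f"{path}: " + "; ".join(problems[:20]))
    calls_arr = np.asarray(calls, dtype="<U1").T if calls else np.empty((len(strains), 0), "<U1")
    return GenotypeMatrix(
        strain_ids=strains,
        marker_ids=marker_ids,
        chromosome=np.asarray(chroms),
        position_mb=np.asarray(pos),
        calls=calls_arr,
    )


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(["Chr", "Locus", "Mb", *geno.strain_ids]) + "\n")
        for j, marker in enumerate(geno.marker_ids):
            row = [
                str(geno.chromosome[j]),
                marker,
                _FLOAT_FMT % geno.position_mb[j],
                *geno.calls[:, j],
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> pd.DataFrame:
    """Strain-level trait table indexed by strain id; trait columns are floats."""
    df = pd.read_csv(path)
    if "strain" not in df.columns:
        raise SchemaError(f"{path}: phenotype CSV must have a 'strain' column")
    trait_cols = [c for c in df.columns if c != "strain"]
    if not trait_cols:
        raise SchemaError(f"{path}: phenotype CSV has no trait columns")
    if df["strain"].duplicated().any():
        dupes = df.loc[df["strain"].duplicated(), "strain"].tolist()
        raise ParseError(f"{path}: duplicate strain ids {dupes[:10]}")
    df = df.set_index(df["strain"].astype(str)).drop(columns="strain")
    df.index.name = "strain"
    return df.astype(float)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    out = pheno.copy()
    out.index.name = "strain"
    out.to_csv(path, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def read_expression(path, scale: str | None = None) -> "pd.DataFrame":
    """Gene x strain matrix; returns a DataFrame with ``.attrs['scale']`` set.

    The declared scale comes from, in order of precedence: the ``scale``
    argument, a ``# scale: ...`` comment line, the default ``log2_tpm_plus1``.
    """
    path = Path(path)
    file_scale = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# scale:"):
            file_scale = first.split(":", 1)[1].strip()
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_stdio.StringIO(body), sep="\t")
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: expression TSV must have a 'gene_id' column")
    df = df.set_index(df["gene_id"].astype(str)).drop(columns="gene_id").astype(float)
    df.index.name = "gene_id"
    df.columns = [str(c) for c in df.columns]
    df.attrs["scale"] = scale or file_scale or "log2_tpm_plus1"
    return df


def write_expression(expr: pd.DataFrame, path, scale: str | None = None) -> None:
    scale = scale or expr.attrs.get("scale", "log2_tpm_plus1")
    with open(path, "w") as fh:
        fh.write(f"# scale: {scale}\n")
        out = expr.copy()
        out.index.name = "gene_id"
        out.to_csv(fh, sep="\t", float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# genes / variants / functional list
# ---------------------------------------------------------------------------

GENE_COLUMNS = ["gene_id", "symbol", "chromosome", "start_mb", "end_mb"]


def read_genes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: gene table missing columns {missing}")
    df = df[GENE_COLUMNS].copy()
    df["start_mb"] = df["start_mb"].astype(float)
    df["end_mb"] = df["end_mb"].astype(float)
    bad = df[df["start_mb"] > df["end_mb"]]
    if len(bad):
        raise ParseError(
            f"{path}: start_mb > end_mb for genes {bad['gene_id'].tolist()[:10]}"
        )
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids")
    return df


def write_genes(genes: pd.DataFrame, path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_variants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "consequence"):
        if col not in df.columns:
            raise SchemaError(f"{path}: variant table missing column {col!r}")
    bad = sorted(set(df["consequence"]) - set(VARIANT_CLASSES))
    if bad:
        raise ParseError(
            f"{path}: unknown consequence classes {bad}; allowed: {list(VARIANT_CLASSES)}"
        )
    return df[["gene_id", "consequence"]].copy()


def write_variants(variants: pd.DataFrame, path) -> None:
    variants[["gene_id", "consequence"]].to_csv(path, sep="\t", index=False)


def read_functional(path) -> set[str]:
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def write_functional(gene_ids, path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(map(str, gene_ids))):
            fh.write(g + "\n")


# ---------------------------------------------------------------------------
# ground truth (simulation bookkeeping)
# ---------------------------------------------------------------------------

def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)


def read_ground_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_strains(*id_lists, context: str = "inputs") -> list[str]:
    """Intersection of strain id sets, in the order of the first list.

    Warns when inputs disagree; raises :class:`AlignmentError` when the
    intersection is empty. Downstream statistics depend only on the id set,
    never on file row order.
    """
    sets = [set(map(str, ids)) for ids in id_lists]
    common = set.intersection(*sets) if sets else set()
    if not common:
        raise AlignmentError(f"no strains shared across {context}")
    n_union = len(set.union(*sets))
    if len(common) < n_union:
        warnings.warn(
            f"{context}: {n_union - len(common)} strain(s) absent from some inputs; "
            f"using the {len(common)}-strain intersection",
            stacklevel=2,
        )
    return [s for s in map(str, id_lists[0]) if s in common]
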