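"""Single-variance-component linear mixed model genome scan.

Model
-----
For a strain-mean trait vector ``y`` (n strains) the null model is

    y = 1*mu + g + e,    g ~ N(0, sg2 * K),    e ~ N(0, se2 * I)

and the per-marker alternative adds the marker dosage x as a fixed effect.
``K`` is the realized genomic relationship ``W W' / m`` over column-centered
dosages, computed leave-one-chromosome-out (LOCO) so a marker is never
corrected against its own chromosome. Both models are fitted by full maximum
likelihood: after one eigendecomposition ``K = U S U'`` per kinship, the
likelihood concentrates to a 1-D problem in ``delta = se2/sg2``, optimized on
a 100-point log grid on [1e-5, 1e5] refined by golden-section search.

The association statistic is the likelihood-ratio statistic
``LRS = 2*(ll_alt - ll_null)`` (chi-square, 1 df), with the conventional
conversion ``LOD = LRS / 4.61``. ML rather than REML is used throughout so
that likelihoods of models with different fixed effects are directly
comparable in the ratio; this is an intentional, documented choice.

Markers with minor allele frequency below 0.05 (computed on the dosage view
over the strains actually analyzed) are excluded before testing.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

from .errors import (
    DegenerateInputError,
    DomainError,
    EmptyScanError,
    InputError,
)
from .io import GenotypeMatrix
from ._util import order_chromosomes

#: LRS units per LOD unit in the conventional conversion LOD = LRS/4.61
LRS_PER_LOD = 4.61

_DELTA_GRID = np.logspace(-5, 5, 100)
_LOG_DELTA_GRID = np.log(_DELTA_GRID)
_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-12
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0
# golden-section iterations: initial log-delta bracket width ~0.47 shrinks by
# invphi per step; 45 steps reach ~1e-9 relative precision in delta
_GOLDEN_ITER = 45


def lod_from_lrs(lrs):
    """LOD = LRS / 4.61 (elementwise); domain error on negative input."""
    lrs = np.asarray(lrs, dtype=float)
    if np.any(lrs < 0):
        raise DomainError("LRS must be non-negative")
    out = lrs / LRS_PER_LOD
    return float(out) if out.ndim == 0 else out


def lrs_from_lod(lod):
    """Inverse of :func:`lod_from_lrs`; exact round trip."""
    lod = np.asarray(lod, dtype=float)
    if np.any(lod < 0):
        raise DomainError("LOD must be non-negative")
    out = lod * LRS_PER_LOD
    return float(out) if out.ndim == 0 else out


@dataclass
class KinshipMatrix:
    """Centered genomic relationship matrix, optionally leave-one-chromosome-out."""

    strain_ids: list[str]
    values: np.ndarray
    excluded_chromosome: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strain_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match strain count")

    def is_psd(self, tol: float = 1e-8) -> bool:
        return bool(np.linalg.eigvalsh(self.values).min() >= -tol)


@dataclass
class LMMFit:
    """Maximum-likelihood fit of the one-variance-component model."""

    beta_hat: np.ndarray
    sigma_g2: float
    sigma_e2: float
    delta: float  # sigma_e2 / sigma_g2
    log_likelihood: float
    boundary: bool = False  # delta optimizer ended on the grid boundary
    degenerate: bool = False  # trait (near-)constant; variances floored


@dataclass
class ScanResult:
    """Per-marker association statistics for one trait."""

    trait: str
    table: pd.DataFrame  # marker, chromosome, position_mb, maf, lrs, lod, p, neg_log10_p
    loco: bool
    suggestive: float = 3.0
    significant: float = 4.0

    def top_marker(self) -> pd.Series:
        """Genome-wide top row; LRS ties broken by chromosome order then Mb."""
        t = self.table
        best = t[t["lrs"] == t["lrs"].max()]
        if len(best) > 1:
            from ._util import chrom_sort_key

            best = best.assign(_k=[chrom_sort_key(c) for c in best["chromosome"]])
            best = best.sort_values(["_k", "position_mb"]).drop(columns="_k")
        return best.iloc[0]


def compute_kinship(
    genotypes: GenotypeMatrix, exclude_chromosome: str | None = None
) -> KinshipMatrix:
    """K = W W'/m over column-centered dosages of the included markers."""
    if genotypes.n_strains < 2:
        raise DegenerateInputError("kinship needs at least 2 strains")
    mask = np.ones(genotypes.n_markers, dtype=bool)
    if exclude_chromosome is not None:
        mask = genotypes.chromosome != str(exclude_chromosome)
    m = int(mask.sum())
    if m == 0:
        raise DegenerateInputError(
            f"no markers left after excluding chromosome {exclude_chromosome!r}"
        )
    W = genotypes.numeric()[:, mask]
    W = W - W.mean(axis=0, keepdims=True)
    K = (W @ W.T) / m
    return KinshipMatrix(
        strain_ids=list(genotypes.strain_ids),
        values=K,
        excluded_chromosome=None if exclude_chromosome is None else str(exclude_chromosome),
    )


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------

def _eigendecompose(K: np.ndarray):
    s, U = np.linalg.eigh(K)
    return np.clip(s, 0.0, None), U


def _ml_loglik(delta: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """Profile ML log-likelihood at a given delta (beta, sg2 concentrated out)."""
    n = yt.shape[0]
    w = 1.0 / (s + delta)
    Xw = Xt * w[:, None]
    A = Xw.T @ Xt
    b = Xw.T @ yt
    beta = np.linalg.solve(A, b)
    rss = float(w @ (yt * yt)) - float(beta @ b)
    sg2 = max(rss / n, _VAR_FLOOR)
    return -0.5 * n * (_LOG2PI + 1.0 + np.log(sg2)) - 0.5 * float(np.log(s + delta).sum())


def _ml_beta_sg2(delta: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    n = yt.shape[0]
    w = 1.0 / (s + delta)
    Xw = Xt * w[:, None]
    beta = np.linalg.solve(Xw.T @ Xt, Xw.T @ yt)
    rss = float(w @ (yt * yt)) - float(beta @ (Xw.T @ yt))
    return beta, max(rss / n, _VAR_FLOOR)


def _optimize_delta(s, yt, Xt):
    """Grid scan over delta then bounded refinement; returns (delta, ll, boundary)."""
    lls = np.array([_ml_loglik(d, s, yt, Xt) for d in _DELTA_GRID])
    k = int(np.argmax(lls))
    boundary = k in (0, len(_DELTA_GRID) - 1)
    if boundary:
        return float(_DELTA_GRID[k]), float(lls[k]), True
    res = optimize.minimize_scalar(
        lambda ld: -_ml_loglik(float(np.exp(ld)), s, yt, Xt),
        bounds=(_LOG_DELTA_GRID[k - 1], _LOG_DELTA_GRID[k + 1]),
        method="bounded",
        options={"xatol": 1e-9},
    )
    delta = float(np.exp(res.x))
    ll = float(-res.fun)
    if ll < lls[k]:  # refinement can only improve; keep the grid point otherwise
        delta, ll = float(_DELTA_GRID[k]), float(lls[k])
    return delta, ll, False


def fit_null(trait, K: KinshipMatrix) -> LMMFit:
    """ML fit of the intercept-only mixed model y = 1*mu + g + e.

    ``trait`` may be a pandas Series indexed by strain id (aligned to K) or a
    plain vector already in K's strain order.
    """
    if isinstance(trait, pd.Series):
        y = trait.reindex(K.strain_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if y.shape[0] != len(K.strain_ids):
        raise InputError("trait length does not match kinship strains")
    if not np.all(np.isfinite(y)):
        raise InputError("trait contains non-finite values")
    if y.shape[0] < 3:
        raise DegenerateInputError("need at least 3 strains to fit the mixed model")

    s, U = _eigendecompose(K.values)
    yt = U.T @ y
    Xt = U.T @ np.ones((y.shape[0], 1))

    degenerate = float(np.var(y)) < 1e-20
    delta, ll, boundary = _optimize_delta(s, yt, Xt)
    beta, sg2 = _ml_beta_sg2(delta, s, yt, Xt)
    if boundary:
        warnings.warn("delta optimizer hit the grid boundary", stacklevel=2)
    return LMMFit(
        beta_hat=beta,
        sigma_g2=sg2,
        sigma_e2=delta * sg2,
        delta=delta,
        log_likelihood=ll,
        boundary=boundary,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# vectorized per-marker alternative fits
# ---------------------------------------------------------------------------

def _marker_lls_at_delta(delta, s, yt, ot, Gt, G2):
    """Profile log-likelihood of [1, x] models for every marker.

    ``delta`` is either a scalar (grid stage) or a per-marker vector (golden
    stage). Normal equations of the 2-column weighted regression are solved in
    closed form, vectorized across markers.
    """
    n = yt.shape[0]
    if np.ndim(delta) == 0:
        w = 1.0 / (s + delta)  # (n,)
        a11 = float(w @ (ot * ot))
        b1 = float(w @ (ot * yt))
        syy = float(w @ (yt * yt))
        wo = w * ot
        wy = w * yt
        a12 = wo @ Gt
        a22 = w @ G2
        b2 = wy @ Gt
        logdet = float(np.log(s + delta).sum())
    else:
        W = 1.0 / (s[:, None] + np.asarray(delta)[None, :])  # (n, m)
        a11 = (ot * ot) @ W
        b1 = (ot * yt) @ W
        syy = (yt * yt) @ W
        a12 = np.einsum("i,im,im->m", ot, W, Gt)
        a22 = (W * G2).sum(axis=0)
        b2 = np.einsum("i,im,im->m", yt, W, Gt)
        logdet = -np.log(W).sum(axis=0)
    det = a11 * a22 - a12 * a12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta1 = (a22 * b1 - a12 * b2) / det
        beta2 = (a11 * b2 - a12 * b1) / det
        rss = syy - beta1 * b1 - beta2 * b2
    sg2 = np.maximum(np.nan_to_num(rss, nan=np.inf) / n, _VAR_FLOOR)
    return -0.5 * n * (_LOG2PI + 1.0 + np.log(sg2)) - 0.5 * logdet


def _fit_markers(s, yt, ot, Gt):
    """Per-marker maximized alternative log-likelihoods (grid + golden section)."""
    m = Gt.shape[1]
    G2 = Gt * Gt
    best_ll = np.full(m, -np.inf)
    best_k = np.zeros(m, dtype=int)
    for k, d in enumerate(_DELTA_GRID):
        ll = _marker_lls_at_delta(float(d), s, yt, ot, Gt, G2)
        upd = ll > best_ll
        best_ll[upd] = ll[upd]
        best_k[upd] = k

    lo = _LOG_DELTA_GRID[np.maximum(best_k - 1, 0)]
    hi = _LOG_DELTA_GRID[np.minimum(best_k + 1, len(_DELTA_GRID) - 1)]
    a, b = lo.copy(), hi.copy()
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = _marker_lls_at_delta(np.exp(x1), s, yt, ot, Gt, G2)
    f2 = _marker_lls_at_delta(np.exp(x2), s, yt, ot, Gt, G2)
    for _ in range(_GOLDEN_ITER):
        cond = f1 > f2
        b = np.where(cond, x2, b)
        a = np.where(cond, a, x1)
        x_keep = np.where(cond, x1, x2)
        f_keep = np.where(cond, f1, f2)
        x_new = np.where(cond, b - _INVPHI * (b - a), a + _INVPHI * (b - a))
        f_new = _marker_lls_at_delta(np.exp(x_new), s, yt, ot, Gt, G2)
        x1 = np.where(cond, x_new, x_keep)
        f1 = np.where(cond, f_new, f_keep)
        x2 = np.where(cond, x_keep, x_new)
        f2 = np.where(cond, f_keep, f_new)
    return np.maximum(best_ll, np.maximum(f1, f2))


# ---------------------------------------------------------------------------
# genome scan
# ---------------------------------------------------------------------------

def scan_trait(
    trait: pd.Series,
    genotypes: GenotypeMatrix,
    loco: bool = True,
    kinship: KinshipMatrix | None = None,
    maf_min: float = 0.05,
    suggestive: float = 3.0,
    significant: float = 4.0,
    trait_name: str | None = None,
) -> ScanResult:
    """Mixed-model association scan of one strain-mean trait.

    Parameters
    ----------
    trait : Series indexed by strain id (NaN entries dropped).
    loco : use leave-one-chromosome-out kinship (ignored when ``kinship`` is
        supplied, in which case that single matrix corrects every marker —
        useful for oracle comparisons, e.g. a zero matrix reduces the scan to
        ordinary least-squares likelihood-ratio tests).
    maf_min : markers with minor allele frequency below this are dropped.
    """
    if not isinstance(trait, pd.Series):
        trait = pd.Series(np.asarray(trait, dtype=float), index=genotypes.strain_ids)
    name = trait_name or (trait.name if trait.name is not None else "trait")
    trait = trait.dropna()
    if not np.all(np.isfinite(trait.to_numpy(dtype=float))):
        raise InputError("trait contains non-finite values")
    keep = [s for s in genotypes.strain_ids if s in set(trait.index.astype(str))]
    if len(keep) < 3:
        raise DegenerateInputError("fewer than 3 strains with trait data")
    if len(keep) < 10:
        warnings.warn(
            f"only {len(keep)} strains with trait data; scan will be underpowered",
            stacklevel=2,
        )
    geno = genotypes.subset_strains(keep) if len(keep) < genotypes.n_strains else genotypes
    y = trait.reindex(geno.strain_ids).to_numpy(dtype=float)
    n = y.shape[0]

    X = geno.numeric()
    p = X.mean(axis=0)
    maf = np.minimum(p, 1.0 - p)
    keep_m = maf >= maf_min - 1e-12
    if not keep_m.any():
        raise EmptyScanError("all markers removed by the MAF filter")
    geno_f = geno.subset_markers(keep_m)
    Xf = X[:, keep_m]
    maf_f = maf[keep_m]

    ones = np.ones(n)
    rows = []
    if kinship is not None:
        groups = [(None, np.ones(geno_f.n_markers, dtype=bool), kinship)]
    elif loco:
        groups = [
            (c, geno_f.chromosome == c, compute_kinship(geno, exclude_chromosome=c))
            for c in geno_f.chromosomes()
        ]
    else:
        K_all = compute_kinship(geno)
        groups = [(None, np.ones(geno_f.n_markers, dtype=bool), K_all)]

    lrs_all = np.empty(geno_f.n_markers)
    for _, mask, K in groups:
        if kinship is not None and K.values.shape[0] != n:
            K = KinshipMatrix(
                strain_ids=list(geno_f.strain_ids),
                values=np.asarray(K.values)[
                    np.ix_(
                        [K.strain_ids.index(s) for s in geno_f.strain_ids],
                        [K.strain_ids.index(s) for s in geno_f.strain_ids],
                    )
                ],
                excluded_chromosome=K.excluded_chromosome,
            )
        s, U = _eigendecompose(K.values)
        yt = U.T @ y
        ot = U.T @ ones
        _, ll_null, _ = _optimize_delta(s, yt, Xt=np.column_stack([ot]))
        Gt = U.T @ Xf[:, mask]
        ll_alt = _fit_markers(s, yt, ot, Gt)
        lrs_all[mask] = np.clip(2.0 * (ll_alt - ll_null), 0.0, None)

    lod = lrs_all / LRS_PER_LOD
    pvals = chi2.sf(lrs_all, df=1)
    neg_log10_p = -chi2.logsf(lrs_all, df=1) / np.log(10.0)
    table = pd.DataFrame(
        {
            "marker": geno_f.marker_ids,
            "chromosome": geno_f.chromosome,
            "position_mb": geno_f.position_mb,
            "maf": maf_f,
            "lrs": lrs_all,
            "lod": lod,
            "p": pvals,
            "neg_log10_p": neg_log10_p,
        }
    )
    return ScanResult(
        trait=str(name),
        table=table,
        loco=loco and kinship is None,
        suggestive=suggestive,
        significant=significant,
    )


def write_scan(scan: ScanResult, path) -> None:
    out = scan.table.rename(
        columns={
            "chromosome": "chr",
            "position_mb": "mb",
            "neg_log10_p": "neglog10p",
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path, trait: str = "trait") -> ScanResult:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    df = df.rename(
        columns={"chr": "chromosome", "mb": "position_mb", "neglog10p": "neg_log10_p"}
    )
    return ScanResult(trait=trait, table=df, loco=True)
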