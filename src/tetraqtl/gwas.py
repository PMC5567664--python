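"""Kinship-corrected single-marker mixed-model association on tetraploid dosages.

The model for a phenotype vector ``y`` over ``n`` individuals is

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with ``K`` a marker-derived realized-relationship matrix and each SNP
entering ``X`` as an additive numeric dosage (0-4 alt copies). Estimation
follows the eigendecomposition trick: ``K = U diag(lambda) U^T`` is
computed once, the variance-ratio ``delta = se2 / sg2`` is estimated on
the null model by maximum likelihood over a log-spaced grid with
golden-section refinement, and every SNP is then tested by generalized
least squares in the rotated space with weights ``1 / (lambda_i + delta)``
("population parameters previously determined" approximation: the null
delta is reused across SNPs). Wald p-values come from a t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, DegenerateGroupError, NumericError
from .io import _atomic_path
from .simulate import PLOIDY, VariantSite

__all__ = [
    "kinship",
    "select_kinship_markers",
    "MixedModelGWAS",
    "GWASResults",
    "genomic_inflation",
    "threshold_hits",
]

_PSD_TOL = 1e-8
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


def kinship(dosages: np.ndarray, marker_subset: Sequence[int] | None = None) -> np.ndarray:
    """Realized-relationship matrix from tetraploid dosages.

    Markers are centered by their mean dosage and the cross-product is
    normalized by ``sum_j ploidy * p_j * (1 - p_j)`` with
    ``p_j = mean dosage / ploidy`` (the VanRaden construction generalized
    to ploidy 4), so an outbred, unrelated population has diagonal ~1.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise DataError("dosages must be a (individuals x markers) matrix")
    if marker_subset is not None:
        d = d[:, np.asarray(marker_subset, dtype=int)]
    if d.shape[1] < 2:
        raise ConfigurationError("need at least 2 markers for kinship")
    p = d.mean(axis=0) / PLOIDY
    poly = d.var(axis=0) > 0
    if not poly.any():
        raise NumericError("all kinship markers are monomorphic")
    d = d[:, poly]
    p = p[poly]
    z = d - PLOIDY * p
    c = float(np.sum(PLOIDY * p * (1.0 - p)))
    return (z @ z.T) / c


def select_kinship_markers(
    sites: Sequence[VariantSite],
    n_markers: int,
) -> np.ndarray:
    """Indices of ``n_markers`` SNPs spread evenly along the genome.

    Markers are allocated to chromosomes proportionally to their SNP count
    and picked at equally spaced ranks within each chromosome, mirroring a
    selection 'for equal distribution' over the physical map.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        by_chrom.setdefault(s.chrom, []).append(i)
    total = len(sites)
    if n_markers > total:
        raise ConfigurationError(f"asked for {n_markers} markers but only {total} sites")
    chosen: list[int] = []
    chroms = sorted(by_chrom)
    quotas = [len(by_chrom[c]) * n_markers / total for c in chroms]
    counts = [int(q) for q in quotas]
    remainder = n_markers - sum(counts)
    order = np.argsort([c - q for c, q in zip(counts, quotas)], kind="stable")
    for k in order[:remainder]:
        counts[k] += 1
    for chrom, k in zip(chroms, counts):
        ix = by_chrom[chrom]
        if k == 0:
            continue
        ranks = np.linspace(0, len(ix) - 1, k).round().astype(int)
        chosen.extend(ix[r] for r in np.unique(ranks))
    return np.array(sorted(chosen), dtype=int)


def _null_loglik(delta: float, lam: np.ndarray, yr: np.ndarray, xr: np.ndarray) -> float:
    """Profiled ML log-likelihood of the null model at a given delta."""
    w = 1.0 / (lam + delta)
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    beta = np.linalg.solve(xtwx, xtwy)
    r = yr - xr @ beta
    n = yr.size
    sg2 = float(np.sum(w * r * r)) / n
    return -0.5 * (n * np.log(2 * np.pi * sg2) + float(np.sum(np.log(lam + delta))) + n)


def _golden_section(f, lo: float, hi: float, tol: float = 1e-4) -> float:
    """Maximize ``f`` over [lo, hi] (log10-delta space)."""
    invphi = (np.sqrt(5.0) - 1) / 2
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2


class MixedModelGWAS:
    """Single-marker mixed-model association scan.

    Parameters
    ----------
    phenotype
        Length-n trait vector (adjusted entry means); NaNs drop the
        corresponding individuals from the scan.
    dosages
        (n x m) tetraploid dosage matrix, entries in {0..4}.
    K
        n x n kinship matrix; required for ``method="mlm"``.
    sites
        Optional variant annotation aligned with the dosage columns.
    """

    def __init__(
        self,
        phenotype: np.ndarray | pd.Series,
        dosages: np.ndarray,
        K: np.ndarray | None = None,
        sites: Sequence[VariantSite] | None = None,
        min_individuals: int = 10,
    ):
        y = np.asarray(phenotype, dtype=float)
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2 or y.size != d.shape[0]:
            raise DataError("phenotype length must match dosage rows")
        keep = np.isfinite(y)
        if keep.sum() < min_individuals:
            raise DegenerateGroupError(
                f"phenotype non-missing for {int(keep.sum())} individuals (< {min_individuals})"
            )
        self.y = y[keep]
        self.dosages = d[keep]
        if np.ptp(self.y) == 0:
            raise DegenerateGroupError("constant phenotype")
        self.K = None
        if K is not None:
            K = np.asarray(K, dtype=float)
            if K.shape != (y.size, y.size):
                raise DataError("kinship matrix does not match individuals")
            self.K = K[np.ix_(keep, keep)]
            if not np.allclose(self.K, self.K.T, atol=1e-10):
                raise NumericError("kinship matrix is not symmetric")
        self.sites = sites

    def fit(self, method: str = "mlm") -> "GWASResults":
        """Run the scan; ``method`` is ``"mlm"`` (kinship GLS) or ``"ols"``."""
        if method == "ols":
            lam = np.ones(self.y.size)
            U = np.eye(self.y.size)
            delta = np.inf  # no genetic variance component
            yr, w = self.y, np.ones(self.y.size)
        elif method == "mlm":
            if self.K is None:
                raise ConfigurationError("method='mlm' requires a kinship matrix")
            lam, U = np.linalg.eigh(self.K)
            if lam.min() < -_PSD_TOL * max(1.0, lam.max()):
                raise NumericError(
                    f"kinship matrix is not PSD within tolerance (min eigenvalue {lam.min():.3g})"
                )
            lam = np.clip(lam, 0.0, None)
            yr = U.T @ self.y
            ones_r = U.T @ np.ones(self.y.size)
            f = lambda log_delta: _null_loglik(10.0 ** log_delta, lam, yr, ones_r[:, None])
            grid = np.linspace(-5, 5, 61)
            values = [f(g) for g in grid]
            best = int(np.argmax(values))
            lo = grid[max(best - 1, 0)]
            hi = grid[min(best + 1, grid.size - 1)]
            delta = 10.0 ** _golden_section(f, lo, hi)
            w = 1.0 / (lam + delta)
        else:
            raise ConfigurationError(f"unknown method {method!r}")

        n = self.y.size
        if method == "mlm":
            xr_all = U.T @ self.dosages
            ones_rot = U.T @ np.ones(n)
        else:
            xr_all = self.dosages
            ones_rot = np.ones(n)

        # per-SNP weighted LS of y on [1, x] via closed-form 2x2 normal equations
        sw = float(np.sum(w))
        swy = float(np.sum(w * yr))
        swyy = float(np.sum(w * yr * yr))
        swx = (w * ones_rot) @ xr_all
        swxx = w @ (xr_all * xr_all)
        swxy = (w * yr) @ xr_all
        # with rotation, sum(w * ones_rot^2) == sum(w); keep the general form
        sw1 = float(np.sum(w * ones_rot * ones_rot))
        sw1y = float(np.sum(w * ones_rot * yr))

        det = sw1 * swxx - swx * swx
        testable = det > 1e-12 * max(sw1, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (sw1 * swxy - swx * sw1y) / det
            beta0 = (swxx * sw1y - swx * swxy) / det
            rss = swyy - beta0 * sw1y - beta * swxy
            rss = np.clip(rss, 0.0, None)
            sigma2 = rss / (n - 2)
            se = np.sqrt(sigma2 * sw1 / det)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        beta = np.where(testable, beta, 0.0)
        se = np.where(testable, se, np.nan)
        p = np.where(testable, p, 1.0)

        table = _gwas_table(self.sites, beta, se, p, testable, method)
        return GWASResults(table=table, model=method,
                           delta=float(delta) if np.isfinite(delta) else np.inf,
                           n_individuals=n)


def _gwas_table(sites, beta, se, p, testable, model) -> pd.DataFrame:
    m = beta.size
    if sites is not None:
        if len(sites) != m:
            raise DataError("site annotation does not match dosage columns")
        base = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in sites],
                "chrom": [s.chrom for s in sites],
                "pos": [s.pos for s in sites],
                "gene_id": pd.Series([s.gene_id for s in sites], dtype=object),
            }
        )
    else:
        base = pd.DataFrame(
            {"snp_id": [f"snp{i}" for i in range(m)], "chrom": "", "pos": 0,
             "gene_id": pd.Series([None] * m, dtype=object)}
        )
    base["beta"] = beta
    base["se"] = se
    base["p"] = p
    base["model"] = model
    base["testable"] = testable
    return base


@dataclass
class GWASResults:
    """Association scan results: per-SNP effects, errors and p-values."""

    table: pd.DataFrame
    model: str
    delta: float
    n_individuals: int

    def threshold_hits(self, alpha: float = 1e-4) -> tuple[pd.DataFrame, int]:
        """SNPs with p below ``alpha`` plus the distinct-gene count."""
        hits = self.table[self.table["testable"] & (self.table["p"] < alpha)]
        return hits.reset_index(drop=True), int(hits["gene_id"].dropna().nunique())

    @property
    def lambda_gc(self) -> float:
        """Genomic inflation factor of the scan's p-values."""
        return genomic_inflation(self.table.loc[self.table["testable"], "p"].to_numpy())

    def summary(self, alpha: float = 1e-4) -> str:
        hits, n_genes = self.threshold_hits(alpha)
        delta = "inf" if not np.isfinite(self.delta) else f"{self.delta:.4g}"
        return "\n".join(
            [
                f"Mixed-model association scan ({self.model}), n = {self.n_individuals}",
                f"  SNPs tested: {int(self.table['testable'].sum())} of {len(self.table)}",
                f"  residual/genetic variance ratio delta: {delta}",
                f"  genomic inflation lambda: {self.lambda_gc:.3f}",
                f"  hits at p < {alpha:g}: {len(hits)} SNPs in {n_genes} genes",
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        with _atomic_path(path) as tmp:
            with open(tmp, "w") as fh:
                fh.write(f"# model={self.model}\n# delta={self.delta:.10g}\n"
                         f"# n_individuals={self.n_individuals}\n")
                self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    def plot_manhattan(self, ax=None, alpha: float = 1e-4):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = self.table[self.table["testable"]]
        offset = 0
        ticks, labels = [], []
        for chrom, grp in t.groupby("chrom", sort=True):
            with np.errstate(divide="ignore"):
                y = -np.log10(grp["p"].clip(lower=1e-300))
            ax.scatter(grp["pos"] + offset, y, s=4)
            ticks.append(offset + grp["pos"].max() / 2)
            labels.append(str(chrom))
            offset += grp["pos"].max()
        ax.axhline(-np.log10(alpha), color="grey", lw=0.8, ls="--")
        ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
        ax.set_ylabel("-log10 p")
        ax.set_title(f"association scan ({self.model})")
        return ax


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over its
    null median (~0.455)."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals)]
    if pvals.size == 0:
        return float("nan")
    chi2 = stats.chi2.isf(np.clip(pvals, 1e-300, 1.0), df=1)
    return float(np.median(chi2) / _CHI2_MEDIAN_1DF)


def threshold_hits(results: GWASResults, alpha: float = 1e-4) -> tuple[pd.DataFrame, int]:
    """Module-level convenience wrapper around :meth:`GWASResults.threshold_hits`."""
    return results.threshold_hits(alpha)
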