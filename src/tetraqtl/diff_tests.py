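"""Per-SNP differential allele-frequency tests for pooled case-control data.

Two genotyping arms share one result container:

* the pooled-reads arm compares raw read counts between the case and
  control pools with a two-sided Fisher exact test, Bonferroni-adjusted
  over the number of testable SNPs (the adjusted value is what the source
  study calls "FDR");
* the dosage-array arm converts five-class tetraploid dosage calls into
  chromosome counts (each individual contributes 4 alleles) and applies a
  Pearson goodness-of-fit chi-square on the 2x2 table without continuity
  correction.

The Fisher test is computed in exact integer arithmetic: two-sided
p-values follow the minimum-likelihood rule (sum of hypergeometric
probabilities of all tables, at fixed margins, no more probable than the
observed one), with table probabilities represented as integer weights
``C(n1, x) * C(n2, K - x)`` so that ties are resolved exactly and the
result matches exhaustive enumeration to floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from math import comb
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DataError, SizingError
from .io import _atomic_path
from .simulate import PLOIDY, VariantSite

__all__ = [
    "AlleleCounts",
    "pool_counts_reads",
    "dosage_allele_counts",
    "fisher_exact_two_sided",
    "fisher_exact_batch",
    "chisq_two_by_two",
    "bonferroni_adjust",
    "PooledReadScan",
    "DosageScan",
    "DifferentialScanResults",
    "FilterCascade",
    "filter_cascade",
    "DEFAULT_THRESHOLDS",
]


# ---------------------------------------------------------------------------
# exact Fisher test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=500_000)
def _margin_pvalues(n1: int, n2: int, K: int) -> tuple[int, tuple[float, ...]]:
    """Two-sided p-values for every table with margins (n1, n2, K).

    Returns ``(lo, pvals)`` where ``lo`` is the smallest feasible
    case-alt count and ``pvals[a - lo]`` the p-value for observing ``a``.
    Integer hypergeometric weights make tie comparisons exact.
    """
    lo = max(0, K - n2)
    hi = min(K, n1)
    weights = [comb(n1, x) * comb(n2, K - x) for x in range(lo, hi + 1)]
    total = sum(weights)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    pvals = [0.0] * len(weights)
    csum = 0
    i = 0
    while i < len(order):
        j = i
        w = weights[order[i]]
        while j < len(order) and weights[order[j]] == w:
            csum += weights[order[j]]
            j += 1
        value = csum / total
        for k in range(i, j):
            pvals[order[k]] = value
        i = j
    return lo, tuple(pvals)


def fisher_exact_two_sided(alt_case: int, ref_case: int, alt_ctrl: int, ref_ctrl: int) -> float:
    """Exact two-sided Fisher p-value for one 2x2 allele-count table.

    Rows are the two pools, columns the alt/ref alleles. Returns NaN when a
    pool has zero total depth (the SNP is untestable); a column margin of
    zero (monomorphic SNP) gives p = 1 since only one table is feasible.
    """
    counts = (alt_case, ref_case, alt_ctrl, ref_ctrl)
    if any(c < 0 for c in counts):
        raise DataError(f"negative counts in table {counts}")
    n1 = alt_case + ref_case
    n2 = alt_ctrl + ref_ctrl
    if n1 == 0 or n2 == 0:
        return float("nan")
    K = alt_case + alt_ctrl
    lo, pvals = _margin_pvalues(n1, n2, K)
    return pvals[alt_case - lo]


def fisher_exact_batch(
    alt_case: np.ndarray,
    ref_case: np.ndarray,
    alt_ctrl: np.ndarray,
    ref_ctrl: np.ndarray,
) -> np.ndarray:
    """Vector of exact two-sided Fisher p-values (NaN where untestable)."""
    arrays = [np.asarray(a, dtype=np.int64) for a in (alt_case, ref_case, alt_ctrl, ref_ctrl)]
    if any((a < 0).any() for a in arrays):
        raise DataError("negative counts")
    ac, rc, aC, rC = arrays
    n1 = ac + rc
    n2 = aC + rC
    K = ac + aC
    out = np.empty(ac.shape, dtype=float)
    table = _margin_pvalues
    for i in range(ac.size):
        if n1[i] == 0 or n2[i] == 0:
            out[i] = np.nan
            continue
        lo, pvals = table(int(n1[i]), int(n2[i]), int(K[i]))
        out[i] = pvals[ac[i] - lo]
    return out


# ---------------------------------------------------------------------------
# Pearson chi-square on 2x2 allele counts
# ---------------------------------------------------------------------------

def chisq_two_by_two(
    alt_case: np.ndarray,
    ref_case: np.ndarray,
    alt_ctrl: np.ndarray,
    ref_ctrl: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square (1 df, no continuity correction) per 2x2 table.

    Monomorphic tables (a zero column margin) get chi2 = 0, p = 1.
    Returns ``(chi2, p)``.
    """
    a = np.asarray(alt_case, dtype=float)
    b = np.asarray(ref_case, dtype=float)
    c = np.asarray(alt_ctrl, dtype=float)
    d = np.asarray(ref_ctrl, dtype=float)
    n1 = a + b
    n2 = c + d
    K = a + c
    R = b + d
    N = n1 + n2
    denom = n1 * n2 * K * R
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, N * (a * d - b * c) ** 2 / denom, 0.0)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(denom > 0, p, 1.0)
    return chi2, p


def bonferroni_adjust(p: np.ndarray, n_tests: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: min(1, m * p)."""
    if n_tests < 1:
        raise ConfigurationError("n_tests must be >= 1")
    return np.minimum(1.0, n_tests * np.asarray(p, dtype=float))


# ---------------------------------------------------------------------------
# allele-count assembly
# ---------------------------------------------------------------------------

@dataclass
class AlleleCounts:
    """Case/control alt and ref counts per SNP plus a testability mask.

    Counts are read counts in the pooled-reads arm and chromosome counts
    (sum of dosages vs ``4n`` minus that) in the dosage-array arm.
    """

    alt_case: np.ndarray
    ref_case: np.ndarray
    alt_ctrl: np.ndarray
    ref_ctrl: np.ndarray
    testable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("alt_case", "ref_case", "alt_ctrl", "ref_ctrl"):
            arr = np.asarray(getattr(self, name), dtype=np.int64)
            if (arr < 0).any():
                raise DataError(f"negative counts in {name}")
            setattr(self, name, arr)
        if self.testable is None:
            depth_case = self.alt_case + self.ref_case
            depth_ctrl = self.alt_ctrl + self.ref_ctrl
            self.testable = (depth_case > 0) & (depth_ctrl > 0)
        else:
            self.testable = np.asarray(self.testable, dtype=bool)

    @property
    def freq_case(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.alt_case + self.ref_case > 0,
                self.alt_case / (self.alt_case + self.ref_case),
                np.nan,
            )

    @property
    def freq_ctrl(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                self.alt_ctrl + self.ref_ctrl > 0,
                self.alt_ctrl / (self.alt_ctrl + self.ref_ctrl),
                np.nan,
            )


def pool_counts_reads(
    counts_by_sample: Mapping[str, tuple[np.ndarray, np.ndarray]],
    case_samples: Sequence[str],
    control_samples: Sequence[str],
) -> AlleleCounts:
    """Sum per-sample (alt, ref) read counts into case and control pools.

    SNPs with zero total depth in either pool are flagged untestable.
    """
    if not case_samples or not control_samples:
        raise SizingError("both pools must contain at least one sample")

    def _sum(samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        alts, refs = zip(*(counts_by_sample[s] for s in samples))
        return np.sum(alts, axis=0), np.sum(refs, axis=0)

    alt_case, ref_case = _sum(case_samples)
    alt_ctrl, ref_ctrl = _sum(control_samples)
    return AlleleCounts(alt_case, ref_case, alt_ctrl, ref_ctrl)


def dosage_allele_counts(dosages_case: np.ndarray, dosages_ctrl: np.ndarray) -> AlleleCounts:
    """Chromosome counts from tetraploid dosages: (sum d, 4n - sum d) per group."""
    dc = np.asarray(dosages_case)
    dk = np.asarray(dosages_ctrl)
    if dc.ndim != 2 or dk.ndim != 2 or dc.shape[0] == 0 or dk.shape[0] == 0:
        raise SizingError("both dosage groups must be non-empty matrices")
    for d in (dc, dk):
        if d.min() < 0 or d.max() > PLOIDY:
            raise DataError("dosages must lie in {0..4}")
    alt_case = dc.sum(axis=0).astype(np.int64)
    alt_ctrl = dk.sum(axis=0).astype(np.int64)
    ref_case = PLOIDY * dc.shape[0] - alt_case
    ref_ctrl = PLOIDY * dk.shape[0] - alt_ctrl
    return AlleleCounts(alt_case, ref_case, alt_ctrl, ref_ctrl)


# ---------------------------------------------------------------------------
# scan models
# ---------------------------------------------------------------------------

def _site_frame(sites: Sequence[VariantSite] | None, n: int) -> pd.DataFrame:
    if sites is None:
        return pd.DataFrame(
            {
                "snp_id": [f"snp{i}" for i in range(n)],
                "chrom": "",
                "pos": 0,
                "ref": "",
                "alt": "",
                "gene_id": pd.Series([None] * n, dtype=object),
                "coding_effect": "noncoding",
            }
        )
    if len(sites) != n:
        raise DataError(f"{len(sites)} sites for {n} SNP count rows")
    return pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in sites],
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "ref": [s.ref for s in sites],
            "alt": [s.alt for s in sites],
            "gene_id": pd.Series([s.gene_id for s in sites], dtype=object),
            "coding_effect": [s.coding_effect for s in sites],
        }
    )


_RESULT_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt", "gene_id", "coding_effect", "trait",
    "alt_case", "ref_case", "alt_ctrl", "ref_ctrl",
    "freq_case", "freq_ctrl", "statistic", "p", "p_adj", "direction", "testable",
]


def _assemble_results(
    counts: AlleleCounts,
    sites: Sequence[VariantSite] | None,
    trait: str,
    arm: str,
    statistic: np.ndarray,
    p: np.ndarray,
) -> "DifferentialScanResults":
    n = counts.alt_case.size
    table = _site_frame(sites, n)
    table["trait"] = trait
    table["alt_case"] = counts.alt_case
    table["ref_case"] = counts.ref_case
    table["alt_ctrl"] = counts.alt_ctrl
    table["ref_ctrl"] = counts.ref_ctrl
    fc = counts.freq_case
    fk = counts.freq_ctrl
    table["freq_case"] = fc
    table["freq_ctrl"] = fk
    table["statistic"] = statistic
    testable = counts.testable & np.isfinite(p)
    n_tests = int(testable.sum())
    p = np.where(testable, p, np.nan)
    table["p"] = p
    table["p_adj"] = np.where(testable, bonferroni_adjust(np.nan_to_num(p, nan=1.0), max(n_tests, 1)), np.nan)
    diff = fc - fk
    direction = np.where(np.isnan(diff) | (diff == 0), "0", np.where(diff > 0, "+", "-"))
    table["direction"] = direction
    table["testable"] = testable
    return DifferentialScanResults(table[_RESULT_COLUMNS], arm=arm, trait=trait, n_tests=n_tests)


class PooledReadScan:
    """Fisher-exact differential scan on pooled read counts.

    Parameters
    ----------
    counts
        Case/control allele counts per SNP (see :func:`pool_counts_reads`).
    sites
        Optional variant annotation aligned with the count arrays.
    trait
        Trait label carried into the results table.
    """

    arm = "reads"

    def __init__(self, counts: AlleleCounts, sites: Sequence[VariantSite] | None = None,
                 trait: str = "NA"):
        self.counts = counts
        self.sites = sites
        self.trait = trait

    def fit(self) -> "DifferentialScanResults":
        c = self.counts
        p = fisher_exact_batch(c.alt_case, c.ref_case, c.alt_ctrl, c.ref_ctrl)
        # the exact statistic is the table probability itself; report the
        # alt-frequency difference as a signed effect summary instead
        statistic = c.freq_case - c.freq_ctrl
        return _assemble_results(c, self.sites, self.trait, self.arm, statistic, p)


class DosageScan:
    """Pearson chi-square differential scan on tetraploid dosage calls."""

    arm = "array"

    def __init__(
        self,
        dosages_case: np.ndarray,
        dosages_ctrl: np.ndarray,
        sites: Sequence[VariantSite] | None = None,
        trait: str = "NA",
    ):
        self.counts = dosage_allele_counts(dosages_case, dosages_ctrl)
        self.sites = sites
        self.trait = trait

    def fit(self) -> "DifferentialScanResults":
        c = self.counts
        chi2, p = chisq_two_by_two(c.alt_case, c.ref_case, c.alt_ctrl, c.ref_ctrl)
        return _assemble_results(c, self.sites, self.trait, self.arm, chi2, p)


@dataclass
class DifferentialScanResults:
    """Per-SNP differential test results for one trait and one arm.

    ``n_tests`` is the Bonferroni ``m``: the number of SNPs actually tested
    (untestable SNPs — zero-depth pools, empty margins — are excluded).
    """

    table: pd.DataFrame
    arm: str
    trait: str
    n_tests: int

    def significant(self, alpha: float | None = None, adjusted: bool | None = None) -> pd.DataFrame:
        """Rows below the significance threshold.

        Defaults mirror each arm's procedure: the reads arm thresholds the
        Bonferroni-adjusted value at 0.05, the array arm the raw p at 0.01.
        """
        if adjusted is None:
            adjusted = self.arm == "reads"
        if alpha is None:
            alpha = 0.05 if self.arm == "reads" else 0.01
        col = "p_adj" if adjusted else "p"
        t = self.table
        return t[t["testable"] & (t[col] < alpha)]

    def summary(self) -> str:
        sig = self.significant()
        lines = [
            f"Differential allele-frequency scan ({self.arm} arm, trait {self.trait})",
            f"  SNPs tested (Bonferroni m): {self.n_tests} of {len(self.table)}",
            f"  significant at default threshold: {len(sig)}",
        ]
        if len(sig):
            genes = sig["gene_id"].dropna().nunique()
            lines.append(f"  distinct annotated genes among hits: {genes}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        with _atomic_path(path) as tmp:
            with open(tmp, "w") as fh:
                fh.write(f"# arm={self.arm}\n# trait={self.trait}\n# n_tests={self.n_tests}\n")
                self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DifferentialScanResults":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key] = value
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, sep="\t")
        if not {"arm", "trait", "n_tests"} <= meta.keys():
            raise DataError(f"{path}: missing scan metadata header")
        return cls(table, arm=meta["arm"], trait=meta["trait"], n_tests=int(meta["n_tests"]))

    def plot_manhattan(self, ax=None, alpha: float | None = None):
        """Manhattan plot of -log10 adjusted p along the physical map."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        t = self.table[self.table["testable"]]
        offset = 0
        ticks, labels = [], []
        col = "p_adj" if self.arm == "reads" else "p"
        for chrom, grp in t.groupby("chrom", sort=True):
            with np.errstate(divide="ignore"):
                y = -np.log10(grp[col].clip(lower=1e-300))
            ax.scatter(grp["pos"] + offset, y, s=4)
            ticks.append(offset + grp["pos"].max() / 2)
            labels.append(str(chrom))
            offset += grp["pos"].max()
        if alpha is None:
            alpha = 0.05 if self.arm == "reads" else 0.01
        ax.axhline(-np.log10(alpha), color="grey", lw=0.8, ls="--")
        ax.set_xticks(ticks, labels, rotation=45, fontsize=7)
        ax.set_ylabel(f"-log10 {col}")
        ax.set_title(f"{self.trait} ({self.arm} arm)")
        return ax


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    "significant": 0.05,       # stage (a): adjusted p below this
    "missense_strict": 1e-4,   # stage (d): missense SNPs below this
    "gene_strict": 1e-3,       # stage (e): genes with >=1 SNP below this
}


@dataclass
class FilterCascade:
    """Staged filtering of a differential scan, with per-stage counts.

    Stages (reads arm defaults in parentheses):

    a. significant SNPs (adjusted p < 0.05)
    b. stage (a) restricted to SNPs inside annotated genes
    c. stage (b) restricted to missense SNPs
    d. stage (c) at the strict threshold (adjusted p < 1e-4)
    e. genes with at least one SNP at adjusted p < 1e-3
    """

    stages: dict[str, pd.DataFrame]
    genes_multi_hit: int
    thresholds: dict[str, float]

    @property
    def counts(self) -> dict[str, int]:
        out = {k: len(v) for k, v in self.stages.items()}
        out["genes_with_hits"] = self.stages["b"]["gene_id"].nunique()
        out["genes_missense"] = self.stages["c"]["gene_id"].nunique()
        out["genes_multi_hit"] = self.genes_multi_hit
        return out

    def summary(self) -> str:
        c = self.counts
        return "\n".join(
            [
                "Filtering cascade",
                f"  (a) significant SNPs:              {c['a']}",
                f"  (b) ... in annotated genes:        {c['b']} ({c['genes_with_hits']} genes)",
                f"  (c) ... causing amino acid change: {c['c']} ({c['genes_missense']} genes)",
                f"  (d) ... at strict threshold:       {c['d']}",
                f"  (e) genes with >=1 strict-gene hit: {c['e']}",
                f"  genes with >=2 differential SNPs:  {c['genes_multi_hit']}",
            ]
        )


def filter_cascade(
    results: DifferentialScanResults,
    thresholds: Mapping[str, float] | None = None,
) -> FilterCascade:
    """Apply the staged SNP/gene filtering to one scan's results."""
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigurationError(f"unknown threshold keys: {sorted(unknown)}")
        th.update(thresholds)

    t = results.table
    testable = t[t["testable"]]
    a = testable[testable["p_adj"] < th["significant"]]
    b = a[a["gene_id"].notna()]
    c = b[b["coding_effect"] == "missense"]
    d = c[c["p_adj"] < th["missense_strict"]]
    strict = testable[(testable["p_adj"] < th["gene_strict"]) & testable["gene_id"].notna()]
    e = (
        strict.groupby("gene_id", sort=True)
        .agg(n_snps=("snp_id", "size"), min_p_adj=("p_adj", "min"), chrom=("chrom", "first"))
        .reset_index()
    )
    multi = int((b.groupby("gene_id").size() >= 2).sum())
    return FilterCascade({"a": a, "b": b, "c": c, "d": d, "e": e}, multi, th)
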