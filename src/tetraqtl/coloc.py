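"""Cross-experiment comparison of hit sets and QTL-region construction.

Hits from different genotyping arms or populations are compared at three
resolutions: identical SNPs (allele-aware chrom+pos+ref+alt match),
identical genes (intersection of distinct gene identifiers), and physical
co-localization (distance from a hit to the nearest peak interval below a
cutoff, 0 if inside). Multi-experiment evidence is merged into QTL regions
by single-linkage clustering of hit positions per chromosome; clusters
supported by at least two distinct experiments become regions, padded to a
minimum physical width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

__all__ = [
    "HitSet",
    "overlap_snps",
    "overlap_genes",
    "genes_in_all",
    "colocalize_to_peaks",
    "define_qtl_regions",
]

logger = logging.getLogger(__name__)

_HIT_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt", "gene_id")


@dataclass
class HitSet:
    """Significant SNPs from one experiment (one arm, one population)."""

    label: str
    hits: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _HIT_COLUMNS if c not in self.hits.columns]
        if missing:
            raise DataError(f"hit set {self.label!r} lacks columns {missing}")
        self.hits = self.hits.reset_index(drop=True)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.hits["gene_id"].dropna())

    def __len__(self) -> int:
        return len(self.hits)


def overlap_snps(a: HitSet, b: HitSet) -> pd.DataFrame:
    """SNPs identical between two experiments (same chrom, pos, ref, alt)."""
    key = ["chrom", "pos", "ref", "alt"]
    left = a.hits.drop_duplicates(subset=key)
    right = b.hits.drop_duplicates(subset=key)
    merged = left.merge(right, on=key, suffixes=(f"_{a.label}", f"_{b.label}"))
    return merged.sort_values(key).reset_index(drop=True)


def overlap_genes(a: HitSet, b: HitSet) -> list[str]:
    """Genes hit in both experiments (by any SNP)."""
    return sorted(a.gene_ids & b.gene_ids)


def genes_in_all(hit_sets: Sequence[HitSet]) -> list[str]:
    """Genes hit in every one of the experiments."""
    if not hit_sets:
        return []
    shared = set.intersection(*(h.gene_ids for h in hit_sets))
    return sorted(shared)


def colocalize_to_peaks(
    hits: HitSet,
    peaks: pd.DataFrame,
    max_dist: int = 500_000,
) -> tuple[pd.DataFrame, float]:
    """Distance from each hit to the nearest peak interval, plus the
    co-localized fraction.

    A hit co-localizes when its distance to the nearest peak on the same
    chromosome (0 if inside the peak span) is strictly below ``max_dist``.
    With no peaks at all the fraction is 0 and a warning is logged.
    """
    out = hits.hits.copy()
    if peaks is None or len(peaks) == 0:
        logger.warning("no peaks supplied; co-localized fraction is 0")
        out["peak_distance"] = np.nan
        out["colocalized"] = False
        return out, 0.0

    distances = np.full(len(out), np.inf)
    for chrom, grp in peaks.groupby("chrom"):
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        pos = out.loc[mask, "pos"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        # distance from point to interval: 0 inside, else gap to nearest edge
        d = np.maximum.reduce(
            [starts[None, :] - pos[:, None], pos[:, None] - ends[None, :],
             np.zeros((pos.size, starts.size))]
        )
        distances[mask] = d.min(axis=1)
    out["peak_distance"] = np.where(np.isinf(distances), np.nan, distances)
    out["colocalized"] = distances < max_dist
    fraction = float(out["colocalized"].mean()) if len(out) else 0.0
    return out, fraction


def define_qtl_regions(
    hit_sets: Sequence[HitSet],
    link_dist: int = 500_000,
    min_width: int = 1_000_000,
    wide_warning: int = 4_000_000,
    genome=None,
) -> pd.DataFrame:
    """Merge hits from several experiments into physical QTL regions.

    Hits on one chromosome are clustered by single linkage: two hits join
    the same cluster when their positions are within ``link_dist`` of each
    other (directly or transitively). Clusters containing hits from at
    least two distinct experiments become regions spanning the extreme hit
    positions, symmetrically padded to ``min_width`` (clamped to the
    chromosome when its length is known). Regions wider than
    ``wide_warning`` are flagged.
    """
    if len(hit_sets) < 2:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "width", "n_hits", "n_experiments",
                     "experiments", "wide"]
        )
    frames = []
    for h in hit_sets:
        f = h.hits[["chrom", "pos", "snp_id"]].copy()
        f["experiment"] = h.label
        frames.append(f)
    allhits = pd.concat(frames, ignore_index=True)

    rows = []
    for chrom, grp in allhits.groupby("chrom", sort=True):
        grp = grp.sort_values(["pos", "experiment", "snp_id"]).reset_index(drop=True)
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > link_dist)
        cluster_id = np.zeros(len(grp), dtype=int)
        cluster_id[1:] = np.cumsum(np.isin(np.arange(len(grp) - 1), breaks))
        grp["cluster"] = cluster_id
        chrom_regions = []
        for _, cl in grp.groupby("cluster"):
            experiments = sorted(cl["experiment"].unique())
            if len(experiments) < 2:
                continue
            raw_lo, raw_hi = int(cl["pos"].min()), int(cl["pos"].max())
            lo, hi = raw_lo, raw_hi
            if hi - lo + 1 < min_width:
                pad = min_width - (hi - lo + 1)
                lo -= pad // 2
                hi += pad - pad // 2
            if genome is not None:
                length = genome.length_of(chrom)
                if lo < 1:
                    hi = min(hi + (1 - lo), length)
                if hi > length:
                    lo = max(1, lo - (hi - length))
                    hi = length
            lo = max(lo, 1)
            chrom_regions.append(
                {"raw_lo": raw_lo, "raw_hi": raw_hi, "lo": lo, "hi": hi,
                 "n_hits": len(cl), "experiments": experiments}
            )
        # padding must never make neighbouring regions overlap: trim padded
        # edges back to the midpoint of the raw gap between clusters
        for prev, cur in zip(chrom_regions, chrom_regions[1:]):
            if cur["lo"] <= prev["hi"]:
                mid = (prev["raw_hi"] + cur["raw_lo"]) // 2
                prev["hi"] = min(prev["hi"], mid)
                cur["lo"] = max(cur["lo"], mid + 1)
        for r in chrom_regions:
            width = r["hi"] - r["lo"] + 1
            rows.append(
                (chrom, r["lo"], r["hi"], width, r["n_hits"], len(r["experiments"]),
                 ",".join(r["experiments"]), width > wide_warning)
            )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "width", "n_hits", "n_experiments",
                 "experiments", "wide"],
    )
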