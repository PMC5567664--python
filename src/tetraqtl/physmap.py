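"""Gene-density windows and peak calling along the physical map.

Hit-bearing genes are binned into fixed 0.5-Mbp windows anchored at
position 1 of each chromosome (each gene assigned once, by its start
coordinate). Maximal runs of edge-adjacent windows that each hold at least
``min_genes`` genes are fused into peaks; peaks whose densest window
reaches the prominence threshold are flagged. Peak widths are reported,
not capped — runs wider than 4 Mbp (beyond the LD scale that motivates the
procedure) trigger a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError
from .simulate import GeneModel, GenomeSpec

__all__ = ["WINDOW_SIZE", "bin_genes", "call_peaks", "flag_prominent"]

logger = logging.getLogger(__name__)

WINDOW_SIZE = 500_000
WIDTH_WARNING = 4_000_000


def bin_genes(
    genes: Sequence[GeneModel],
    genome: GenomeSpec,
    window: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Count distinct hit-bearing genes per fixed window.

    Windows tile every chromosome without overlap: window ``k`` spans
    ``[k*window + 1, (k+1)*window]`` 1-based inclusive, the last one
    truncated at the chromosome end. Every gene lands in exactly one
    window, chosen by its start coordinate.
    """
    counts: dict[tuple[str, int], set[str]] = {}
    for g in genes:
        try:
            length = genome.length_of(g.chrom)
        except KeyError:
            raise DataError(f"gene {g.gene_id} on unknown chromosome {g.chrom}") from None
        if not 1 <= g.start <= length:
            raise DataError(f"gene {g.gene_id} start {g.start} outside {g.chrom}")
        k = (g.start - 1) // window
        counts.setdefault((g.chrom, k), set()).add(g.gene_id)

    rows = []
    for chrom, length in genome.chromosomes:
        n_windows = (length + window - 1) // window
        for k in range(n_windows):
            start = k * window + 1
            end = min((k + 1) * window, length)
            rows.append((chrom, k, start, end, len(counts.get((chrom, k), ()))))
    return pd.DataFrame(rows, columns=["chrom", "index", "start", "end", "gene_count"])


def call_peaks(windows: pd.DataFrame, min_genes: int = 3) -> pd.DataFrame:
    """Fuse maximal runs of adjacent qualifying windows into peaks.

    A window qualifies when ``gene_count >= min_genes``; strictly adjacent
    qualifying windows (consecutive indices on one chromosome) form one
    peak spanning from the first window's start to the last window's end.
    """
    peaks = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("index")
        qualifying = grp[grp["gene_count"] >= min_genes]
        if qualifying.empty:
            continue
        run: list[pd.Series] = []
        prev_index = None
        for _, w in qualifying.iterrows():
            if prev_index is not None and w["index"] != prev_index + 1:
                peaks.append(_finish_run(chrom, run))
                run = []
            run.append(w)
            prev_index = w["index"]
        peaks.append(_finish_run(chrom, run))
    columns = ["chrom", "start", "end", "n_windows", "total_genes", "max_window_genes", "prominent"]
    if not peaks:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(peaks, columns=columns)
    wide = df[(df["end"] - df["start"] + 1) > WIDTH_WARNING]
    for _, p in wide.iterrows():
        logger.warning(
            "peak %s:%d-%d is %.1f Mbp wide (beyond the expected LD scale)",
            p["chrom"], p["start"], p["end"], (p["end"] - p["start"] + 1) / 1e6,
        )
    return df


def _finish_run(chrom: str, run: list[pd.Series]) -> tuple:
    start = int(run[0]["start"])
    end = int(run[-1]["end"])
    counts = [int(w["gene_count"]) for w in run]
    return (chrom, start, end, len(run), sum(counts), max(counts), False)


def flag_prominent(peaks: pd.DataFrame, threshold: int = 10) -> pd.DataFrame:
    """Mark peaks whose densest window holds at least ``threshold`` genes."""
    peaks = peaks.copy()
    peaks["prominent"] = peaks["max_window_genes"] >= threshold
    return peaks
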