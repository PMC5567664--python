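"""Trait-combination and direction-of-effect classification.

A SNP enters the profile table when it is significant at the arm's primary
threshold for at least one trait; for the other two traits a laxer
secondary threshold is then consulted (the reads arm uses Bonferroni-
adjusted tiers throughout, the array arm raw p at 0.01 primary / 0.05
secondary). Each profiled SNP maps to exactly one trait combination (the
non-empty subset of {TSC, TY, TSY} it is flagged for) and one direction
pattern:

* antagonistic — the alt allele moves starch content and yield in opposite
  directions (frequency higher in HIGH-TSC but lower in HIGH-TY pools or
  vice versa);
* unidirectional — every nonzero direction agrees (neutral directions
  allowed); single-trait SNPs fall here by convention;
* mixed — anything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diff_tests import DifferentialScanResults
from .exceptions import AlignmentError, ConfigurationError
from .simulate import TRAITS

__all__ = [
    "build_profiles",
    "classify_pattern",
    "summarize_combinations",
    "PATTERNS",
]

PATTERNS = ("antagonistic", "unidirectional", "mixed")

_DIR_VALUE = {"+": 1, "-": -1, "0": 0}


def classify_pattern(combination: Sequence[str], directions: Mapping[str, str]) -> str:
    """Direction pattern of one SNP given its significant traits.

    ``directions`` maps trait name to "+", "-" or "0"; only traits in
    ``combination`` are considered. Starch content versus yield (or, when
    yield is absent, versus starch yield) with opposite nonzero signs is
    antagonistic; all nonzero signs equal is unidirectional; the rest is
    mixed.
    """
    combo = [t for t in TRAITS if t in combination]
    if not combo:
        raise ConfigurationError("combination must be a non-empty subset of the traits")
    d = {t: _DIR_VALUE[directions[t]] for t in combo}
    if "TSC" in d and "TY" in d and d["TSC"] * d["TY"] == -1:
        return "antagonistic"
    if "TSC" in d and "TY" not in d and "TSY" in d and d["TSC"] * d["TSY"] == -1:
        return "antagonistic"
    nonzero = {v for v in d.values() if v != 0}
    if len(nonzero) <= 1:
        return "unidirectional"
    return "mixed"


def build_profiles(
    results: Mapping[str, DifferentialScanResults],
    primary_alpha: float | None = None,
    secondary_alpha: float | None = None,
) -> pd.DataFrame:
    """Cross-trait significance/direction profiles per SNP.

    ``results`` maps trait name to that trait's scan results; all scans
    must come from the same arm and cover the same SNP universe in the
    same order. A SNP is kept when at least one trait passes the primary
    threshold; the remaining traits are flagged at the secondary
    threshold.
    """
    if not results:
        raise ConfigurationError("need at least one trait's results")
    arms = {r.arm for r in results.values()}
    if len(arms) != 1:
        raise AlignmentError(f"results mix arms: {sorted(arms)}")
    arm = arms.pop()
    use_adjusted = arm == "reads"
    if primary_alpha is None:
        primary_alpha = 0.05 if use_adjusted else 0.01
    if secondary_alpha is None:
        secondary_alpha = 0.05

    traits = [t for t in TRAITS if t in results]
    first = results[traits[0]].table
    ids = first["snp_id"]
    for t in traits[1:]:
        other = results[t].table["snp_id"]
        if len(other) != len(ids) or (other.values != ids.values).any():
            raise AlignmentError(f"SNP universe of {t} differs from {traits[0]}")

    col = "p_adj" if use_adjusted else "p"
    base = first[["snp_id", "chrom", "pos", "ref", "alt", "gene_id", "coding_effect"]].copy()
    primary_any = np.zeros(len(base), dtype=bool)
    for t in traits:
        table = results[t].table
        pvals = table[col].to_numpy()
        testable = table["testable"].to_numpy()
        primary = testable & (pvals < primary_alpha)
        secondary = testable & (pvals < secondary_alpha)
        primary_any |= primary
        base[f"primary_{t}"] = primary
        base[f"sig_{t}"] = secondary
        base[f"dir_{t}"] = table["direction"].to_numpy()
        base[f"p_{t}"] = pvals
    for t in TRAITS:
        if t not in traits:
            base[f"primary_{t}"] = False
            base[f"sig_{t}"] = False
            base[f"dir_{t}"] = "0"
            base[f"p_{t}"] = np.nan

    profiles = base[primary_any].copy()
    # membership: primary hit always included; other traits via secondary flag
    combos, patterns = [], []
    for _, row in profiles.iterrows():
        combo = [t for t in TRAITS if row[f"primary_{t}"] or row[f"sig_{t}"]]
        directions = {t: row[f"dir_{t}"] for t in TRAITS}
        combos.append("+".join(combo))
        patterns.append(classify_pattern(combo, directions))
    profiles["combination"] = combos
    profiles["pattern"] = patterns
    return profiles.reset_index(drop=True)


def summarize_combinations(profiles: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP and distinct-gene counts per trait combination and pattern.

    Returns ``(summary, unidirectional_three_trait)``: the second frame
    lists SNPs flagged for all three traits whose directions all agree —
    the alleles that raise starch content, yield and starch yield together
    (breeding targets).
    """
    all_combos = [
        "TSC", "TY", "TSY", "TSC+TY", "TSC+TSY", "TY+TSY", "TSC+TY+TSY",
    ]
    rows = []
    for combo in all_combos:
        sub = profiles[profiles["combination"] == combo] if len(profiles) else profiles
        row = {
            "combination": combo,
            "n_snps": len(sub),
            "n_genes": sub["gene_id"].dropna().nunique() if len(sub) else 0,
        }
        for pattern in PATTERNS:
            row[f"n_{pattern}"] = int((sub["pattern"] == pattern).sum()) if len(sub) else 0
        rows.append(row)
    summary = pd.DataFrame(rows)
    if len(profiles):
        uni3 = profiles[
            (profiles["combination"] == "TSC+TY+TSY") & (profiles["pattern"] == "unidirectional")
        ].copy()
    else:
        uni3 = profiles.copy()
    return summary, uni3
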