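"""Case-control pool construction from adjusted trait means.

Cases are the genotypes with the highest adjusted means for the selected
trait, controls the lowest; ties at a cutoff break by ascending
genotype_id so the selection is reproducible and invariant under row order
of the phenotype table. The contrast between HIGH and LOW groups is
verified with Welch two-sample t-tests for the selected trait and the two
other traits (cross-trait contrasts are reported but never gate the
pipeline).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateGroupError, SizingError
from .io import PhenotypeTable
from .simulate import TRAITS

__all__ = ["PoolPair", "select_pools", "contrast_test"]


@dataclass(frozen=True)
class PoolPair:
    """Case (HIGH) and control (LOW) genotype-ID sets for one trait."""

    trait: str
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if not self.case_ids or not self.control_ids:
            raise ValueError("case and control groups must both be non-empty")
        if set(self.case_ids) & set(self.control_ids):
            raise ValueError("case and control groups must be disjoint")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "trait": self.trait,
            "case_ids": list(self.case_ids),
            "control_ids": list(self.control_ids),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PoolPair":
        payload = json.loads(Path(path).read_text())
        return cls(payload["trait"], tuple(payload["case_ids"]), tuple(payload["control_ids"]))


def select_pools(
    pheno: PhenotypeTable,
    trait: str,
    n_case: int,
    n_control: int,
) -> PoolPair:
    """Assemble maximally contrasting HIGH/LOW groups for one trait.

    Requires at least ``n_case + n_control`` genotypes with non-missing
    values for ``trait``. A genotype may appear in pools of different
    traits; within one pair the groups are disjoint by construction.
    """
    values = pheno.trait_values(trait)
    if len(values) < n_case + n_control:
        raise SizingError(
            f"need {n_case + n_control} phenotyped genotypes for {trait}, have {len(values)}"
        )
    frame = values.reset_index()
    frame.columns = ["genotype_id", "value"]
    high = frame.sort_values(["value", "genotype_id"], ascending=[False, True], kind="stable")
    case_ids = tuple(sorted(high["genotype_id"].head(n_case)))
    # controls come from the remaining genotypes so that a tie block spanning
    # both cutoffs can never place one genotype in both groups
    rest = frame[~frame["genotype_id"].isin(case_ids)]
    low = rest.sort_values(["value", "genotype_id"], ascending=[True, True], kind="stable")
    control_ids = tuple(sorted(low["genotype_id"].head(n_control)))
    return PoolPair(trait, case_ids, control_ids)


def contrast_test(
    pools: PoolPair,
    pheno: PhenotypeTable,
    traits: Sequence[str] = TRAITS,
) -> pd.DataFrame:
    """Welch two-sample t-test between case and control members per trait.

    Returns one row per trait with group means, the t statistic, the
    two-sided p-value and whether that trait is the one the pools were
    selected for. Raises :class:`DegenerateGroupError` if either group has
    fewer than two non-missing values for the pools' own trait; for the
    other traits such rows carry NaN.
    """
    rows = []
    for trait in traits:
        case = pheno.trait_values(trait, pools.case_ids)
        control = pheno.trait_values(trait, pools.control_ids)
        if len(case) < 2 or len(control) < 2:
            if trait == pools.trait:
                raise DegenerateGroupError(
                    f"group with <2 phenotyped members for selected trait {trait}"
                )
            rows.append((trait, np.nan, np.nan, np.nan, np.nan, trait == pools.trait))
            continue
        t, p = stats.ttest_ind(case, control, equal_var=False)
        rows.append((trait, case.mean(), control.mean(), float(t), float(p), trait == pools.trait))
    return pd.DataFrame(
        rows, columns=["trait", "mean_case", "mean_control", "t", "p", "selected"]
    )
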