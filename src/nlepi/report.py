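"""Headline summary statistics over a signature table and cohort metadata."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd


@dataclass
class DirectionSplit:
    """Counts of signature rows by fold-change direction (RM:HN orientation)."""

    n_higher_ref: int  # fold > 1: higher in the reference-named group (RM)
    n_higher_other: int  # fold < 1: higher in the comparison group (HN)
    n_ties: int  # fold exactly 1, reported separately

    def __iter__(self):
        return iter((self.n_higher_ref, self.n_higher_other))


def direction_split(table: pd.DataFrame, fold_column: str = "fold_rm_hn") -> DirectionSplit:
    """Split signature rows by whether expression is higher in RM or in HN."""
    folds = table[fold_column]
    if (folds <= 0).any():
        raise ValueError("folds must be positive")
    return DirectionSplit(
        n_higher_ref=int((folds > 1).sum()),
        n_higher_other=int((folds < 1).sum()),
        n_ties=int((folds == 1).sum()),
    )


def cross_contrast_concordance(
    table: pd.DataFrame,
    column_a: str = "fold_rm_hn",
    column_b: str = "fold_rm_pm",
) -> tuple[int, list[str]]:
    """Rows whose two contrasts point the same way, plus the discordant rows.

    A row is concordant when its RM:HN and RM:PM folds sit on the same side
    of 1 — i.e. the PM group's expression shift (relative to RM) copies the
    HN group's direction.
    """
    same = (table[column_a] > 1) == (table[column_b] > 1)
    discordant = list(table.loc[~same, "symbol"]) if "symbol" in table else list(
        table.index[~same]
    )
    return int(same.sum()), discordant


def prior_overlap(table: pd.DataFrame) -> int:
    """Rows flagged as overlapping the earlier study's probe-set list."""
    return int(table["prior_study_flag"].astype(bool).sum())


def group_age_summary(sample_meta: pd.DataFrame) -> pd.DataFrame:
    """Per-group age summary: n, mean (full precision and display), min, max.

    ``display_mean`` rounds to one decimal; comparisons should use ``mean``.
    Samples with a missing age are excluded with a warning.
    """
    meta = sample_meta.copy()
    meta["age"] = pd.to_numeric(meta["age"], errors="coerce")
    missing = meta["age"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} sample(s) without an age excluded", stacklevel=2
        )
        meta = meta[~missing]
    rows = []
    for group, sub in meta.groupby("group", sort=True):
        ages = sub["age"]
        rows.append(
            {
                "group": group,
                "n": int(len(ages)),
                "mean": float(ages.mean()),
                "display_mean": round(float(ages.mean()), 1),
                "min": float(ages.min()),
                "max": float(ages.max()),
            }
        )
    return pd.DataFrame(rows).set_index("group")
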