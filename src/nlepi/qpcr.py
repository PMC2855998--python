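"""Relative-quantification qPCR analysis and microarray direction validation.

Conventions (stated explicitly because the sign mapping is easy to invert):
a CT is the amplification cycle at threshold, so *lower CT means more
template*; dCT = CT(test gene) - CT(reference gene) per sample, so *lower dCT
means higher expression of the test gene*; ddCT = mean dCT(test group) -
mean dCT(reference group); the group fold change is 2^-ddCT under the exact
doubling-per-cycle assumption of the ddCT method.

A microarray fold > 1 in reference:test orientation (e.g. RM:HN fold of 4
means higher in RM) therefore predicts that a test-group sample's dCT exceeds
the reference-group mean dCT. A reaction "validates" when its dCT falls on
the predicted side; ties count as not validated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CtTable

Direction = Literal["higher-in-reference", "higher-in-test"]


@dataclass
class ValidationReport:
    """Per-gene, per-test-group ddCT summaries and direction-validation rates.

    ``per_gene`` columns: gene, group, n, mean_dct, sem_dct, ddct, fold,
    predicted_direction, n_validated, n_tested, validation_rate,
    t_p_one_tailed. ``overall_rate`` is total validated / total reactions
    (NaN when no reactions were testable).
    """

    per_gene: pd.DataFrame
    reference_group: str
    n_validated: int
    n_tested: int

    @property
    def overall_rate(self) -> float:
        if self.n_tested == 0:
            return float("nan")
        return self.n_validated / self.n_tested


def direction_from_fold(microarray_fold: float) -> Direction:
    """Predicted direction from a reference:test microarray fold change."""
    if microarray_fold <= 0:
        raise ValueError("fold must be positive")
    return "higher-in-reference" if microarray_fold > 1 else "higher-in-test"


def compute_dct(ct_table: CtTable) -> pd.DataFrame:
    """Per-sample dCT for every test gene: CT(test) - CT(reference gene).

    Samples lacking a reference-gene CT are excluded with a warning; their
    test-gene reactions cannot be normalised.
    """
    data = ct_table.data
    ref = data[data["gene"] == ct_table.reference_gene].set_index("sample_id")["ct"]
    test = data[data["gene"] != ct_table.reference_gene].copy()
    missing_ref = sorted(set(test["sample_id"]) - set(ref.index))
    if missing_ref:
        warnings.warn(
            f"samples without reference-gene CT excluded: {missing_ref}",
            stacklevel=2,
        )
        test = test[~test["sample_id"].isin(missing_ref)]
    test["dct"] = test["ct"].to_numpy() - ref.loc[test["sample_id"]].to_numpy()
    return test[["sample_id", "group", "gene", "dct"]].reset_index(drop=True)


def ddct_fold(mean_dct_test_group: float, mean_dct_reference_group: float) -> float:
    """Group fold change 2^-ddCT, ddCT = mean test dCT - mean reference dCT."""
    ddct = mean_dct_test_group - mean_dct_reference_group
    return float(2.0 ** (-ddct))


def validate_reaction(
    sample_dct: float, mean_reference_dct: float, predicted_direction: Direction
) -> bool:
    """Does one sample's dCT fall on the side the microarray predicted?

    'higher-in-reference' predicts lower expression in the test sample, i.e.
    sample dCT strictly above the reference mean; an exact tie is not
    validated.
    """
    if predicted_direction == "higher-in-reference":
        return sample_dct > mean_reference_dct
    if predicted_direction == "higher-in-test":
        return sample_dct < mean_reference_dct
    raise ValueError(f"unknown predicted direction {predicted_direction!r}")


def group_ttest_one_tailed(
    dcts_test: Sequence[float],
    dcts_reference: Sequence[float],
    predicted_direction: Direction,
) -> float:
    """One-tailed two-sample equal-variance t-test on per-sample dCT values.

    The tail follows the prediction: 'higher-in-reference' expects the test
    group's dCT to be larger. Returns NaN when the pooled variance is zero.
    """
    a = np.asarray(dcts_test, dtype=float)
    b = np.asarray(dcts_reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 dCT values per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return float("nan")
    alternative = "greater" if predicted_direction == "higher-in-reference" else "less"
    return float(
        stats.ttest_ind(a, b, equal_var=True, alternative=alternative).pvalue
    )


def summarize_validation(
    ct_table: CtTable,
    signature: Mapping[str, float],
    reference_group: str = "RM",
) -> ValidationReport:
    """Full validation report against microarray predictions.

    ``signature`` maps gene to its microarray fold change in
    reference:test orientation (fold > 1 means higher in the reference
    group). Genes in the CT table but absent from the signature are skipped
    with a warning. SEM = sample standard deviation (ddof=1) / sqrt(n).
    """
    dct = compute_dct(ct_table)
    known = sorted(set(dct["gene"]) & set(signature))
    skipped = sorted(set(dct["gene"]) - set(signature))
    if skipped:
        warnings.warn(f"genes absent from signature skipped: {skipped}", stacklevel=2)
    rows = []
    total_validated = 0
    total_tested = 0
    for gene in known:
        gene_dct = dct[dct["gene"] == gene]
        ref = gene_dct[gene_dct["group"] == reference_group]["dct"].to_numpy()
        if ref.size == 0:
            warnings.warn(
                f"gene {gene!r}: no reference-group reactions; skipped", stacklevel=2
            )
            continue
        mean_ref = float(ref.mean())
        direction = direction_from_fold(signature[gene])
        for group in sorted(set(gene_dct["group"]) - {reference_group}):
            vals = gene_dct[gene_dct["group"] == group]["dct"].to_numpy()
            n = vals.size
            validated = sum(
                validate_reaction(v, mean_ref, direction) for v in vals
            )
            total_validated += validated
            total_tested += n
            mean_dct = float(vals.mean())
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "n": n,
                    "mean_dct": mean_dct,
                    "sem_dct": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                    "ddct": mean_dct - mean_ref,
                    "fold": ddct_fold(mean_dct, mean_ref),
                    "predicted_direction": direction,
                    "n_validated": int(validated),
                    "n_tested": int(n),
                    "validation_rate": validated / n,
                    "t_p_one_tailed": (
                        group_ttest_one_tailed(vals, ref, direction)
                        if n >= 2 and ref.size >= 2
                        else float("nan")
                    ),
                }
            )
    return ValidationReport(
        per_gene=pd.DataFrame(
            rows,
            columns=[
                "gene",
                "group",
                "n",
                "mean_dct",
                "sem_dct",
                "ddct",
                "fold",
                "predicted_direction",
                "n_validated",
                "n_tested",
                "validation_rate",
                "t_p_one_tailed",
            ],
        ),
        reference_group=reference_group,
        n_validated=total_validated,
        n_tested=total_tested,
    )
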