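"""Readers/writers for the pipeline's tab-delimited table dialects.

The expression dialect mirrors GEO series-matrix conventions: a plain
tab-delimited block with probe sets in rows and a header row of sample ids,
optionally preceded by a ``!groups`` line carrying the sample group labels,
and followed (inline dialect) by a ``!detection`` block of the same shape
carrying MAS5-style Present/Marginal/Absent calls. With the sidecar dialect
the detection block lives in ``<path>.detection.tsv`` instead.

Also packages the two study-cohort fixtures: the 42-case cohort table
(groups, ages, receptor status) and the 98-probe-set signature table
(fold changes, probability scores, t-test p-values).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

VALID_DETECTION = frozenset({"P", "M", "A"})
VALID_GROUPS = frozenset({"RM", "HN", "PM"})

GROUPS_TAG = "!groups"
DETECTION_TAG = "!detection"
REFERENCE_TAG = "!reference_gene"

Dialect = Literal["inline", "sidecar"]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExpressionMatrix:
    """Probe-set x sample intensity matrix with detection calls and labels.

    ``intensities`` and ``detection`` are probe x sample DataFrames sharing
    index (probe ids) and columns (sample ids); ``groups`` maps sample id to
    one of RM / HN / PM; ``sample_meta`` optionally carries per-sample
    covariates (age, receptor status, distance class).
    """

    intensities: pd.DataFrame
    detection: pd.DataFrame
    groups: pd.Series
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.intensities.shape != self.detection.shape:
            raise ValueError(
                f"intensities {self.intensities.shape} and detection "
                f"{self.detection.shape} differ in shape"
            )
        if not self.intensities.index.equals(self.detection.index):
            raise ValueError("intensities and detection disagree on probe ids")
        if not self.intensities.columns.equals(self.detection.columns):
            raise ValueError("intensities and detection disagree on sample ids")
        if self.intensities.index.has_duplicates:
            dupes = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate probe ids: {list(dupes[:5])}")
        if self.intensities.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("intensities must be finite and non-negative")
        bad = set(np.unique(self.detection.to_numpy())) - VALID_DETECTION
        if bad:
            raise ValueError(f"unknown detection symbols: {sorted(bad)}")
        missing = set(self.intensities.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad_groups = set(self.groups.loc[list(self.intensities.columns)]) - VALID_GROUPS
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    # -- convenience views ---------------------------------------------------

    @property
    def probe_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_probes(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def select_probes(self, probe_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(probe_ids)
        missing = set(ids) - set(self.intensities.index)
        if missing:
            raise KeyError(f"probes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.intensities.loc[ids],
            self.detection.loc[ids],
            self.groups,
            self.sample_meta,
        )

    def select_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        missing = set(ids) - set(self.intensities.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            self.intensities[ids],
            self.detection[ids],
            self.groups.loc[ids],
            None if self.sample_meta is None else self.sample_meta.loc[ids],
        )

    def drop_sample(self, sample_id: str) -> "ExpressionMatrix":
        return self.select_samples([s for s in self.sample_ids if s != sample_id])


@dataclass
class CtTable:
    """qPCR cycle-threshold table: one row per (sample, gene) reaction.

    ``data`` has columns sample_id, group, gene, ct. Missing reactions are
    simply absent rows (per-primer sample availability is uneven in practice).
    """

    data: pd.DataFrame
    reference_gene: str = "CPSF6"

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        dupes = self.data.duplicated(subset=["sample_id", "gene"])
        if dupes.any():
            pair = self.data.loc[dupes, ["sample_id", "gene"]].iloc[0]
            raise ValueError(
                f"duplicate reaction for sample {pair.sample_id!r} gene {pair.gene!r}"
            )
        ct = pd.to_numeric(self.data["ct"], errors="coerce")
        if ct.isna().any():
            raise ValueError("non-numeric or missing CT value")
        self.data = self.data.assign(ct=ct)

    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())


SIGNATURE_COLUMNS = [
    "probe_id",
    "symbol",
    "fold_rm_hn",
    "probability_score",
    "t_p_value",
    "fold_rm_pm",
    "prior_study_flag",
]


def _validate_signature(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(SIGNATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"signature table missing columns: {sorted(missing)}")
    for col in ("fold_rm_hn", "fold_rm_pm"):
        if (table[col] <= 0).any():
            raise ValueError(f"{col} must be positive")
    for col in ("probability_score", "t_p_value"):
        if ((table[col] < 0) | (table[col] > 1)).any():
            raise ValueError(f"{col} must lie in [0, 1]")
    if table["probe_id"].duplicated().any():
        raise ValueError("duplicate probe_id in signature table")
    return table


# ---------------------------------------------------------------------------
# expression matrix dialect


def _detection_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".detection.tsv")


def _parse_block(
    lines: list[tuple[int, str]], what: str
) -> tuple[list[str], list[str], list[list[str]]]:
    """Parse a header+rows block; returns (sample_ids, probe_ids, cells)."""
    if not lines:
        raise ParseError(f"empty {what} block")
    header_no, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2:
        raise ParseError(f"line {header_no}: malformed header (need >=2 columns)")
    sample_ids = cols[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"line {header_no}: duplicate sample ids in header")
    probe_ids: list[str] = []
    rows: list[list[str]] = []
    seen: set[str] = set()
    for line_no, line in lines[1:]:
        cells = line.split("\t")
        if len(cells) != len(cols):
            raise ParseError(
                f"line {line_no}: expected {len(cols)} fields, found {len(cells)}"
            )
        if cells[0] in seen:
            raise ParseError(f"line {line_no}: duplicate probe id {cells[0]!r}")
        seen.add(cells[0])
        probe_ids.append(cells[0])
        rows.append(cells[1:])
    return sample_ids, probe_ids, rows


def read_expression_matrix(
    path: str | Path,
    dialect: Dialect = "inline",
    groups: pd.Series | dict | None = None,
) -> ExpressionMatrix:
    """Read the tab-delimited expression dialect.

    ``dialect='inline'`` expects the detection block after a ``!detection``
    tag in the same file; ``'sidecar'`` reads it from ``<path>.detection.tsv``.
    Group labels come from the ``!groups`` line unless passed explicitly.
    """
    path = Path(path)
    numbered = [
        (i + 1, line.rstrip("\n"))
        for i, line in enumerate(path.read_text().splitlines())
        if line.strip()
    ]
    groups_line: tuple[int, str] | None = None
    main: list[tuple[int, str]] = []
    det: list[tuple[int, str]] = []
    target = main
    for line_no, line in numbered:
        if line.startswith(GROUPS_TAG):
            groups_line = (line_no, line)
        elif line.startswith(DETECTION_TAG):
            target = det
        else:
            target.append((line_no, line))

    sample_ids, probe_ids, rows = _parse_block(main, "intensity")
    try:
        values = np.asarray(rows, dtype=float)
    except ValueError as exc:
        raise ParseError(f"non-numeric intensity value: {exc}") from exc
    intensities = pd.DataFrame(values, index=probe_ids, columns=sample_ids)

    if dialect == "sidecar":
        sidecar = _detection_sidecar(path)
        if not sidecar.exists():
            raise ParseError(f"detection sidecar not found: {sidecar}")
        det = [
            (i + 1, line.rstrip("\n"))
            for i, line in enumerate(sidecar.read_text().splitlines())
            if line.strip()
        ]
    if not det:
        raise ParseError(f"{path}: no detection block (dialect={dialect})")
    det_samples, det_probes, det_rows = _parse_block(det, "detection")
    if det_samples != sample_ids or det_probes != probe_ids:
        raise ParseError("detection block disagrees with intensity block layout")
    for row_idx, row in enumerate(det_rows):
        for col_idx, cell in enumerate(row):
            if cell not in VALID_DETECTION:
                raise ParseError(
                    f"unknown detection symbol {cell!r} for probe "
                    f"{probe_ids[row_idx]!r}, sample {sample_ids[col_idx]!r}"
                )
    detection = pd.DataFrame(det_rows, index=probe_ids, columns=sample_ids)

    if groups is None:
        if groups_line is None:
            raise ParseError(f"{path}: no {GROUPS_TAG} line and no groups given")
        line_no, line = groups_line
        labels = line.split("\t")[1:]
        if len(labels) != len(sample_ids):
            raise ParseError(
                f"line {line_no}: {len(labels)} group labels for "
                f"{len(sample_ids)} samples"
            )
        group_series = pd.Series(labels, index=sample_ids)
    else:
        group_series = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    return ExpressionMatrix(intensities, detection, group_series)


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, dialect: Dialect = "inline"
) -> None:
    """Write the expression dialect; inverse of :func:`read_expression_matrix`."""
    path = Path(path)
    buf = io.StringIO()
    labels = [matrix.groups[s] for s in matrix.sample_ids]
    buf.write(GROUPS_TAG + "\t" + "\t".join(labels) + "\n")
    matrix.intensities.to_csv(buf, sep="\t", index_label="probe_id", float_format="%.6g")
    det = io.StringIO()
    matrix.detection.to_csv(det, sep="\t", index_label="probe_id")
    if dialect == "inline":
        buf.write(DETECTION_TAG + "\n")
        buf.write(det.getvalue())
    else:
        _detection_sidecar(path).write_text(det.getvalue())
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# CT tables


def read_ct_table(path: str | Path) -> CtTable:
    path = Path(path)
    lines = path.read_text().splitlines()
    reference_gene = "CPSF6"
    skip = 0
    if lines and lines[0].startswith(REFERENCE_TAG):
        parts = lines[0].split("\t")
        if len(parts) != 2 or not parts[1]:
            raise ParseError(f"line 1: malformed {REFERENCE_TAG} line")
        reference_gene = parts[1]
        skip = 1
    data = pd.read_csv(io.StringIO("\n".join(lines[skip:])), sep="\t")
    return CtTable(data, reference_gene=reference_gene)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"{REFERENCE_TAG}\t{table.reference_gene}\n")
    table.data.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# packaged fixtures


def _fixture(name: str) -> pd.DataFrame:
    with resources.files("nlepi.data").joinpath(name).open() as handle:
        return pd.read_csv(handle, sep="\t")


def load_table2_fixture() -> pd.DataFrame:
    """The packaged 98-probe-set signature table.

    Fold orientation is reference-on-the-right: fold_rm_hn > 1 means higher
    expression in RM than HN (and likewise fold_rm_pm for RM vs PM).
    """
    table = _fixture("table2.tsv")
    table["prior_study_flag"] = table["prior_study_flag"].astype(bool)
    return _validate_signature(table)


def load_table1_fixture() -> pd.DataFrame:
    """The packaged 42-case cohort table (sample id, group, age, covariates)."""
    table = _fixture("table1.tsv")
    table["prior_study_flag"] = table["prior_study_flag"].astype(bool)
    if not set(table["group"]) <= VALID_GROUPS:
        raise ValueError("cohort fixture has unknown group labels")
    return table


# ---------------------------------------------------------------------------
# result tables

RESULT_COLUMNS = [
    "probe_id",
    "symbol",
    "fold",
    "probability_score",
    "t_p_value",
    "selection_frequency",
    "selected",
]


def write_results_table(
    scores,
    selection,
    path: str | Path,
    symbols: dict[str, str] | None = None,
) -> None:
    """Write the per-probe results table with a deterministic column order.

    ``scores`` is a list of BadgeScore; ``selection`` a SelectionResult whose
    probe set must match. ``symbols`` optionally maps probe id to gene symbol.
    """
    score_ids = [s.probe_id for s in scores]
    if list(selection.frequencies.index) != score_ids:
        raise ValueError("scores and selection cover different probe sets")
    symbols = symbols or {}
    rows = []
    for score in scores:
        rows.append(
            {
                "probe_id": score.probe_id,
                "symbol": symbols.get(score.probe_id, score.probe_id),
                "fold": score.fold,
                "probability_score": score.p_value,
                "t_p_value": selection.final_t_p[score.probe_id],
                "selection_frequency": selection.frequencies[score.probe_id],
                "selected": bool(selection.selected_mask[score.probe_id]),
            }
        )
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.10g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(Path(path), sep="\t")
    missing = set(RESULT_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"results table missing columns: {sorted(missing)}")
    return frame
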