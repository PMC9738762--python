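"""Data model and I/O for pharmacogenomic dose-response panels.

A :class:`DoseResponsePanel` holds a drugs x cell-lines matrix of IC50 (or
AUC) values together with per-line tissue/subtype annotations, mirroring the
shape of large public sensitivity screens (GDSC-style exports: one row per
compound, one column per cell line, blanks for unmeasured pairs).

IC50 values are stored internally in nM and must be strictly positive so that
log10 transforms downstream are always defined; non-positive or non-numeric
entries are coerced to missing on read, with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_UNIT_TO_NM = {"nM": 1.0, "uM": 1000.0, "µM": 1000.0}


@dataclass
class DoseResponsePanel:
    """Drug x cell-line sensitivity matrix with cell-line annotations.

    Parameters
    ----------
    ic50 : pandas.DataFrame
        Matrix of positive concentrations in nM, indexed by drug identifier
        with cell-line identifiers as columns. ``NaN`` marks a missing
        measurement.
    measure_kind : {"IC50", "AUC"}
    annotations : pandas.DataFrame, optional
        Indexed by cell-line identifier, with ``tissue`` and ``subtype``
        columns. Every annotated line must appear in the matrix.
    """

    ic50: pd.DataFrame
    measure_kind: str = "IC50"
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.ic50.size == 0:
            raise ValueError("empty dose-response matrix")
        if self.ic50.index.duplicated().any():
            dupes = self.ic50.index[self.ic50.index.duplicated()].tolist()
            raise ValueError(f"duplicate drug identifiers: {dupes}")
        if self.ic50.columns.duplicated().any():
            dupes = self.ic50.columns[self.ic50.columns.duplicated()].tolist()
            raise ValueError(f"duplicate cell-line identifiers: {dupes}")
        vals = self.ic50.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.isfinite(vals) & (vals <= 0)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} non-positive IC50 entries; coerce to missing first"
            )
        if self.measure_kind not in ("IC50", "AUC"):
            raise ValueError(f"unknown measure_kind {self.measure_kind!r}")
        if self.annotations is not None:
            unknown = self.annotations.index.difference(self.ic50.columns)
            if len(unknown):
                raise ValueError(
                    f"annotated lines absent from matrix: {unknown.tolist()}"
                )

    @property
    def drug_ids(self) -> list[str]:
        return list(self.ic50.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.ic50.columns)

    @property
    def n_missing(self) -> int:
        return int(self.ic50.isna().to_numpy().sum())

    def tissue_counts(self) -> pd.Series:
        """Number of lines per tissue label (annotated lines only)."""
        if self.annotations is None:
            raise ValueError("panel has no annotations")
        return self.annotations["tissue"].value_counts()


def _coerce_matrix(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Coerce a raw parsed table to a float matrix; return (matrix, n_coerced)."""
    numeric = df.apply(pd.to_numeric, errors="coerce")
    non_numeric = (~df.isna()) & numeric.isna()
    with np.errstate(invalid="ignore"):
        non_positive = numeric.le(0.0)
    n_coerced = int((non_numeric | non_positive).to_numpy().sum())
    numeric = numeric.mask(non_positive)
    return numeric.astype(float), n_coerced


def read_panel(
    path,
    orientation: str = "drugs_as_rows",
    unit: str = "nM",
    measure_kind: str = "IC50",
    annotations: pd.DataFrame | None = None,
) -> DoseResponsePanel:
    """Read a delimited IC50 matrix into a :class:`DoseResponsePanel`.

    The first column holds row identifiers and the header row holds column
    identifiers. Blank cells and the token ``NA`` are missing; any other
    non-numeric or non-positive entry is coerced to missing with a warning.

    Parameters
    ----------
    orientation : {"drugs_as_rows", "drugs_as_columns"}
        ``drugs_as_columns`` transposes after parsing, so a transposed export
        read with the flag flipped yields an identical panel.
    unit : {"nM", "uM"}
        Unit of the stored values; µM inputs are converted to nM.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=["NA", ""])
    if orientation == "drugs_as_columns":
        df = df.T
    elif orientation != "drugs_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str).rename(None)
    df.columns = df.columns.astype(str).rename(None)
    matrix, n_coerced = _coerce_matrix(df)
    if n_coerced:
        warnings.warn(
            f"{n_coerced} non-numeric or non-positive entries treated as missing",
            stacklevel=2,
        )
    matrix *= _UNIT_TO_NM[unit]
    panel = DoseResponsePanel(matrix, measure_kind=measure_kind, annotations=annotations)
    logger.info(
        "read panel: %d drugs x %d lines, %d missing",
        len(panel.drug_ids), len(panel.cell_line_ids), panel.n_missing,
    )
    return panel


def write_panel(panel: DoseResponsePanel, path, orientation: str = "drugs_as_rows") -> None:
    """Write the IC50 matrix back to disk (inverse of :func:`read_panel`)."""
    df = panel.ic50 if orientation == "drugs_as_rows" else panel.ic50.T
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df.to_csv(path, sep=sep, na_rep="NA")


def read_annotations(path) -> pd.DataFrame:
    """Read a cell-line annotation CSV (cell_line_id, tissue, subtype)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    ann = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "cell_line_id" not in ann.columns or "tissue" not in ann.columns:
        raise ValueError("annotation file needs cell_line_id and tissue columns")
    if "subtype" not in ann.columns:
        ann["subtype"] = ""
    ann = ann.set_index("cell_line_id")
    if ann.index.duplicated().any():
        raise ValueError("duplicate cell_line_id in annotation file")
    return ann


def read_drug_annotations(path) -> pd.DataFrame:
    """Read a drug annotation CSV (drug_id, target, target_pathway)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    ann = pd.read_csv(path, sep=sep, dtype=str)
    required = {"drug_id", "target", "target_pathway"}
    if not required.issubset(ann.columns):
        raise ValueError(f"drug annotation file needs columns {sorted(required)}")
    ann = ann.set_index("drug_id")
    if ann.index.duplicated().any():
        raise ValueError("duplicate drug_id in drug annotation file")
    return ann


def filter_by_tissue(panel: DoseResponsePanel, include) -> DoseResponsePanel:
    """Restrict a panel to cell lines whose tissue label is in ``include``.

    Matching is case-insensitive exact; the drug set is unchanged. Raises if
    the panel has no annotations or if no line survives the filter.
    """
    if panel.annotations is None:
        raise ValueError("panel has no tissue annotations to filter on")
    include_lc = {str(t).strip().lower() for t in include}
    if not include_lc:
        raise ValueError("empty tissue include set")
    tissues = panel.annotations["tissue"].astype(str).str.strip().str.lower()
    keep = tissues.index[tissues.isin(include_lc)]
    keep = [c for c in panel.cell_line_ids if c in set(keep)]
    if not keep:
        raise ValueError(f"no cell line retained for tissues {sorted(include_lc)}")
    sub = replace(
        panel,
        ic50=panel.ic50.loc[:, keep],
        annotations=panel.annotations.loc[keep],
    )
    counts = sub.tissue_counts()
    logger.info(
        "tissue filter retained %d lines: %s", len(keep),
        ", ".join(f"{t}={n}" for t, n in counts.items()),
    )
    return sub
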