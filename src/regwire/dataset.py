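"""Expression dataset container and TSV loaders.

The central object is :class:`ExpressionDataset`: a probe x sample matrix of
log2 intensities together with the sample design (genetic type / group,
hybridization series, optional family) and a probe annotation carrying gene
symbols and a regulatory-factor flag.  Missing values are an error at load
time, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataValidationError

__all__ = ["ExpressionDataset", "load_expression"]


@dataclass
class ExpressionDataset:
    """Probe x sample log2 intensity matrix plus design and annotation.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes in rows, samples in columns, log2-scale intensities.
    design : pandas.DataFrame
        Indexed by sample id, with at least columns ``group`` and ``series``.
    annotation : pandas.DataFrame
        Indexed by probe id, with columns ``gene_symbol`` and ``is_rf``.
    group_levels : tuple of str
        ``(reference, treatment)`` ordering of the two groups; contrasts and
        expression ratios are treatment relative to reference.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.DataFrame = None
    group_levels: tuple = None

    def __post_init__(self):
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                {"gene_symbol": self.values.index, "is_rf": False},
                index=self.values.index,
            )
        if self.group_levels is None:
            levels = list(pd.unique(self.design["group"]))
            if set(levels) == {"IB", "DUxIB"}:
                self.group_levels = ("IB", "DUxIB")
            else:
                self.group_levels = tuple(sorted(levels))
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check dataset invariants, raising :class:`DataValidationError`."""
        vals = self.values
        if vals.index.has_duplicates:
            dupes = vals.index[vals.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate probe ids: {dupes[:5]}")
        if vals.isna().any().any():
            probe = vals.index[vals.isna().any(axis=1)][0]
            sample = vals.columns[vals.isna().any(axis=0)][0]
            raise DataValidationError(
                f"missing expression value at probe {probe!r}, sample {sample!r}"
            )
        missing = set(vals.columns) - set(self.design.index)
        if missing:
            raise DataValidationError(
                f"samples absent from design: {sorted(missing)}"
            )
        extra = set(self.design.index) - set(vals.columns)
        if extra:
            raise DataValidationError(
                f"design rows without matrix column: {sorted(extra)}"
            )
        for col in ("group", "series"):
            if col not in self.design.columns:
                raise DataValidationError(f"design lacks required column {col!r}")
            if self.design[col].isna().any():
                bad = self.design.index[self.design[col].isna()][0]
                raise DataValidationError(f"sample {bad!r} has no {col}")
        if len(self.group_levels) != 2:
            raise DataValidationError(
                f"expected exactly 2 groups, found {self.group_levels}"
            )
        counts = self.design["group"].value_counts()
        for g in self.group_levels:
            if counts.get(g, 0) == 0:
                raise DataValidationError(f"group {g!r} has no samples")
        missing_probes = set(vals.index) - set(self.annotation.index)
        if missing_probes:
            raise DataValidationError(
                f"probes without annotation: {sorted(missing_probes)[:5]}"
            )

    # ------------------------------------------------------------------
    @property
    def probe_ids(self):
        return self.values.index

    @property
    def sample_ids(self):
        return self.values.columns

    def group_samples(self, group: str):
        """Sample ids belonging to one group, in matrix column order."""
        members = self.design.index[self.design["group"] == group]
        return [s for s in self.values.columns if s in set(members)]

    def group_matrix(self, group: str) -> np.ndarray:
        return self.values[self.group_samples(group)].to_numpy()

    def rf_probes(self):
        """Probe ids flagged as regulatory factors."""
        flag = self.annotation.loc[self.values.index, "is_rf"].astype(bool)
        return self.values.index[flag.to_numpy()]

    def subset(self, probe_ids) -> "ExpressionDataset":
        """Restrict the dataset to the given probes (order preserved)."""
        probe_ids = list(probe_ids)
        return ExpressionDataset(
            values=self.values.loc[probe_ids],
            design=self.design,
            annotation=self.annotation.loc[probe_ids],
            group_levels=self.group_levels,
        )

    # ------------------------------------------------------------------
    def write(self, matrix_path, design_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        self.design.to_csv(design_path, sep="\t", index_label="sample_id")


def _read_tsv(path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", **kw)


def load_expression(
    matrix_path,
    design_path,
    rf_list_path=None,
    *,
    linear_scale: bool = False,
) -> ExpressionDataset:
    """Load an expression matrix, sample design and RF list from TSV files.

    Parameters
    ----------
    matrix_path : path
        Probes x samples TSV; header row of sample ids, first column probe ids.
    design_path : path
        TSV with columns ``sample_id``, ``group``, ``series`` (``family``
        optional).
    rf_list_path : path, optional
        One regulatory-factor identifier per line (probe id or gene symbol).
    linear_scale : bool
        When True the matrix holds linear intensities and is log2-transformed
        on load.  There is no auto-detection.
    """
    matrix = _read_tsv(matrix_path, index_col=0)
    non_numeric = matrix.select_dtypes(exclude="number").columns
    if len(non_numeric):
        col = non_numeric[0]
        bad = matrix[col][pd.to_numeric(matrix[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise DataValidationError(
            f"non-numeric expression value in sample {col!r} at probe {where!r}"
        )
    if matrix.isna().any().any():
        probe = matrix.index[matrix.isna().any(axis=1)][0]
        sample = matrix.columns[matrix.isna().any(axis=0)][0]
        raise DataValidationError(
            f"empty cell at probe {probe!r}, sample {sample!r}"
        )
    if linear_scale:
        if (matrix.to_numpy() <= 0).any():
            raise DataValidationError("non-positive intensity on linear scale")
        matrix = np.log2(matrix)

    design = _read_tsv(design_path, index_col="sample_id")
    design.index = design.index.astype(str)
    matrix.columns = matrix.columns.astype(str)

    annotation = pd.DataFrame(
        {"gene_symbol": matrix.index, "is_rf": False}, index=matrix.index
    )
    if rf_list_path is not None:
        rf_ids = [
            line.strip()
            for line in Path(rf_list_path).read_text().splitlines()
            if line.strip()
        ]
        annotation.loc[annotation.index.intersection(rf_ids), "is_rf"] = True
        by_symbol = annotation["gene_symbol"].isin(rf_ids)
        annotation.loc[by_symbol, "is_rf"] = True

    return ExpressionDataset(values=matrix, design=design, annotation=annotation)
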