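"""Time-course expression container and TSV I/O.

The central object is :class:`TimeCourseMatrix`: a log2-scale gene × sample
expression table together with a sample design that maps every sample column
to an ordered time-point and a replicate index.  Time-point labels are pure
metadata — all downstream computation treats time-points as ordered
categories, never as numeric times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeCourseMatrix", "load_expression", "InvalidDesignError"]


class InvalidDesignError(ValueError):
    """Raised when the sample design does not describe a valid time course."""


@dataclass
class TimeCourseMatrix:
    """Log2 expression values with a time-point/replicate sample design.

    Parameters
    ----------
    values
        Genes × samples DataFrame of log2-scale intensities.  The index holds
        unique gene identifiers; columns are sample identifiers.
    design
        One row per sample (index = sample id) with columns ``time_point``
        (label) and ``replicate`` (int).  Time-point order is the order of
        first appearance in the design.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    time_order: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dupes[:5]}")
        if not {"time_point", "replicate"}.issubset(self.design.columns):
            raise InvalidDesignError("design needs 'time_point' and 'replicate' columns")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise InvalidDesignError(f"samples absent from design: {missing}")
        extra = [s for s in self.design.index if s not in self.values.columns]
        if extra:
            raise InvalidDesignError(f"design rows without matrix column: {extra}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.time_order is None:
            self.time_order = list(dict.fromkeys(self.design["time_point"]))
        counts = self.design["time_point"].value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise InvalidDesignError(f"time-points with < 2 replicates: {bad}")
        # keep matrix columns in design order
        self.values = self.values.loc[:, self.design.index]

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_timepoints(self) -> int:
        return len(self.time_order)

    def samples_at(self, time_point) -> list:
        """Sample ids belonging to one time-point, in design order."""
        mask = self.design["time_point"] == time_point
        return list(self.design.index[mask])

    def timepoint_means(self, log2: bool = True) -> pd.DataFrame:
        """Per-time-point replicate means (genes × time-points).

        Means are taken on the log2 scale; with ``log2=False`` the log2 means
        are exponentiated to the linear scale (this is the scale on which the
        chi-squared statistic and the fold change operate).
        """
        cols = {t: self.values[self.samples_at(t)].mean(axis=1) for t in self.time_order}
        means = pd.DataFrame(cols)[self.time_order]
        return means if log2 else 2.0**means

    # ------------------------------------------------------------------
    def to_tsv(self, matrix_path, design_path) -> None:
        self.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
        self.design.rename_axis("sample").to_csv(design_path, sep="\t")


def load_expression(matrix_path, design_path) -> TimeCourseMatrix:
    """Read an expression TSV (genes × samples) and design TSV into a validated matrix.

    The design file needs columns ``sample``, ``time_point``, ``replicate``;
    time-points are ordered as first encountered in the file.
    """
    matrix_path, design_path = Path(matrix_path), Path(design_path)
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[[not np.issubdtype(d, np.number) for d in values.dtypes]]
    if len(non_numeric):
        for col in non_numeric:
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric cell in column '{col}', row '{bad.index[0]}': {bad.iloc[0]!r}"
                )
        values = values.astype(float)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return TimeCourseMatrix(values=values, design=design)
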