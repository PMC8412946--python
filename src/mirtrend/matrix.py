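"""Feature-by-timepoint expression container used by the screen.

An :class:`ExpressionMatrix` holds nonnegative expression values (rpm-like or
raw counts) for a set of small-RNA features across an ordered series of ages,
together with the per-sample total read depth needed for min-depth
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class ExpressionMatrix:
    """Nonnegative expression values, features x ordered age samples.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with one column per sample; column
        labels are the age labels (months), kept as strings internally.
    ages
        Ages in months, strictly increasing, parallel to the columns.
    totals
        Per-sample total read depth (same order as columns). Optional; the
        screen can fall back to column sums when told to.
    """

    values: pd.DataFrame
    ages: list[float]
    totals: np.ndarray | None = None
    coverage: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.ages = [float(a) for a in self.ages]
        if self.values.shape[1] != len(self.ages):
            raise ValidationError(
                f"{self.values.shape[1]} columns but {len(self.ages)} ages"
            )
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValidationError(f"ages must be strictly increasing: {self.ages}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicated feature IDs: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("expression values must be nonnegative")
        if self.totals is not None:
            self.totals = np.asarray(self.totals, dtype=float)
            if self.totals.shape != (self.values.shape[1],):
                raise ValidationError("one total read depth required per sample")
            if (self.totals <= 0).any():
                raise ValidationError("total read depths must be positive")
        if self.coverage is not None and self.coverage.shape != self.values.shape:
            raise ValidationError("coverage table must match the value table shape")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            ages=list(self.ages),
            totals=None if self.totals is None else self.totals.copy(),
            coverage=None if self.coverage is None else self.coverage.copy(),
        )

    def trajectory(self, feature: str) -> np.ndarray:
        """Ordered expression values for one feature (youngest first)."""
        return self.values.loc[feature].to_numpy(dtype=float)
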