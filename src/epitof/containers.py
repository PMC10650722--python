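"""In-memory containers for per-cell marker data.

``CellMatrix`` holds raw abundances with per-cell sample/group annotation;
``NormalizedMatrix`` holds residual-normalized HPTM abundances aligned to
its source. Both are thin typed wrappers over pandas objects so that the
invariants (finite values, complete annotation, panel consistency) are
checked once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .panels import MarkerPanel, SchemaError

# Canonical group labels and accepted aliases.
GROUP_HEALTHY = "HCB"
GROUP_DISEASE = "JSP"
_GROUP_ALIASES = {
    "HCB": GROUP_HEALTHY,
    "UCB": GROUP_HEALTHY,
    "HD UCB": GROUP_HEALTHY,
    "HEALTHY": GROUP_HEALTHY,
    "JSP": GROUP_DISEASE,
    "JMML": GROUP_DISEASE,
    "DISEASE": GROUP_DISEASE,
}


def normalize_group_labels(groups: pd.Series) -> pd.Series:
    """Map group aliases (UCB/healthy, JMML/disease) onto {HCB, JSP}."""
    mapped = groups.astype(str).str.strip().str.upper().map(_GROUP_ALIASES)
    if mapped.isna().any():
        bad = sorted(groups[mapped.isna()].astype(str).unique())
        raise SchemaError(f"unrecognized group labels: {bad}")
    return mapped.rename(groups.name)


@dataclass
class CellMatrix:
    """Cells x markers raw abundance matrix with sample/group annotation.

    ``values`` columns are exactly ``panel.all_markers`` (HPTMs followed by
    the total-histone regressors); extra input columns are preserved in
    ``annotations``.
    """

    values: pd.DataFrame
    sample_id: pd.Series
    group: pd.Series
    panel: MarkerPanel
    annotations: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [m for m in self.panel.all_markers if m not in self.values.columns]
        if missing:
            raise SchemaError(f"missing marker column(s): {missing}")
        self.values = self.values.loc[:, list(self.panel.all_markers)].astype(float)
        n = len(self.values)
        self.sample_id = pd.Series(np.asarray(self.sample_id, dtype=object),
                                   index=self.values.index, name="sample_id")
        self.group = normalize_group_labels(
            pd.Series(np.asarray(self.group, dtype=object),
                      index=self.values.index, name="group"))
        if len(self.sample_id) != n or len(self.group) != n:
            raise SchemaError("sample_id/group length does not match cell count")
        if self.sample_id.isna().any() or self.group.isna().any():
            raise SchemaError("sample_id/group must have no missing entries")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise SchemaError("marker values must all be finite")
        if self.annotations is not None:
            self.annotations = self.annotations.set_axis(self.values.index, axis=0)

    @property
    def n_cells(self) -> int:
        return len(self.values)

    @property
    def hptm(self) -> pd.DataFrame:
        """HPTM channels only."""
        return self.values.loc[:, list(self.panel.hptm_markers)]

    @property
    def regressors(self) -> pd.DataFrame:
        """Total-histone channels (H3/H4 by default)."""
        return self.values.loc[:, list(self.panel.regressor_markers)]

    def sample_groups(self) -> pd.Series:
        """Group label per sample (each sample belongs to exactly one group)."""
        tab = pd.crosstab(self.sample_id, self.group)
        if (tab.gt(0).sum(axis=1) > 1).any():
            raise SchemaError("a sample maps to more than one group")
        return tab.idxmax(axis=1).rename("group")


@dataclass
class NormalizedMatrix:
    """Residual-normalized HPTM abundances, row-aligned with the source cells.

    Only HPTM columns are kept: the total-histone regressors are consumed
    by the normalization and excluded from all downstream features.
    """

    residuals: pd.DataFrame
    sample_id: pd.Series
    group: pd.Series
    panel: MarkerPanel

    def __post_init__(self) -> None:
        expected = list(self.panel.hptm_markers)
        if list(self.residuals.columns) != expected:
            raise SchemaError("residual columns must be exactly the panel HPTMs")
        if not (len(self.residuals) == len(self.sample_id) == len(self.group)):
            raise SchemaError("annotation length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.residuals)

    def subset(self, positions: np.ndarray) -> "NormalizedMatrix":
        """Row subset by integer positions, preserving order of ``positions``."""
        return NormalizedMatrix(
            residuals=self.residuals.iloc[positions],
            sample_id=self.sample_id.iloc[positions],
            group=self.group.iloc[positions],
            panel=self.panel,
        )
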