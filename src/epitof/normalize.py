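"""Two-step EpiTOF normalization.

Step 1 rescales raw ion-count-derived abundances (divide by a cofactor,
optionally arcsinh-compressed) to tame the dynamic range. Step 2 fits,
separately for every sample, an ordinary least-squares regression of each
transformed HPTM on the transformed total-histone channels,

    HPTM_{i,j} = b0 + b1 * H3_i + b2 * H4_i + eps_{i,j},

and keeps the residual eps_{i,j} as the normalized abundance. Regressing
on total H3/H4 removes per-cell differences in overall histone content
(cell size, ionization efficiency) so residuals reflect relative mark
abundance.

The model/results pair follows the statsmodels convention:
``ResidualRegression(cells).fit()`` returns ``ResidualRegressionResults``
carrying the normalized matrix, the per-(sample, HPTM) coefficients and a
``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CellMatrix, NormalizedMatrix
from .panels import SchemaError

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class TransformSpec:
    """Abundance transform: ``scale`` is x/cofactor, ``arcsinh`` is asinh(x/cofactor)."""

    kind: str = "scale"
    cofactor: float = 50.0

    def __post_init__(self) -> None:
        if self.kind not in ("scale", "arcsinh"):
            raise ValidationError(f"unknown transform kind {self.kind!r}")
        if not self.cofactor > 0:
            raise ValidationError("cofactor must be > 0")


def transform_abundance(raw, spec: TransformSpec = TransformSpec()):
    """Apply the abundance transform elementwise; shape is preserved."""
    arr = np.asarray(raw, dtype=float)
    if not np.isfinite(arr).all():
        raise ValidationError("raw abundances must be finite")
    if (arr < 0).any():
        raise ValidationError("raw abundances must be nonnegative")
    out = arr / spec.cofactor
    if spec.kind == "arcsinh":
        out = np.arcsinh(out)
    if isinstance(raw, pd.DataFrame):
        return pd.DataFrame(out, index=raw.index, columns=raw.columns)
    return out


class ResidualRegression:
    """Per-sample residual normalization of HPTMs against total H3/H4.

    Parameters
    ----------
    cells : CellMatrix
        Raw per-cell abundances with sample annotation; the panel names
        the regressor channels.
    transform : TransformSpec
        Applied identically to HPTM and regressor channels before the fit.
    min_cells : int
        Samples with fewer cells than this cannot identify the three
        regression parameters and raise an error (default 3).
    """

    def __init__(self, cells: CellMatrix, transform: TransformSpec = TransformSpec(),
                 min_cells: int = 3):
        if len(cells.panel.regressor_markers) < 1:
            raise SchemaError("panel defines no regressor channels")
        self.cells = cells
        self.transform = transform
        self.min_cells = min_cells

    def fit(self) -> "ResidualRegressionResults":
        cells = self.cells
        hptm_names = list(cells.panel.hptm_markers)
        reg_names = list(cells.panel.regressor_markers)
        hptm_t = transform_abundance(cells.hptm.to_numpy(), self.transform)
        reg_t = transform_abundance(cells.regressors.to_numpy(), self.transform)

        residuals = np.empty_like(hptm_t)
        records = []
        sample_codes, sample_names = pd.factorize(cells.sample_id)
        for s, name in enumerate(sample_names):
            rows = np.flatnonzero(sample_codes == s)
            if len(rows) < self.min_cells:
                raise ValidationError(
                    f"sample {name!r} has {len(rows)} cells; "
                    f"at least {self.min_cells} are required to fit the regression")
            X_full = np.column_stack([np.ones(len(rows)), reg_t[rows]])
            kept = _independent_columns(X_full)
            rank_ok = len(kept) == X_full.shape[1]
            if not rank_ok:
                dropped = [(["intercept"] + reg_names)[j]
                           for j in range(X_full.shape[1]) if j not in kept]
                log.warning("sample %r: rank-deficient design, dropping %s",
                            name, dropped)
            X = X_full[:, kept]
            beta_kept, *_ = np.linalg.lstsq(X, hptm_t[rows], rcond=None)
            beta = np.zeros((X_full.shape[1], len(hptm_names)))
            beta[kept] = beta_kept
            residuals[rows] = hptm_t[rows] - X @ beta_kept
            for j, hname in enumerate(hptm_names):
                rec = {"sample_id": name, "hptm": hname, "n_cells": len(rows),
                       "rank_ok": rank_ok, "beta0": beta[0, j]}
                for r, rname in enumerate(reg_names, start=1):
                    rec[f"beta_{rname}"] = beta[r, j]
                records.append(rec)

        normalized = NormalizedMatrix(
            residuals=pd.DataFrame(residuals, index=cells.values.index,
                                   columns=hptm_names),
            sample_id=cells.sample_id,
            group=cells.group,
            panel=cells.panel,
        )
        fits = pd.DataFrame.from_records(records)
        return ResidualRegressionResults(self, normalized, fits)


class ResidualRegressionResults:
    """Fit results: normalized residual matrix plus per-(sample, HPTM) coefficients."""

    def __init__(self, model: ResidualRegression, normalized: NormalizedMatrix,
                 fits: pd.DataFrame):
        self.model = model
        self.normalized = normalized
        self.fits = fits

    @property
    def residuals(self) -> pd.DataFrame:
        return self.normalized.residuals

    def summary(self) -> str:
        f = self.fits
        lines = [
            "Residual normalization (per-sample OLS on total-histone channels)",
            f"  transform: {self.model.transform.kind} "
            f"(cofactor {self.model.transform.cofactor:g})",
            f"  samples: {f['sample_id'].nunique()}   HPTMs: {f['hptm'].nunique()}",
            f"  cells: {self.normalized.n_cells}",
            f"  rank-deficient sample fits: {int((~f['rank_ok']).sum())}",
        ]
        return "\n".join(lines)


def fit_residual_normalization(
    cells: CellMatrix, spec: TransformSpec = TransformSpec()
) -> tuple[NormalizedMatrix, pd.DataFrame]:
    """Convenience wrapper: fit and return (NormalizedMatrix, fit table)."""
    res = ResidualRegression(cells, transform=spec).fit()
    return res.normalized, res.fits


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy left-to-right selection of linearly independent columns.

    The intercept column comes first, so constant or collinear regressors
    are the ones dropped — constant H3/H4 degrades to mean-centering.
    """
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        scale = np.linalg.norm(cand, axis=0).prod()
        if np.linalg.matrix_rank(cand, tol=tol * max(scale, 1.0)) == len(kept) + 1:
            kept.append(j)
    return kept
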