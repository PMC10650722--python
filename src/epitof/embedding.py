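"""Stratified subsampling and 2-D UMAP embedding.

The study design embeds a fixed-size random subset — by default 10,000
cells from each stratum (antibody panel x disease group), 40,000 cells in
all — and computes UMAP with n_neighbors=15 and min_dist=0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import NormalizedMatrix
from .normalize import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubsampleSpec:
    """Per-stratum uniform subsample without replacement.

    ``strata`` names the annotation(s) defining strata; the default is the
    disease group alone (single-panel runs). ``target`` is the number of
    cells drawn per stratum; strata smaller than the target are kept whole.
    """

    target: int = 10_000
    strata: tuple[str, ...] = ("group",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target < 1:
            raise ValidationError("subsample target must be >= 1")


def stratified_subsample(
    norm: NormalizedMatrix, spec: SubsampleSpec,
    extra_strata: pd.DataFrame | None = None,
) -> tuple[NormalizedMatrix, np.ndarray]:
    """Draw min(target, stratum size) cells uniformly per stratum.

    Returns the subset (rows in original order) and the selected integer
    positions. Deterministic given ``spec.seed``.
    """
    cols = {}
    for name in spec.strata:
        if name == "group":
            cols[name] = norm.group.to_numpy()
        elif name == "sample_id":
            cols[name] = norm.sample_id.to_numpy()
        elif extra_strata is not None and name in extra_strata.columns:
            cols[name] = extra_strata[name].to_numpy()
        else:
            raise ValidationError(f"unknown stratum annotation {name!r}")
    labels = pd.DataFrame(cols)
    if labels.isna().any().any():
        raise ValidationError("stratum labels must be present on every cell")
    keys = pd.MultiIndex.from_frame(labels)

    rng = np.random.default_rng(spec.seed)
    selected: list[np.ndarray] = []
    for key in sorted(keys.unique()):
        rows = np.flatnonzero(keys == key)
        if len(rows) == 0:  # pragma: no cover - unique() excludes empties
            raise ValidationError(f"empty stratum {key}")
        if len(rows) <= spec.target:
            if len(rows) < spec.target:
                log.warning("stratum %s has %d < target %d cells; keeping all",
                            key, len(rows), spec.target)
            selected.append(rows)
        else:
            selected.append(rng.choice(rows, size=spec.target, replace=False))
    positions = np.sort(np.concatenate(selected))
    return norm.subset(positions), positions


@dataclass
class Embedding:
    """2-D coordinates plus the parameters that produced them."""

    coords: np.ndarray
    n_neighbors: int
    min_dist: float
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("embedding must be (cells x 2)")
        if not np.isfinite(self.coords).all():
            raise ValidationError("embedding coordinates must be finite")


def embed_umap(
    data: NormalizedMatrix | pd.DataFrame | np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> Embedding:
    """2-D UMAP of the residual-normalized marker space.

    A fixed seed makes the embedding reproducible run-to-run on the same
    platform (umap-learn falls back to single-threaded layout when a
    random_state is given).
    """
    if isinstance(data, NormalizedMatrix):
        X = data.residuals.to_numpy()
    else:
        X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < n_neighbors + 1:
        raise ValidationError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}; "
            "reduce n_neighbors")
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 features to embed")
    import umap  # deferred: numba compilation is slow at import time

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed)
    coords = reducer.fit_transform(X)
    return Embedding(coords=coords, n_neighbors=n_neighbors,
                     min_dist=min_dist, seed=seed)
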