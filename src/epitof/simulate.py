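"""Synthetic EpiTOF and ATAC data with known ground truth.

The cell simulator emulates the structure the normalization and
clustering stages assume: heavy-tailed nonnegative marker abundances
whose expectation depends linearly (in transformed units) on latent
total-histone levels, planted cell subpopulations with additive mark
shifts, and group-specific subpopulation mixing so that disease
enrichment of a subpopulation is a recoverable signal. The region
simulator draws negative-binomial counts with a planted fraction of
differential regions.

Defaults mirror the study design: 5 samples per disease group and per
healthy group, a methylation-style panel of 11 marks regressed on total
H3/H4.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .atac import RegionCountMatrix
from .containers import GROUP_DISEASE, GROUP_HEALTHY, CellMatrix
from .normalize import ValidationError
from .panels import MarkerPanel

DEFAULT_HPTMS = (
    "H3K27me3", "H3K27me1", "H3K9me1", "H3K9me2", "H3K4me2", "H3K4me3",
    "H4K20me1", "H4K20me2", "H3K36me3", "Rme2asy", "Rme2sym",
)


class ConfigurationError(ValidationError):
    pass


@dataclass
class EpiTofSimConfig:
    """Configuration of the per-cell simulator.

    ``subpop_effects`` maps (subpop index, marker name) to an additive
    shift in transformed units; ``subpop_group_weights`` gives per-group
    mixing proportions over subpopulations (each summing to 1);
    ``histone_coupling`` maps marker -> (b1, b2) linear coefficients on
    the latent transformed H3/H4 levels; ``noise_scale`` is the SD of the
    per-cell Gaussian noise in transformed units.
    """

    n_samples_per_group: int = 5
    cells_per_sample: int = 2000
    hptm_names: Sequence[str] = DEFAULT_HPTMS
    n_subpops: int = 1
    subpop_effects: Mapping[tuple[int, str], float] = field(default_factory=dict)
    subpop_group_weights: Optional[Mapping[str, Sequence[float]]] = None
    histone_coupling: Optional[Mapping[str, tuple[float, float]]] = None
    noise_scale: float = 0.3
    cofactor: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")
        if self.cells_per_sample < 1:
            raise ConfigurationError("cells_per_sample must be >= 1")
        if not self.noise_scale > 0:
            raise ConfigurationError("noise_scale must be > 0")
        if self.subpop_group_weights is None:
            uniform = [1.0 / self.n_subpops] * self.n_subpops
            self.subpop_group_weights = {GROUP_HEALTHY: uniform,
                                         GROUP_DISEASE: list(uniform)}
        for group, w in self.subpop_group_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != self.n_subpops or not np.isclose(w.sum(), 1.0):
                raise ConfigurationError(
                    f"mixing weights for group {group!r} must be "
                    f"{self.n_subpops} values summing to 1")
        for (sub, marker) in self.subpop_effects:
            if not 0 <= sub < self.n_subpops:
                raise ConfigurationError(f"effect references subpop {sub}")
            if marker not in self.hptm_names:
                raise ConfigurationError(f"effect references marker {marker!r}")

    def panel(self) -> MarkerPanel:
        return MarkerPanel(hptm_markers=tuple(self.hptm_names),
                           panel_name="custom")


@dataclass
class GroundTruth:
    """What the simulator planted: per-cell subpop, effect signs, regions."""

    subpop: Optional[np.ndarray] = None
    effect_signs: Optional[dict] = None
    region_differential: Optional[pd.DataFrame] = None


def simulate_epitof(config: EpiTofSimConfig) -> tuple[CellMatrix, GroundTruth]:
    """Simulate a multi-sample EpiTOF dataset.

    Latent total-histone levels are correlated lognormals; each HPTM's
    transformed abundance is baseline + b1*H3 + b2*H4 + subpop shift +
    Gaussian noise, then mapped back to raw scale (clipped at zero and
    multiplied by the cofactor) so that the residual regression has a
    recoverable linear signal. Group labels are assigned per sample.
    """
    rng = np.random.default_rng(config.seed)
    markers = list(config.hptm_names)
    coupling = config.histone_coupling or {m: (0.8, 0.4) for m in markers}
    b1 = np.array([coupling.get(m, (0.8, 0.4))[0] for m in markers])
    b2 = np.array([coupling.get(m, (0.8, 0.4))[1] for m in markers])
    baseline = 0.5 + 0.05 * np.arange(len(markers))

    blocks, sample_ids, groups, subpops = [], [], [], []
    for group in (GROUP_HEALTHY, GROUP_DISEASE):
        weights = np.asarray(config.subpop_group_weights[group], dtype=float)
        for s in range(config.n_samples_per_group):
            n = config.cells_per_sample
            name = f"{group}{s + 1}"
            # per-sample marker offsets: biological sample-to-sample noise
            sample_shift = rng.normal(0.0, 0.05, size=len(markers))
            z = rng.choice(config.n_subpops, size=n, p=weights)
            log_h = rng.multivariate_normal(
                mean=[0.6, 0.3],
                cov=[[0.16, 0.7 * 0.4 * 0.35], [0.7 * 0.4 * 0.35, 0.1225]],
                size=n)
            h3, h4 = np.exp(log_h[:, 0]), np.exp(log_h[:, 1])
            t = (baseline[None, :] + sample_shift[None, :]
                 + np.outer(h3, b1) + np.outer(h4, b2)
                 + rng.normal(0.0, config.noise_scale, size=(n, len(markers))))
            for (sub, marker), shift in config.subpop_effects.items():
                t[z == sub, markers.index(marker)] += shift
            raw_hptm = np.clip(t, 0.0, None) * config.cofactor
            # measured total-histone channels carry small assay noise
            meas_h3 = h3 * np.exp(rng.normal(0.0, 0.02, size=n)) * config.cofactor
            meas_h4 = h4 * np.exp(rng.normal(0.0, 0.02, size=n)) * config.cofactor
            blocks.append(np.column_stack([raw_hptm, meas_h3, meas_h4]))
            sample_ids.extend([name] * n)
            groups.extend([group] * n)
            subpops.append(z)

    panel = config.panel()
    values = pd.DataFrame(np.vstack(blocks), columns=list(panel.all_markers))
    cells = CellMatrix(values=values,
                       sample_id=pd.Series(sample_ids, dtype=object),
                       group=pd.Series(groups, dtype=object),
                       panel=panel)
    signs = {key: int(np.sign(v)) for key, v in config.subpop_effects.items()}
    truth = GroundTruth(subpop=np.concatenate(subpops), effect_signs=signs)
    return cells, truth


def planted_study_config(
    n_subpops: int,
    seed: int = 0,
    n_samples_per_group: int = 4,
    cells_per_sample: int = 2000,
    effect: float = 2.0,
    enrichment_delta: Optional[float] = None,
) -> EpiTofSimConfig:
    """Scaled-down study design with recoverable planted structure.

    Subpopulation 0 is the unshifted baseline; each further subpopulation
    s shifts three marks (a rolling triplet over the panel, alternating
    sign by subpopulation) by ``effect`` transformed units — with the
    default noise scale 0.3 that is ~6.7 noise SDs. Mixing weights give
    every subpopulation the same pooled size; disease enrichment
    alternates across subpopulations (odd indices disease-enriched, even
    indices healthy-enriched, the middle one neutral when n_subpops is
    odd) with per-subpopulation delta ``enrichment_delta`` (default
    0.5/n_subpops, a 3:1 disease:healthy ratio). Subpopulation 1 is
    always disease-enriched.
    """
    if n_subpops < 2:
        raise ConfigurationError("a planted study needs >= 2 subpopulations")
    marks = list(DEFAULT_HPTMS)
    effects = {}
    for s in range(1, n_subpops):
        sign = -1.0 if s % 2 else 1.0
        for j in range(3):
            effects[(s, marks[(3 * (s - 1) + j) % len(marks)])] = sign * effect
    d = 0.5 / n_subpops if enrichment_delta is None else enrichment_delta
    base = 1.0 / n_subpops
    deltas = [(-d if i % 2 == 0 else d) for i in range(n_subpops)]
    if n_subpops % 2:
        deltas[n_subpops // 2 if n_subpops // 2 % 2 == 0 else -1] = 0.0
    w_hcb = [base - x for x in deltas]
    w_jsp = [base + x for x in deltas]
    return EpiTofSimConfig(
        n_samples_per_group=n_samples_per_group,
        cells_per_sample=cells_per_sample,
        n_subpops=n_subpops,
        subpop_effects=effects,
        subpop_group_weights={GROUP_HEALTHY: w_hcb, GROUP_DISEASE: w_jsp},
        seed=seed)


def simulate_region_counts(
    n_regions: int,
    n_per_group: int,
    frac_diff: float,
    log2fc: float,
    dispersion: float,
    seed: int = 0,
) -> tuple[RegionCountMatrix, GroundTruth]:
    """Simulate a region x sample count matrix with planted differences.

    Counts are negative-binomial with var = mu + dispersion * mu^2; a
    ``frac_diff`` fraction of regions has the disease-group mean scaled
    by 2**log2fc. Sample library sizes vary lognormally.
    """
    if not 0 <= frac_diff <= 1:
        raise ConfigurationError("frac_diff must be in [0, 1]")
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be nonnegative")
    rng = np.random.default_rng(seed)
    base_mean = np.exp(rng.normal(np.log(200.0), 0.8, size=n_regions))
    n_diff = int(round(frac_diff * n_regions))
    diff_idx = rng.choice(n_regions, size=n_diff, replace=False)
    scale = np.ones(n_regions)
    scale[diff_idx] = 2.0 ** log2fc

    samples = ([f"{GROUP_HEALTHY}_{i + 1}" for i in range(n_per_group)]
               + [f"{GROUP_DISEASE}_{i + 1}" for i in range(n_per_group)])
    groups = pd.Series([GROUP_HEALTHY] * n_per_group
                       + [GROUP_DISEASE] * n_per_group, index=samples)
    lib = np.exp(rng.normal(0.0, 0.1, size=2 * n_per_group))

    counts = np.empty((n_regions, 2 * n_per_group), dtype=np.int64)
    for j in range(2 * n_per_group):
        mu = base_mean * lib[j]
        if groups.iloc[j] == GROUP_DISEASE:
            mu = mu * scale
        if dispersion == 0:
            counts[:, j] = rng.poisson(mu)
        else:
            n_nb = 1.0 / dispersion
            counts[:, j] = rng.negative_binomial(n_nb, n_nb / (n_nb + mu))

    regions = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n_regions) * 1000,
        "end": np.arange(n_regions) * 1000 + 500,
    })
    matrix = RegionCountMatrix(
        regions=regions,
        counts=pd.DataFrame(counts, columns=samples),
        group=groups)
    direction = np.zeros(n_regions, dtype=int)
    direction[diff_idx] = int(np.sign(log2fc))
    truth = GroundTruth(region_differential=pd.DataFrame({
        "differential": np.isin(np.arange(n_regions), diff_idx) & (log2fc != 0),
        "direction": direction,
    }))
    return matrix, truth


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Serialize ground truth to JSON (arrays as lists)."""
    import json

    payload = {}
    if truth.subpop is not None:
        payload["subpop"] = truth.subpop.tolist()
    if truth.effect_signs is not None:
        payload["effect_signs"] = {f"{s}|{m}": v
                                   for (s, m), v in truth.effect_signs.items()}
    if truth.region_differential is not None:
        payload["region_differential"] = truth.region_differential.to_dict("list")
    with open(path, "w") as fh:
        json.dump(payload, fh)
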