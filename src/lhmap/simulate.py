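"""Synthetic cohorts carrying the statistical structure of the LH study.

Three generators stand in for the study's data:

* a two-phenotype shuttle-box cohort (a ~22% helpless / 78% resilient
  mixture; per-trial shuttle times from truncated normals per phenotype,
  with failures as latencies censored at the 10 s shock end),
* paired region-count matrices (negative-binomial counts with a shared
  log-normal pair-level nuisance offset — exactly the confound the blocking
  variable absorbs — and group effects of known sign in designated signal
  regions),
* 3-D cell clouds in a toy box-parcellated label atlas (Poisson counts per
  region, uniform placement), for the sphere-voxel density pipeline.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .behavior import CUE_DURATION_S, HELPLESS, RESILIENT, TRIAL_WINDOW_S

__all__ = [
    "BehaviorSimParams",
    "CountSimParams",
    "CloudSimParams",
    "LabelAtlas",
    "gen_behavior_cohort",
    "gen_region_counts",
    "gen_cell_cloud",
]


@dataclass(frozen=True)
class BehaviorSimParams:
    """Parameters of the two-phenotype behavioral mixture.

    ``latency_means``/``latency_sds`` describe the latent escape latency
    (seconds from shock onset) per phenotype (resilient, helpless);
    ``failure_rates`` is an extra per-trial probability of outright failure.
    Defaults emulate the published cohort: 144 animals, ~22% helpless,
    35 trials per session, resilient animals escaping in ~1 s with rare
    failures, helpless animals near the 10 s censoring limit.
    """

    n_animals: int = 144
    p_helpless: float = 0.22
    n_trials: int = 35
    latency_means: tuple[float, float] = (1.0, 8.5)
    latency_sds: tuple[float, float] = (1.5, 2.0)
    failure_rates: tuple[float, float] = (0.02, 0.55)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_helpless <= 1.0:
            raise ValueError("p_helpless must lie in [0, 1]")
        if self.n_animals < 1:
            raise ValueError("n_animals must be positive")
        if self.n_trials < 6:
            raise ValueError("n_trials must be at least 6")
        for m in self.latency_means:
            if not 0.0 <= m <= 10.0:
                raise ValueError("latency means must lie within the 10 s shock window")
        for r in self.failure_rates:
            if not 0.0 <= r <= 1.0:
                raise ValueError("failure rates are probabilities")


def gen_behavior_cohort(params: BehaviorSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-trial shuttle times plus true phenotype labels.

    Returns ``(trials, truth)``: a trial table (animal_id, trial_index,
    shuttle_time with NaN = failure) and a truth table (animal_id,
    phenotype).  A trial fails outright with the phenotype's failure rate;
    otherwise its latent escape latency is drawn normal and censored —
    latencies past the 10 s shock end become failures, negative latencies
    become avoidances (a shuttle during the cue).
    """
    rng = np.random.default_rng(params.seed)
    n, nt = params.n_animals, params.n_trials
    ids = np.array([f"M{i + 1:04d}" for i in range(n)])
    pheno = np.where(rng.random(n) < params.p_helpless, HELPLESS, RESILIENT)
    g = (pheno == HELPLESS).astype(int)
    means = np.asarray(params.latency_means)[g][:, None]
    sds = np.asarray(params.latency_sds)[g][:, None]
    frates = np.asarray(params.failure_rates)[g][:, None]
    lat = rng.normal(means, sds, (n, nt))
    fail = (rng.random((n, nt)) < frates) | (lat >= 10.0)
    shuttle = np.clip(CUE_DURATION_S + lat, 0.0, TRIAL_WINDOW_S - 1e-9)
    shuttle[fail] = np.nan
    trials = pd.DataFrame(
        {
            "animal_id": np.repeat(ids, nt),
            "trial_index": np.tile(np.arange(1, nt + 1), n),
            "shuttle_time": shuttle.ravel(),
        }
    )
    truth = pd.DataFrame({"animal_id": ids, "phenotype": pheno})
    return trials, truth


@dataclass(frozen=True)
class CountSimParams:
    """Parameters of the paired region-count generator.

    Counts are NB2 (variance = mu + dispersion * mu**2) around a log mean
    ``log(region baseline) + pair offset (+/- group effect)``.  Region
    baselines are log-normal around ``baseline_mean`` with log-scale SD
    ``region_profile_sd``: real per-region activity counts span orders of
    magnitude with region size, and this shared profile is what makes
    brain-wide activity vectors of different animals strongly positively
    correlated (the geometry the stereotypy bootstrap operates in); set it
    to 0 for a flat baseline.  The pair offset, shared by both animals of a
    pair, is normal with SD ``pair_sd`` on the log scale.  ``signal_regions`` lists indices (0-based) of regions
    carrying a group effect of size ``log_fold_change``; directions default
    to +1 (resilient higher, the dominant direction in this paradigm) and
    may be flipped per region via ``signal_directions`` (-1 = helpless
    higher, LC-like).
    """

    n_pairs: int = 11
    n_regions: int = 100
    baseline_mean: float = 100.0
    region_profile_sd: float = 1.0
    dispersion: float = 0.2
    pair_sd: float = 0.3
    signal_regions: tuple[int, ...] = ()
    log_fold_change: float = 0.7
    signal_directions: Mapping[int, int] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.pair_sd < 0:
            raise ValueError("pair_sd must be non-negative")
        if self.region_profile_sd < 0:
            raise ValueError("region_profile_sd must be non-negative")
        if self.n_pairs < 1 or self.n_regions < 1:
            raise ValueError("n_pairs and n_regions must be positive")
        for i in self.signal_regions:
            if not 0 <= i < self.n_regions:
                raise ValueError(f"signal region index {i} outside 0..{self.n_regions - 1}")
        for i, d in self.signal_directions.items():
            if i not in set(self.signal_regions):
                raise ValueError(f"direction given for non-signal region {i}")
            if d not in (-1, 1):
                raise ValueError("signal directions must be +1 (R high) or -1 (LH high)")


def _nb_draws(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mu))


def gen_region_counts(
    params: CountSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a paired animals x regions count matrix with known truth.

    Returns ``(counts, design, truth)``: counts indexed by animal_id with
    one column per region acronym; a design frame (animal_id, pair_id,
    group); and a truth frame (region, is_signal, direction,
    log_fold_change) where direction +1 means the resilient group's
    population mean is exp(log_fold_change)-fold the helpless one.
    """
    rng = np.random.default_rng(params.seed)
    regions = [f"R{j + 1:03d}" for j in range(params.n_regions)]
    region_base = np.log(params.baseline_mean) + rng.normal(
        0.0, params.region_profile_sd, params.n_regions
    )
    lfc = np.zeros(params.n_regions)
    for j in params.signal_regions:
        lfc[j] = params.log_fold_change * params.signal_directions.get(j, 1)

    animal_ids, pair_ids, groups, rows = [], [], [], []
    for i in range(params.n_pairs):
        offset = rng.normal(0.0, params.pair_sd)
        for group in (HELPLESS, RESILIENT):
            log_mu = region_base + offset
            if group == RESILIENT:
                log_mu = log_mu + lfc
            mu = np.exp(log_mu)
            rows.append(_nb_draws(rng, mu, params.dispersion))
            animal_ids.append(f"P{i + 1:02d}-{'LH' if group == HELPLESS else 'R'}")
            pair_ids.append(f"P{i + 1:02d}")
            groups.append(group)
    counts = pd.DataFrame(np.asarray(rows, dtype=np.int64), columns=regions)
    counts.index = pd.Index(animal_ids, name="animal_id")
    design = pd.DataFrame({"animal_id": animal_ids, "pair_id": pair_ids, "group": groups})
    truth = pd.DataFrame(
        {
            "region": regions,
            "is_signal": lfc != 0.0,
            "direction": np.sign(lfc).astype(int),
            "log_fold_change": lfc,
        }
    )
    return counts, design, truth


@dataclass(frozen=True)
class LabelAtlas:
    """Integer label volume with voxel spacing in micrometers.

    ``volume[i, j, k]`` is the region label of the voxel spanning
    ``[i*s_x, (i+1)*s_x) x ...``; 0 is background.
    """

    volume: np.ndarray
    spacing: tuple[float, float, float]
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.volume.ndim != 3 or not np.issubdtype(self.volume.dtype, np.integer):
            raise ValueError("atlas volume must be a 3-D integer array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.volume.shape, self.spacing))

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.volume)
        return lab[lab != 0]


@dataclass(frozen=True)
class CloudSimParams:
    """Toy-brain layout: axis-aligned boxes (in voxels) inside a label volume.

    ``region_layout`` maps a positive label to ((i0, i1), (j0, j1), (k0, k1))
    half-open voxel index ranges; boxes must be disjoint and inside
    ``volume_shape``.  Each animal gets Poisson(cells_per_region * scaling)
    cells placed uniformly in each region's box.
    """

    volume_shape: tuple[int, int, int] = (40, 40, 20)
    voxel_size: tuple[float, float, float] = (50.0, 50.0, 50.0)
    region_layout: Mapping[int, tuple] = field(default_factory=dict)
    cells_per_region: float = 200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cells_per_region < 0:
            raise ValueError("cells_per_region must be non-negative")
        occupied = np.zeros(self.volume_shape, dtype=bool)
        for label, box in self.region_layout.items():
            if int(label) <= 0:
                raise ValueError("labels must be positive integers (0 = background)")
            (i0, i1), (j0, j1), (k0, k1) = box
            if not (0 <= i0 < i1 <= self.volume_shape[0]
                    and 0 <= j0 < j1 <= self.volume_shape[1]
                    and 0 <= k0 < k1 <= self.volume_shape[2]):
                raise ValueError(f"region {label} box {box} outside the volume")
            sl = occupied[i0:i1, j0:j1, k0:k1]
            if sl.any():
                raise ValueError(f"region {label} box overlaps another region")
            occupied[i0:i1, j0:j1, k0:k1] = True


def build_atlas(params: CloudSimParams) -> LabelAtlas:
    """Rasterize the box layout into a LabelAtlas."""
    vol = np.zeros(params.volume_shape, dtype=np.int32)
    for label, ((i0, i1), (j0, j1), (k0, k1)) in params.region_layout.items():
        vol[i0:i1, j0:j1, k0:k1] = int(label)
    names = {int(lb): f"A{int(lb):03d}" for lb in params.region_layout}
    return LabelAtlas(volume=vol, spacing=params.voxel_size, names=names)


def gen_cell_cloud(
    params: CloudSimParams,
    per_region_intensity: Mapping[int, float] | None = None,
) -> tuple[pd.DataFrame, LabelAtlas]:
    """Generate one animal's cell centroids inside the toy atlas.

    ``per_region_intensity`` scales the expected count per region (default
    1).  Returns a centroid table (x_um, y_um, z_um, region) and the atlas.
    """
    rng = np.random.default_rng(params.seed)
    atlas = build_atlas(params)
    scale = per_region_intensity or {}
    pts = []
    for label, box in params.region_layout.items():
        lam = params.cells_per_region * float(scale.get(label, 1.0))
        if lam < 0:
            raise ValueError("per-region intensity must be non-negative")
        n = rng.poisson(lam)
        (i0, i1), (j0, j1), (k0, k1) = box
        lo = np.array([i0, j0, k0]) * np.array(params.voxel_size)
        hi = np.array([i1, j1, k1]) * np.array(params.voxel_size)
        xyz = rng.uniform(lo, hi, size=(n, 3))
        for p in xyz:
            pts.append((p[0], p[1], p[2], int(label)))
    cloud = pd.DataFrame(pts, columns=["x_um", "y_um", "z_um", "region"])
    if cloud.empty:
        cloud = pd.DataFrame(columns=["x_um", "y_um", "z_um", "region"])
    return cloud, atlas


def default_brain_layout(params_shape: tuple[int, int, int] = (40, 40, 20)) -> dict[int, tuple]:
    """A small 4-region box parcellation used by examples and tests."""
    nx, ny, nz = params_shape
    return {
        1: ((2, nx // 2 - 2), (2, ny // 2 - 2), (2, nz - 2)),
        2: ((nx // 2 + 2, nx - 2), (2, ny // 2 - 2), (2, nz - 2)),
        3: ((2, nx // 2 - 2), (ny // 2 + 2, ny - 2), (2, nz - 2)),
        4: ((nx // 2 + 2, nx - 2), (ny // 2 + 2, ny - 2), (2, nz - 2)),
    }
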