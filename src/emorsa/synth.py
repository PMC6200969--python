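"""Synthetic fMRI-like cohorts with planted "abstract emotion" structure.

The generative model makes the abstract-representation hypothesis a single
tunable parameter.  Inside each planted spherical region, the noiseless
beta of condition (emotion e, stimulus type t) at voxel v is

    amplitude * (share * s_e[v] + (1 - share) * u_{e,t}[v])

where ``s_e`` is an emotion-shared standard-normal voxel field (one per
emotion) and ``u_{e,t}`` a condition-private field, both drawn once per
subject.  ``share`` in [0, 1] interpolates between fully condition-private
patterns (share 0: no cross-type generalization, the null for the
hypothesis) and a fully shared emotion pattern (share 1).  Per-run betas
add white Gaussian noise with sd ``noise_sd``; outside planted regions
betas are pure noise.

Randomness discipline: all draws descend from ``numpy.random.SeedSequence``
keyed on (spec.seed, stream), with one child per subject, and within a
subject the draw order is fixed: shared fields (3, V), private fields
(3, 3, V), then run noise (n_runs, 9, V).  Identical specs therefore
reproduce bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .conditions import CONDITIONS, EMOTIONS, N_CONDITIONS, STIM_TYPES
from .glm import BetaPatterns, build_design

__all__ = [
    "PlantedRegion",
    "SyntheticSpec",
    "SubjectDataset",
    "GroundTruth",
    "generate_betas",
    "generate_timeseries",
    "generate_null",
    "sphere_mask",
]

# seed-stream tags, so the three generators draw from disjoint streams
_STREAM_BETAS = 0
_STREAM_TIMESERIES = 1
_STREAM_NULL = 2


@dataclass(frozen=True)
class PlantedRegion:
    """A spherical region carrying the abstract-emotion signal."""

    center: tuple[int, int, int]
    radius_vox: float
    effect_amplitude: float = 1.0
    share_fraction: float = 0.8


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort; identical specs (including
    seed) reproduce byte-identical data."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 3.0
    n_subjects: int = 20
    n_runs: int = 3
    emotions: tuple[str, ...] = EMOTIONS
    stim_types: tuple[str, ...] = STIM_TYPES
    planted_regions: tuple[PlantedRegion, ...] = ()
    noise_sd: float = 1.0
    blocks_per_condition_per_run: int = 2
    tr_s: float = 2.0
    block_duration_s: float = 20.0
    fixation_duration_s: float = 10.0
    scan_noise_sd: float = 1.0
    nuisance_sd: float = 0.5
    n_motion_regressors: int = 6
    n_tissue_regressors: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.emotions) != EMOTIONS or tuple(self.stim_types) != STIM_TYPES:
            raise ValueError(
                "condition labels are fixed to the canonical 3 emotions x 3 "
                "stimulus types design"
            )
        if self.noise_sd < 0 or self.scan_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        for k, region in enumerate(self.planted_regions):
            if not 0.0 <= region.share_fraction <= 1.0:
                raise ValueError(
                    f"planted region {k} (center {region.center}): "
                    f"share_fraction {region.share_fraction} outside [0, 1]"
                )
            for axis in range(3):
                lo = region.center[axis] - region.radius_vox
                hi = region.center[axis] + region.radius_vox
                if lo < 0 or hi > self.grid_shape[axis] - 1:
                    raise ValueError(
                        f"planted region {k} (center {region.center}, radius "
                        f"{region.radius_vox}) extends outside the grid "
                        f"{self.grid_shape}"
                    )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        return aff


@dataclass
class SubjectDataset:
    """One subject's data: betas and/or per-run time series with tables."""

    subject_id: str
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    mask: np.ndarray  # boolean volume
    beta_patterns: BetaPatterns | None = None
    timeseries: list[np.ndarray] | None = None  # per run, (T, V)
    events: list[pd.DataFrame] | None = None
    nuisance: list[pd.DataFrame] | None = None

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for recovery tests.

    ``true_condition_patterns`` holds the noiseless betas per subject
    (n_subjects, 9, V); the shared/private fields are subject-specific.
    """

    planted_mask: np.ndarray  # boolean volume
    true_condition_patterns: np.ndarray


def sphere_mask(grid_shape: tuple[int, int, int], center, radius_vox: float) -> np.ndarray:
    """Boolean volume of voxels within ``radius_vox`` of ``center``."""
    grids = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius_vox**2


def _subject_rngs(spec: SyntheticSpec, stream: int) -> list[np.random.Generator]:
    root = np.random.SeedSequence([spec.seed, stream])
    return [np.random.default_rng(child) for child in root.spawn(spec.n_subjects)]


def _true_patterns(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw one subject's noiseless condition patterns and the run noise."""
    v = spec.n_voxels
    shared = rng.standard_normal((len(EMOTIONS), v))
    private = rng.standard_normal((len(EMOTIONS), len(STIM_TYPES), v))
    noise = rng.standard_normal((spec.n_runs, N_CONDITIONS, v)) * spec.noise_sd
    true = np.zeros((N_CONDITIONS, v))
    for region in spec.planted_regions:
        idx = sphere_mask(spec.grid_shape, region.center, region.radius_vox).reshape(-1)
        lam, amp = region.share_fraction, region.effect_amplitude
        for e in range(len(EMOTIONS)):
            for t in range(len(STIM_TYPES)):
                cond = e * len(STIM_TYPES) + t
                true[cond, idx] += amp * (
                    lam * shared[e, idx] + (1.0 - lam) * private[e, t, idx]
                )
    return true, noise


def generate_betas(
    spec: SyntheticSpec,
) -> tuple[list[SubjectDataset], GroundTruth]:
    """Generate per-run, per-condition beta patterns for a cohort."""
    planted = np.zeros(spec.grid_shape, dtype=bool)
    for region in spec.planted_regions:
        planted |= sphere_mask(spec.grid_shape, region.center, region.radius_vox)
    mask = np.ones(spec.grid_shape, dtype=bool)
    datasets: list[SubjectDataset] = []
    all_true = np.empty((spec.n_subjects, N_CONDITIONS, spec.n_voxels))
    for s, rng in enumerate(_subject_rngs(spec, _STREAM_BETAS)):
        true, noise = _true_patterns(spec, rng)
        all_true[s] = true
        bp = BetaPatterns(
            subject_id=f"sub-{s + 1:02d}",
            betas=true[None, :, :] + noise,
            grid_shape=spec.grid_shape,
            voxel_size_mm=spec.voxel_size_mm,
        )
        datasets.append(
            SubjectDataset(
                subject_id=bp.subject_id,
                grid_shape=spec.grid_shape,
                voxel_size_mm=spec.voxel_size_mm,
                mask=mask.copy(),
                beta_patterns=bp,
            )
        )
    return datasets, GroundTruth(planted_mask=planted, true_condition_patterns=all_true)


def _run_events(spec: SyntheticSpec, rng: np.random.Generator) -> pd.DataFrame:
    if spec.blocks_per_condition_per_run < 1:
        raise ValueError(
            "run length implies fewer than 1 block per condition "
            f"(blocks_per_condition_per_run={spec.blocks_per_condition_per_run})"
        )
    order = np.repeat(np.arange(N_CONDITIONS), spec.blocks_per_condition_per_run)
    rng.shuffle(order)
    onsets, conditions = [], []
    t = spec.fixation_duration_s
    for cond in order:
        onsets.append(t)
        conditions.append(CONDITIONS[cond])
        t += spec.block_duration_s + spec.fixation_duration_s
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": spec.block_duration_s,
            "condition": conditions,
        }
    )


def _run_duration_s(spec: SyntheticSpec) -> float:
    n_blocks = N_CONDITIONS * spec.blocks_per_condition_per_run
    return spec.fixation_duration_s + n_blocks * (
        spec.block_duration_s + spec.fixation_duration_s
    )


def _nuisance_table(
    spec: SyntheticSpec, n_volumes: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {}
    # motion-like slow drifts: random walks; tissue-like signals: white
    for i in range(spec.n_motion_regressors):
        cols[f"motion_{i + 1}"] = np.cumsum(rng.standard_normal(n_volumes)) * 0.05
    for i in range(spec.n_tissue_regressors):
        cols[f"tissue_{i + 1}"] = rng.standard_normal(n_volumes)
    return pd.DataFrame(cols)


def generate_timeseries(spec: SyntheticSpec) -> list[SubjectDataset]:
    """Generate block-design time series (design x betas + nuisance + noise).

    The betas underlying the series are exactly those of
    :func:`generate_betas` with the same spec, so GLM estimates can be
    compared against them.
    """
    if min(spec.tr_s, spec.block_duration_s, spec.fixation_duration_s) <= 0:
        raise ValueError("timing fields must be positive")
    datasets, _ = generate_betas(spec)
    n_volumes = math.ceil(_run_duration_s(spec) / spec.tr_s)
    for ds, rng in zip(datasets, _subject_rngs(spec, _STREAM_TIMESERIES)):
        bp = ds.beta_patterns
        assert bp is not None
        series, events_tables, nuisance_tables = [], [], []
        for run in range(spec.n_runs):
            events = _run_events(spec, rng)
            nuisance = _nuisance_table(spec, n_volumes, rng)
            design = build_design(events, None, n_volumes, spec.tr_s)
            x = design.condition_columns()
            y = x @ bp.betas[run]
            if spec.nuisance_sd > 0:
                weights = (
                    rng.standard_normal((nuisance.shape[1], spec.n_voxels))
                    * spec.nuisance_sd
                )
                y = y + nuisance.to_numpy() @ weights
            if spec.scan_noise_sd > 0:
                y = y + rng.standard_normal(y.shape) * spec.scan_noise_sd
            series.append(y)
            events_tables.append(events)
            nuisance_tables.append(nuisance)
        ds.timeseries = series
        ds.events = events_tables
        ds.nuisance = nuisance_tables
    return datasets


def generate_null(spec: SyntheticSpec) -> list[SubjectDataset]:
    """Pure-noise cohort: i.i.d. Gaussian betas, labels carry no information."""
    null_spec = replace(spec, planted_regions=())
    mask = np.ones(null_spec.grid_shape, dtype=bool)
    datasets = []
    for s, rng in enumerate(_subject_rngs(null_spec, _STREAM_NULL)):
        betas = (
            rng.standard_normal((null_spec.n_runs, N_CONDITIONS, null_spec.n_voxels))
            * null_spec.noise_sd
        )
        bp = BetaPatterns(
            subject_id=f"sub-{s + 1:02d}",
            betas=betas,
            grid_shape=null_spec.grid_shape,
            voxel_size_mm=null_spec.voxel_size_mm,
        )
        datasets.append(
            SubjectDataset(
                subject_id=bp.subject_id,
                grid_shape=null_spec.grid_shape,
                voxel_size_mm=null_spec.voxel_size_mm,
                mask=mask.copy(),
                beta_patterns=bp,
            )
        )
    return datasets
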