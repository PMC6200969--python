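"""Whole-brain spherical searchlight RSA and group-level cluster inference.

For every in-mask voxel, the condition patterns over the surrounding
9-mm sphere are turned into a neural RDM (correlation distance) and
compared to the abstract-emotion model RDM with Kendall tau-a; the tau is
assigned to the sphere's center voxel, yielding a per-subject tau map
(r-map).  Group inference runs a one-sided (positive) Wilcoxon signed-rank
test across subjects at every voxel, thresholds at p < alpha, and keeps
connected suprathreshold components of at least ``min_cluster_size``
voxels.  No correction beyond the cluster-extent rule is applied
(uncorrected by design).

Implementation note: the per-sphere Pearson correlations are computed from
moving sums (sums, squared sums and cross-products convolved with the
spherical kernel), which makes the whole-brain map a few dozen small 3-D
convolutions instead of one loop per voxel.  With the binary model RDM,
tau-a reduces to counting, over the 9 within-emotion x 27 between-emotion
dissimilarity pairs, how often the between entry exceeds the within entry;
that count equals the generic tau-a over the 36 upper-triangle entries and
is computed vectorized over all sphere centers.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .conditions import N_CONDITIONS
from .rdm import model_rdm
from .stats import wilcoxon_signrank_many

__all__ = [
    "SearchlightConfig",
    "TauMap",
    "ClusterTable",
    "sphere_offsets",
    "run_searchlight",
    "group_inference",
]

logger = logging.getLogger(__name__)

_CONNECTIVITY_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class SearchlightConfig:
    """Searchlight and group-inference parameters."""

    radius_mm: float = 9.0
    voxel_size_mm: float = 3.0
    min_voxels_per_sphere: int = 10
    alpha: float = 0.01
    min_cluster_size: int = 30
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("radius_mm and voxel_size_mm must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.connectivity not in _CONNECTIVITY_STRUCTURES:
            raise ValueError("connectivity must be one of 6, 18, 26")


@dataclass
class TauMap:
    """Per-subject volume of model-to-neural tau values; NaN outside mask."""

    values: np.ndarray  # 3-D
    affine: np.ndarray
    n_undersized: int = 0


@dataclass
class ClusterTable:
    """Suprathreshold clusters: a table plus the integer label volume."""

    table: pd.DataFrame  # cluster_id, size, peak_ijk, peak_xyz, peak_intensity, voxels
    label_volume: np.ndarray

    def __len__(self) -> int:
        return len(self.table)


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets within ``radius_mm`` of the center (included)."""
    if radius_mm < 0 or voxel_size_mm <= 0:
        raise ValueError("radius must be >= 0 and voxel size > 0")
    r_vox = radius_mm / voxel_size_mm
    reach = int(np.floor(r_vox))
    rng = np.arange(-reach, reach + 1)
    dx, dy, dz = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r_vox**2 + 1e-12
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


def _sphere_kernel(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    offs = sphere_offsets(radius_mm, voxel_size_mm)
    reach = int(np.abs(offs).max()) if len(offs) else 0
    kernel = np.zeros((2 * reach + 1,) * 3)
    kernel[offs[:, 0] + reach, offs[:, 1] + reach, offs[:, 2] + reach] = 1.0
    return kernel


def _model_pair_split() -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle indices of within- vs between-emotion pairs."""
    tri = model_rdm().upper_triangle()
    return np.flatnonzero(tri == 0.0), np.flatnonzero(tri == 1.0)


def _tau_from_dissimilarities(d: np.ndarray) -> np.ndarray:
    """tau-a of each row of (m, 36) dissimilarities against the binary model."""
    within_idx, between_idx = _model_pair_split()
    n = d.shape[1]
    denom = n * (n - 1) / 2
    diff = d[:, between_idx][:, None, :] - d[:, within_idx][:, :, None]
    return np.sign(diff).sum(axis=(1, 2)) / denom


def run_searchlight(
    patterns: np.ndarray,
    mask: np.ndarray,
    config: SearchlightConfig,
    grid_shape: tuple[int, int, int] | None = None,
) -> TauMap:
    """Whole-brain tau map for one subject.

    ``patterns`` is the run-averaged condition x voxel array (9, V);
    ``mask`` a boolean volume.  Centers whose in-mask sphere holds fewer
    than ``config.min_voxels_per_sphere`` voxels (or a constant pattern)
    get NaN; their count is logged, not raised.
    """
    mask = np.asarray(mask, dtype=bool)
    if grid_shape is None:
        grid_shape = mask.shape
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape != (N_CONDITIONS, int(np.prod(grid_shape))):
        raise ValueError(
            f"patterns must be ({N_CONDITIONS}, n_voxels) matching the grid"
        )
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    tau_vol = np.full(grid_shape, np.nan)
    if not mask.any():
        return TauMap(values=tau_vol, affine=affine, n_undersized=0)

    kernel = _sphere_kernel(config.radius_mm, config.voxel_size_mm)
    vols = patterns.reshape(N_CONDITIONS, *grid_shape) * mask

    def sphere_sum(v: np.ndarray) -> np.ndarray:
        return ndimage.correlate(v, kernel, mode="constant", cval=0.0)

    counts = sphere_sum(mask.astype(float))
    sums = np.stack([sphere_sum(v) for v in vols])
    sqsums = np.stack([sphere_sum(v * v) for v in vols])

    min_k = max(config.min_voxels_per_sphere, 3)
    valid = mask & (np.rint(counts).astype(int) >= min_k)
    n_undersized = int((mask & ~valid).sum())
    flat_idx = np.flatnonzero(valid.reshape(-1))
    if flat_idx.size == 0:
        logger.info("searchlight: all %d centers undersized", n_undersized)
        return TauMap(values=tau_vol, affine=affine, n_undersized=n_undersized)

    k = counts.reshape(-1)[flat_idx]
    s = sums.reshape(N_CONDITIONS, -1)[:, flat_idx]
    ss = sqsums.reshape(N_CONDITIONS, -1)[:, flat_idx]
    var = k * ss - s**2  # k^2 * per-sphere variance, >= 0 up to rounding

    iu, ju = np.triu_indices(N_CONDITIONS, k=1)
    d = np.empty((flat_idx.size, iu.size))
    degenerate = np.zeros(flat_idx.size, dtype=bool)
    for p, (i, j) in enumerate(zip(iu, ju)):
        cross = sphere_sum(vols[i] * vols[j]).reshape(-1)[flat_idx]
        cov = k * cross - s[i] * s[j]
        denom = var[i] * var[j]
        bad = denom <= 0
        degenerate |= bad
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip(cov / np.sqrt(np.where(bad, 1.0, denom)), -1.0, 1.0)
        d[:, p] = 1.0 - r

    tau = _tau_from_dissimilarities(d)
    tau[degenerate] = np.nan
    tau_vol.reshape(-1)[flat_idx] = tau
    if n_undersized:
        logger.info(
            "searchlight: %d centers skipped (sphere < %d in-mask voxels)",
            n_undersized,
            min_k,
        )
    return TauMap(values=tau_vol, affine=affine, n_undersized=n_undersized)


def group_inference(
    taumaps: list[TauMap],
    config: SearchlightConfig,
) -> tuple[np.ndarray, ClusterTable]:
    """Voxel-wise one-sided Wilcoxon signed-rank group test plus clustering.

    Returns the p-map volume (NaN where any subject lacks a tau) and the
    table of connected suprathreshold clusters of at least
    ``config.min_cluster_size`` voxels.  Cluster peaks are the voxels with
    the largest across-subject summed tau; peak coordinates are reported in
    world (mm) space through the affine.
    """
    if len(taumaps) < 6:
        raise ValueError("group inference needs at least 6 subjects")
    shapes = {tm.values.shape for tm in taumaps}
    if len(shapes) != 1:
        raise ValueError(f"subject tau maps differ in shape: {sorted(shapes)}")
    shape = taumaps[0].values.shape
    affine = taumaps[0].affine
    stack = np.stack([tm.values.reshape(-1) for tm in taumaps])  # (n, V)
    valid = np.isfinite(stack).all(axis=0)
    p_flat = np.full(stack.shape[1], np.nan)
    if valid.any():
        p_flat[valid] = wilcoxon_signrank_many(
            stack[:, valid], mu0=0.0, tail="one_sided_greater"
        )
    p_vol = p_flat.reshape(shape)

    supra = np.zeros(shape, dtype=bool)
    supra.reshape(-1)[valid] = p_flat[valid] < config.alpha
    structure = _CONNECTIVITY_STRUCTURES[config.connectivity]
    labels, n_raw = ndimage.label(supra, structure=structure)

    summed = np.where(valid, stack.sum(axis=0), -np.inf).reshape(shape)
    rows = []
    keep_labels = np.zeros_like(labels)
    next_id = 0
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n_raw + 1))
    order = np.argsort(sizes)[::-1]
    for raw in order:
        size = int(sizes[raw])
        if size < config.min_cluster_size:
            continue
        next_id += 1
        members = np.argwhere(labels == raw + 1)
        member_stats = summed[tuple(members.T)]
        peak = members[np.argmax(member_stats)]
        peak_xyz = (affine @ np.append(peak, 1.0))[:3]
        keep_labels[tuple(members.T)] = next_id
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_ijk": tuple(int(c) for c in peak),
                "peak_x": float(peak_xyz[0]),
                "peak_y": float(peak_xyz[1]),
                "peak_z": float(peak_xyz[2]),
                "peak_intensity": float(member_stats.max()),
                "voxels": members,
            }
        )
    columns = [
        "cluster_id",
        "size",
        "peak_ijk",
        "peak_x",
        "peak_y",
        "peak_z",
        "peak_intensity",
        "voxels",
    ]
    table = pd.DataFrame(rows, columns=columns)
    return p_vol, ClusterTable(table=table, label_volume=keep_labels)
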