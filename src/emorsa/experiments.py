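"""Canned simulation studies exercising the full pipeline.

These protocols define the package's reference experiments: chance-level
calibration of the cross-modal classifier on structureless cohorts,
null calibration of the searchlight group inference, and recovery of a
planted abstract-emotion region by the complete
searchlight -> group inference -> MVPA-confirmation chain.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .mvpa import (
    N_SUBSAMPLE_REPS,
    confirmed_clusters,
    evaluate_clusters,
    extract_cluster_patterns,
    pair_accuracy,
)
from .searchlight import SearchlightConfig, group_inference, run_searchlight
from .synth import PlantedRegion, SyntheticSpec, generate_betas, generate_null, sphere_mask

__all__ = [
    "null_crossmodal_accuracies",
    "null_searchlight_calibration",
    "planted_recovery",
]

#: conditions of the planted-recovery study: cohort of 20 subjects on a
#: 24^3 grid of 3-mm voxels, one planted sphere of radius 4 voxels with
#: unit amplitude, 0.8 pattern sharing, unit noise
RECOVERY_GRID = (24, 24, 24)
RECOVERY_CENTER = (8, 8, 8)
RECOVERY_CONTROL_CENTER = (16, 16, 16)
RECOVERY_RADIUS_VOX = 4.0


def null_crossmodal_accuracies(
    scheme: str,
    n_subjects: int = 200,
    n_voxels: int = 40,
    type_pair: tuple[str, str] = ("face", "body"),
    seed: int = 0,
    n_subsample_reps: int = N_SUBSAMPLE_REPS,
) -> np.ndarray:
    """Per-subject fold-averaged accuracies on a structureless cohort.

    Each subject has i.i.d. Gaussian betas (3 runs x 9 conditions x
    ``n_voxels``) in a fixed cluster; labels carry no information, so the
    expectation is the chance level of ``scheme``.
    """
    spec = SyntheticSpec(
        grid_shape=(n_voxels, 1, 1), n_subjects=n_subjects, seed=seed
    )
    datasets = generate_null(spec)
    voxels = np.arange(n_voxels)
    root = np.random.SeedSequence([seed, 101])
    accs = []
    for ds, child in zip(datasets, root.spawn(n_subjects)):
        pats = extract_cluster_patterns(ds.beta_patterns, voxels)
        accs.append(
            pair_accuracy(
                pats, scheme, type_pair, np.random.default_rng(child),
                n_subsample_reps,
            )
        )
    return np.array(accs)


def _cohort_taumaps(spec: SyntheticSpec, config: SearchlightConfig):
    datasets, truth = generate_betas(spec)
    mask = datasets[0].mask
    taumaps = [
        run_searchlight(ds.beta_patterns.run_mean(), mask, config)
        for ds in datasets
    ]
    return datasets, truth, taumaps


def null_searchlight_calibration(
    seeds,
    grid_shape: tuple[int, int, int] = RECOVERY_GRID,
    n_subjects: int = 20,
    config: SearchlightConfig | None = None,
) -> pd.DataFrame:
    """Voxelwise and cluster-level false-positive behavior on null cohorts.

    One row per seed: the fraction of in-mask voxels with group
    p < config.alpha and the number of surviving clusters.
    """
    config = config or SearchlightConfig()
    rows = []
    for seed in seeds:
        spec = SyntheticSpec(grid_shape=grid_shape, n_subjects=n_subjects, seed=seed)
        datasets = generate_null(spec)
        mask = datasets[0].mask
        taumaps = [
            run_searchlight(ds.beta_patterns.run_mean(), mask, config)
            for ds in datasets
        ]
        p_vol, clusters = group_inference(taumaps, config)
        valid = np.isfinite(p_vol)
        rows.append(
            {
                "seed": seed,
                "fraction_below_alpha": float((p_vol[valid] < config.alpha).mean()),
                "n_voxels_tested": int(valid.sum()),
                "n_clusters": len(clusters),
            }
        )
    return pd.DataFrame(rows)


def planted_recovery(
    seed: int,
    effect_amplitude: float = 1.0,
    share_fraction: float = 0.8,
    noise_sd: float = 1.0,
    n_subjects: int = 20,
    config: SearchlightConfig | None = None,
    n_subsample_reps: int = N_SUBSAMPLE_REPS,
) -> dict:
    """Full-pipeline recovery of one planted region, with a matched control.

    Runs searchlight + group inference on a planted cohort, then the MVPA
    confirmation test on every recovered cluster plus a matched control
    sphere placed far from the planted region.  Returns per-seed outcome
    flags used by the calibration studies.
    """
    config = config or SearchlightConfig()
    spec = SyntheticSpec(
        grid_shape=RECOVERY_GRID,
        n_subjects=n_subjects,
        planted_regions=(
            PlantedRegion(
                RECOVERY_CENTER, RECOVERY_RADIUS_VOX, effect_amplitude, share_fraction
            ),
        ),
        noise_sd=noise_sd,
        seed=seed,
    )
    datasets, truth, taumaps = _cohort_taumaps(spec, config)
    _, clusters = group_inference(taumaps, config)

    planted = truth.planted_mask
    control_voxels = np.argwhere(
        sphere_mask(spec.grid_shape, RECOVERY_CONTROL_CENTER, RECOVERY_RADIUS_VOX)
    )
    cluster_voxels = {
        int(row["cluster_id"]): row["voxels"] for _, row in clusters.table.iterrows()
    }
    overlaps = {
        cid: bool(planted[tuple(vox.T)].any()) for cid, vox in cluster_voxels.items()
    }
    peaks_inside = [
        bool(planted[row["peak_ijk"]]) for _, row in clusters.table.iterrows()
    ]
    control_id = max(cluster_voxels, default=0) + 1
    cohort = [ds.beta_patterns for ds in datasets]
    results = evaluate_clusters(
        cohort,
        {**cluster_voxels, control_id: control_voxels},
        seed=seed,
        n_subsample_reps=n_subsample_reps,
    )
    confirmed = confirmed_clusters(results)
    return {
        "seed": seed,
        "n_clusters": len(clusters),
        "any_peak_in_planted": any(peaks_inside),
        "clusters_wholly_outside": sum(not v for v in overlaps.values()),
        "confirmed_overlapping": any(
            cid in confirmed and overlaps[cid] for cid in cluster_voxels
        ),
        "confirmed_outside": any(
            cid in confirmed and not overlaps[cid] for cid in cluster_voxels
        ),
        "control_confirmed": control_id in confirmed,
        "accuracy_table": results,
    }
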