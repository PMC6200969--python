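"""Block-design GLM: design-matrix construction and per-run OLS beta estimation.

One GLM is fitted per run, yielding one beta pattern per condition per run
(3 exemplars per condition over the 3 runs).  The MVPA stage consumes the
per-run patterns; the RSA stage averages them across runs to a single
pattern per condition.  Condition regressors are boxcars convolved with the
canonical double-gamma HRF; nuisance regressors and their first temporal
derivatives are appended, then an intercept.  Response periods and fixation
are left unmodeled (implicit baseline).  No high-pass filter or
prewhitening is applied: the synthetic noise model is white.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .conditions import CONDITIONS

__all__ = [
    "DesignMatrix",
    "BetaPatterns",
    "canonical_hrf",
    "build_design",
    "fit_glm",
]

# Canonical double-gamma HRF parameters (response peak, undershoot peak,
# response/undershoot amplitude ratio), in seconds.
HRF_PEAK_S = 6.0
HRF_UNDERSHOOT_S = 16.0
HRF_RATIO = 6.0


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    t = np.asarray(t, dtype=float)
    h = sps.gamma.pdf(t, HRF_PEAK_S) - sps.gamma.pdf(t, HRF_UNDERSHOOT_S) / HRF_RATIO
    peak = sps.gamma.pdf(HRF_PEAK_S - 1.0, HRF_PEAK_S)  # mode of the response gamma
    return h / peak


@dataclass
class DesignMatrix:
    """Time x regressor matrix with named columns.

    Condition columns come first (canonical emotion-major order, only the
    conditions present in the events table), then nuisance columns with
    their temporal derivatives, then the intercept.
    """

    matrix: np.ndarray
    names: list[str]
    condition_names: list[str]
    tr: float

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def condition_columns(self) -> np.ndarray:
        idx = [self.names.index(c) for c in self.condition_names]
        return self.matrix[:, idx]


@dataclass
class BetaPatterns:
    """Per-subject GLM estimates: run x condition x voxel array."""

    subject_id: str
    betas: np.ndarray  # (n_runs, n_conditions, n_voxels), flat voxel axis
    grid_shape: tuple[int, int, int]
    voxel_size_mm: float = 3.0
    mask: np.ndarray | None = None  # flat boolean, None means all voxels
    condition_names: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.ndim != 3:
            raise ValueError("betas must be (n_runs, n_conditions, n_voxels)")
        if self.betas.shape[2] != int(np.prod(self.grid_shape)):
            raise ValueError("voxel axis does not match grid_shape")

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    def run_mean(self) -> np.ndarray:
        """Run-averaged condition x voxel patterns (RSA input)."""
        return self.betas.mean(axis=0)

    def mask_volume(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.grid_shape, dtype=bool)
        return self.mask.reshape(self.grid_shape)


def build_design(
    events: pd.DataFrame,
    nuisance: pd.DataFrame | None,
    n_volumes: int,
    tr: float,
    oversample: int = 16,
) -> DesignMatrix:
    """Build a GLM design from an events table and a nuisance table.

    ``events`` needs columns onset, duration (seconds) and condition;
    conditions must be among the 9 canonical labels.  Each nuisance column
    is included together with its first temporal difference.
    """
    if tr <= 0 or n_volumes <= 0:
        raise ValueError("n_volumes and tr must be positive")
    required = {"onset", "duration", "condition"}
    if not required.issubset(events.columns):
        raise ValueError(f"events table needs columns {sorted(required)}")
    unknown = set(events["condition"]) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown conditions in events table: {sorted(unknown)}")
    run_end = n_volumes * tr
    for _, ev in events.iterrows():
        if ev["onset"] < 0 or ev["onset"] >= run_end:
            raise ValueError(
                f"event (condition={ev['condition']!r}, onset={ev['onset']}) "
                f"lies outside the run of {run_end} s"
            )

    dt = tr / oversample
    n_hi = n_volumes * oversample
    hrf = canonical_hrf(np.arange(0, 32.0, dt))
    present = [c for c in CONDITIONS if c in set(events["condition"])]
    cols: list[np.ndarray] = []
    for cond in present:
        boxcar = np.zeros(n_hi)
        for _, ev in events[events["condition"] == cond].iterrows():
            i0 = int(round(ev["onset"] / dt))
            i1 = int(round((ev["onset"] + ev["duration"]) / dt))
            boxcar[i0 : min(i1, n_hi)] = 1.0
        reg = np.convolve(boxcar, hrf)[:n_hi] * dt
        cols.append(reg[::oversample])
    names = list(present)

    if nuisance is not None and len(nuisance.columns) > 0:
        if len(nuisance) != n_volumes:
            raise ValueError("nuisance table length must equal n_volumes")
        for col in nuisance.columns:
            v = nuisance[col].to_numpy(dtype=float)
            cols.append(v)
            names.append(str(col))
        for col in nuisance.columns:
            v = nuisance[col].to_numpy(dtype=float)
            cols.append(np.diff(v, prepend=v[0]))
            names.append(f"{col}_derivative")

    cols.append(np.ones(n_volumes))
    names.append("intercept")
    matrix = np.column_stack(cols)
    return DesignMatrix(matrix=matrix, names=names, condition_names=present, tr=tr)


def _collinear_columns(matrix: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(matrix)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag <= tol)]


def fit_glm(
    timeseries: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-voxel OLS; returns the condition betas (n_conditions, n_voxels).

    ``timeseries`` is (n_volumes, n_voxels); ``mask`` a flat boolean over
    voxels (out-of-mask betas are NaN).  Nuisance and intercept betas are
    estimated and discarded.
    """
    y = np.asarray(timeseries, dtype=float)
    if y.ndim != 2:
        raise ValueError("timeseries must be (n_volumes, n_voxels)")
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"time dimension mismatch: {y.shape[0]} volumes vs {x.shape[0]} design rows"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, design.names)
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    n_vox = y.shape[1]
    if mask is None:
        mask = np.ones(n_vox, dtype=bool)
    mask = np.asarray(mask, dtype=bool).reshape(-1)
    betas = np.full((len(design.condition_names), n_vox), np.nan)
    if mask.any():
        coef, *_ = np.linalg.lstsq(x, y[:, mask], rcond=None)
        cond_idx = [design.names.index(c) for c in design.condition_names]
        betas[:, mask] = coef[cond_idx]
    return betas
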