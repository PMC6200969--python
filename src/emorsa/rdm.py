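"""Representational dissimilarity matrices and Kendall tau-a model comparison.

A representational dissimilarity matrix (RDM) holds the pairwise
dissimilarity (1 - Pearson r) between the activity patterns of the 9
experimental conditions.  The abstract-emotion model RDM is 0 for
same-emotion condition pairs and 1 otherwise; its diagonal (and every
RDM diagonal) is undefined and stored as NaN.

Model-to-neural agreement uses Kendall's tau-a: (concordant - discordant)
pairs divided by n(n-1)/2, where pairs tied in either vector count in the
denominator only.  With a binary model RDM ties dominate, which is exactly
why tau-a (not the tie-corrected tau-b that scipy computes) is required.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import CONDITIONS, emotion_of

__all__ = [
    "RDM",
    "model_rdm",
    "correlation_distance",
    "neural_rdm",
    "kendall_tau_a",
    "compare_to_model",
]


@dataclass
class RDM:
    """Symmetric dissimilarity matrix with a masked (NaN) diagonal."""

    values: np.ndarray
    labels: tuple[str, ...] = field(default=CONDITIONS)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"RDM must be square, got shape {v.shape}")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.allclose(v[off], v.T[off], equal_nan=True):
            raise ValueError("RDM must be symmetric off the diagonal")
        np.fill_diagonal(v, np.nan)
        self.values = v
        self.labels = tuple(self.labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """The n(n-1)/2 above-diagonal entries, row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


def model_rdm(labels: tuple[str, ...] = CONDITIONS) -> RDM:
    """Abstract-emotion model RDM: 0 within emotion, 1 between, NaN diagonal."""
    emotions = [emotion_of(c) for c in labels]
    n = len(labels)
    values = np.array(
        [[0.0 if emotions[i] == emotions[j] else 1.0 for j in range(n)] for i in range(n)]
    )
    return RDM(values=values, labels=tuple(labels))


def correlation_distance(x, y) -> float:
    """1 minus the Pearson correlation of two patterns; range [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("patterns must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("correlation distance needs at least 3 voxels")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc**2).sum())
    ny = np.sqrt((yc**2).sum())
    if nx == 0.0 or ny == 0.0:
        raise ValueError("correlation distance undefined for a constant pattern")
    r = float(np.clip((xc @ yc) / (nx * ny), -1.0, 1.0))
    return 1.0 - r


def neural_rdm(patterns: np.ndarray, labels: tuple[str, ...] = CONDITIONS) -> RDM:
    """Pairwise correlation-distance RDM of condition x voxel patterns."""
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be a condition x voxel matrix")
    n = patterns.shape[0]
    if len(labels) != n:
        raise ValueError("label count does not match pattern count")
    for i in range(n):
        if np.ptp(patterns[i]) == 0.0:
            raise ValueError(
                f"constant activity pattern for condition {labels[i]!r}: "
                "correlation distance undefined"
            )
    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d = correlation_distance(patterns[i], patterns[j])
            values[i, j] = values[j, i] = d
    return RDM(values=values, labels=tuple(labels))


def kendall_tau_a(a, b) -> float:
    """Kendall tau-a: (concordant - discordant) / (n(n-1)/2).

    Pairs tied in either vector count as neither concordant nor discordant
    but remain in the denominator.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    n = a.size
    if n < 2:
        raise ValueError("kendall tau-a needs at least 2 observations")
    sa = np.sign(a[:, None] - a[None, :])
    sb = np.sign(b[:, None] - b[None, :])
    iu = np.triu_indices(n, k=1)
    return float((sa[iu] * sb[iu]).sum() / (n * (n - 1) / 2))


def compare_to_model(neural: RDM, model: RDM) -> float:
    """tau-a between the upper triangles of a neural and a model RDM."""
    if neural.labels != model.labels:
        raise ValueError(
            "RDM condition labels differ (no silent reordering): "
            f"{neural.labels} vs {model.labels}"
        )
    return kendall_tau_a(neural.upper_triangle(), model.upper_triangle())
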