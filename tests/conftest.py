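"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by brute force
(exhaustive enumeration, explicit loops, textbook formulas) so they stay
independent of the library code paths they check.
"""
from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from emorsa.conditions import CONDITIONS
from emorsa.rdm import compare_to_model, model_rdm, neural_rdm
from emorsa.searchlight import SearchlightConfig


def tau_a_oracle(a, b) -> float:
    """Kendall tau-a by exhaustive O(n^2) pair counting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da * db > 0:
                concordant += 1
            elif da * db < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)


def wilcoxon_enumeration_oracle(values, tail: str) -> float:
    """Exact signed-rank p by literal enumeration of all 2^n sign patterns."""
    from scipy.stats import rankdata

    d = np.asarray(values, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    )
    p_greater = (ws >= w_obs - 1e-9).mean()
    if tail == "one_sided_greater":
        return p_greater
    p_less = (ws <= w_obs + 1e-9).mean()
    return min(1.0, 2.0 * min(p_greater, p_less))


def searchlight_naive_oracle(patterns, mask, config: SearchlightConfig):
    """Per-voxel searchlight by direct, non-vectorized recomputation."""
    from emorsa.searchlight import sphere_offsets

    shape = mask.shape
    vols = patterns.reshape(len(CONDITIONS), *shape)
    offs = sphere_offsets(config.radius_mm, config.voxel_size_mm)
    model = model_rdm()
    out = np.full(shape, np.nan)
    min_k = max(config.min_voxels_per_sphere, 3)
    for ijk in np.argwhere(mask):
        members = ijk + offs
        keep = np.all((members >= 0) & (members < shape), axis=1)
        members = members[keep]
        members = members[mask[tuple(members.T)]]
        if len(members) < min_k:
            continue
        sphere = vols[:, members[:, 0], members[:, 1], members[:, 2]]
        out[tuple(ijk)] = compare_to_model(neural_rdm(sphere), model)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
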