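"""Mean-activation analysis within clusters.

Complements the multivariate analyses: cluster-averaged betas per
condition feed a 3 emotions x 3 stimulus-types repeated-measures ANOVA,
and a paired comparison asks whether — after removing each stimulus
type's mean response — the mean activations are more alike within an
emotion than between emotions across stimulus types.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.stats.anova import AnovaRM

from .conditions import CONDITIONS, EMOTIONS, STIM_TYPES, condition_index
from .glm import BetaPatterns
from .stats import TestResult, paired_t

__all__ = [
    "cluster_means",
    "rm_anova_3x3",
    "within_between_difference",
    "WithinBetweenResult",
]


def cluster_means(cohort: list[BetaPatterns], voxels: np.ndarray) -> pd.DataFrame:
    """Subject x condition matrix of cluster-averaged betas (runs first)."""
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        voxels = np.ravel_multi_index(tuple(voxels.T), cohort[0].grid_shape)
    if voxels.size == 0:
        raise ValueError("empty cluster: no voxels to average")
    rows = {
        bp.subject_id: bp.run_mean()[:, voxels].mean(axis=1) for bp in cohort
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(CONDITIONS))


def _long_format(means: pd.DataFrame) -> pd.DataFrame:
    records = []
    for subject, row in means.iterrows():
        for e in EMOTIONS:
            for t in STIM_TYPES:
                records.append(
                    {
                        "subject": subject,
                        "emotion": e,
                        "category": t,
                        "value": row[CONDITIONS[condition_index(e, t)]],
                    }
                )
    return pd.DataFrame(records)


def rm_anova_3x3(means: pd.DataFrame) -> pd.DataFrame:
    """Two-way (Emotion x Category) within-subject ANOVA on condition means.

    Returns a table with effects ``emotion``, ``category`` and
    ``emotion:category``, their F values, uncorrected degrees of freedom
    (df1, df2) and p-values: with n subjects, (2, 2(n-1)) for the main
    effects and (4, 4(n-1)) for the interaction.  Condition-constant data
    make F 0/0; such effects are reported as NaN (no effect).
    """
    n = len(means)
    if n < 3:
        raise ValueError("repeated-measures ANOVA needs at least 3 subjects")
    if means.isna().any().any():
        raise ValueError("missing cells in the 3x3 within-subject design")
    long = _long_format(means)
    effects = {"emotion": (2, 2 * (n - 1)), "category": (2, 2 * (n - 1)),
               "emotion:category": (4, 4 * (n - 1))}
    if np.allclose(means.to_numpy().std(axis=1), 0.0):
        # no variation across conditions within any subject: F = 0/0
        nan_rows = [
            {"effect": k, "F": np.nan, "df1": effects[k][0], "df2": effects[k][1],
             "p": np.nan}
            for k in effects
        ]
        return pd.DataFrame(nan_rows).set_index("effect")
    try:
        with np.errstate(invalid="ignore", divide="ignore"):
            fitted = AnovaRM(
                long, depvar="value", subject="subject",
                within=["emotion", "category"],
            ).fit()
        table = fitted.anova_table
        f_map = {
            "emotion": table.loc["emotion", "F Value"],
            "category": table.loc["category", "F Value"],
            "emotion:category": table.loc["emotion:category", "F Value"],
        }
        p_map = {
            "emotion": table.loc["emotion", "Pr > F"],
            "category": table.loc["category", "Pr > F"],
            "emotion:category": table.loc["emotion:category", "Pr > F"],
        }
    except Exception:  # degenerate (e.g. zero variance) designs
        f_map = {k: np.nan for k in effects}
        p_map = {k: np.nan for k in effects}
    rows = [
        {
            "effect": k,
            "F": float(f_map[k]) if np.isfinite(f_map[k]) else np.nan,
            "df1": effects[k][0],
            "df2": effects[k][1],
            "p": float(p_map[k]) if np.isfinite(p_map[k]) else np.nan,
        }
        for k in effects
    ]
    return pd.DataFrame(rows).set_index("effect")


@dataclass
class WithinBetweenResult:
    """Per-subject mean absolute differences and their paired comparison."""

    within: np.ndarray  # per subject, mean over the 9 within-emotion pairs
    between: np.ndarray  # per subject, mean over the 18 between-emotion pairs
    test: TestResult
    n_within_pairs: int
    n_between_pairs: int


def within_between_difference(means: pd.DataFrame) -> WithinBetweenResult:
    """Within- vs between-emotion absolute activation differences.

    Per subject, each stimulus type's mean (over emotions) is subtracted
    from its three conditions; the mean |difference| is then taken over the
    9 same-emotion cross-type condition pairs and over the 18
    different-emotion cross-type pairs, and the two are compared with a
    paired two-tailed t test across subjects.  Same-type pairs are
    excluded throughout so both quantities compare across stimulus types.
    """
    if means.isna().any().any():
        raise ValueError("missing cells in the 3x3 within-subject design")
    n_e, n_t = len(EMOTIONS), len(STIM_TYPES)
    within, between = [], []
    for _, row in means.iterrows():
        grid = np.array(
            [[row[CONDITIONS[condition_index(e, t)]] for t in STIM_TYPES]
             for e in EMOTIONS]
        )
        grid = grid - grid.mean(axis=0, keepdims=True)  # remove per-type mean
        w_diffs = [
            abs(grid[e, t1] - grid[e, t2])
            for e in range(n_e)
            for t1, t2 in combinations(range(n_t), 2)
        ]
        b_diffs = [
            abs(grid[e1, t1] - grid[e2, t2])
            for t1, t2 in combinations(range(n_t), 2)
            for e1 in range(n_e)
            for e2 in range(n_e)
            if e1 != e2
        ]
        within.append(np.mean(w_diffs))
        between.append(np.mean(b_diffs))
    within = np.array(within)
    between = np.array(between)
    return WithinBetweenResult(
        within=within,
        between=between,
        test=paired_t(within, between, tail="two_sided"),
        n_within_pairs=n_e * (n_t * (n_t - 1) // 2),
        n_between_pairs=(n_t * (n_t - 1) // 2) * n_e * (n_e - 1),
    )
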