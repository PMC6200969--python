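"""Cluster-based cross-modal MVPA: the confirmation test for RSA clusters.

A logistic classifier is trained on the per-run beta patterns of one
stimulus type and tested on another; above-chance generalization evidences
a representation shared across types.  Two schemes decompose the labels
orthogonally:

* ``three_way`` — happy vs angry vs fearful, chance 1/3;
* ``valence`` — happy (positive) vs angry+fearful (negative), chance 1/2,
  with half of the angry and half of the fearful samples dropped at random
  (repeated and averaged) so the two classes stay balanced.

Per subject and type pair, accuracy is the mean of the two train/test
folds (e.g. face->body and body->face).  Group inference is a one-sample
t test of the per-subject pair accuracies against chance; a cluster is
"confirmed" when, in at least one scheme, it is significantly above chance
for at least two of the three stimulus-type pairs.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .conditions import EMOTIONS, STIM_TYPES, condition_index
from .glm import BetaPatterns
from .stats import one_sample_t

__all__ = [
    "ClassificationTask",
    "PatternSet",
    "extract_cluster_patterns",
    "crossmodal_classify",
    "pair_accuracy",
    "evaluate_clusters",
    "confirmed_clusters",
]

THREE_WAY = "three_way"
VALENCE = "valence"
_SCHEMES = (THREE_WAY, VALENCE)

#: default number of random half-dropping repetitions for the valence scheme
N_SUBSAMPLE_REPS = 20
#: L2 regularization strength of the logistic classifier
LOGISTIC_C = 1.0

TYPE_PAIRS: tuple[tuple[str, str], ...] = tuple(combinations(STIM_TYPES, 2))


@dataclass(frozen=True)
class ClassificationTask:
    """A cross-modal classification problem for one stimulus-type pair."""

    scheme: str
    train_type: str
    test_type: str

    def __post_init__(self) -> None:
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}")
        if self.train_type == self.test_type:
            raise ValueError("train_type and test_type must differ (cross-modal)")
        for t in (self.train_type, self.test_type):
            if t not in STIM_TYPES:
                raise ValueError(f"unknown stimulus type {t!r}")

    @property
    def chance(self) -> float:
        return 1.0 / 3.0 if self.scheme == THREE_WAY else 0.5


@dataclass
class PatternSet:
    """Samples of one stimulus type: (n_runs * 3 emotions) x voxel matrix."""

    x: np.ndarray
    emotions: np.ndarray  # emotion label per sample
    runs: np.ndarray
    stim_type: str


def extract_cluster_patterns(
    bp: BetaPatterns, voxels: np.ndarray
) -> dict[str, PatternSet]:
    """Per stimulus type, one sample per (run, emotion) over cluster voxels.

    ``voxels`` may be flat indices or an (m, 3) array of ijk coordinates.
    """
    voxels = np.asarray(voxels)
    if voxels.ndim == 2:
        voxels = np.ravel_multi_index(tuple(voxels.T), bp.grid_shape)
    if voxels.size == 0:
        raise ValueError("empty cluster: no voxels to extract")
    out: dict[str, PatternSet] = {}
    for stim in STIM_TYPES:
        rows, emo, runs = [], [], []
        for run in range(bp.n_runs):
            for e in EMOTIONS:
                rows.append(bp.betas[run, condition_index(e, stim), voxels])
                emo.append(e)
                runs.append(run)
        out[stim] = PatternSet(
            x=np.array(rows), emotions=np.array(emo), runs=np.array(runs), stim_type=stim
        )
    return out


def _classifier():
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=LOGISTIC_C, max_iter=1000),
    )


def _fit_and_score(train_x, train_y, test_x, test_y) -> float:
    clf = _classifier()
    clf.fit(train_x, train_y)
    return float(clf.score(test_x, test_y))


def _valence_subsample(
    emotions: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Indices keeping all happy samples and half of angry plus half of
    fearful, the halves chosen so the negative class matches the positive
    class count (odd counts are rounded up/down at random)."""
    happy = np.flatnonzero(emotions == "happy")
    angry = np.flatnonzero(emotions == "angry")
    fear = np.flatnonzero(emotions == "fearful")
    n_pos = happy.size
    if n_pos > angry.size + fear.size or n_pos == 0:
        raise ValueError("cannot balance classes for the valence scheme")
    # keep ~half of each negative emotion; odd halves are rounded up in one
    # emotion and down in the other, the direction chosen at random
    choices = [
        k
        for k in {angry.size // 2, (angry.size + 1) // 2}
        if 2 * abs((n_pos - k) - fear.size / 2) <= 1 and 0 <= n_pos - k <= fear.size
    ]
    if not choices:  # degenerate counts: stay balanced, drop the half-split
        lo, hi = max(0, n_pos - fear.size), min(angry.size, n_pos)
        choices = [int(np.clip(round(angry.size / 2), lo, hi))]
    k_angry = int(choices[rng.integers(0, len(choices))])
    k_fear = n_pos - k_angry
    keep = np.concatenate(
        [
            happy,
            rng.choice(angry, size=k_angry, replace=False),
            rng.choice(fear, size=k_fear, replace=False),
        ]
    )
    return np.sort(keep)


def _to_valence(emotions: np.ndarray) -> np.ndarray:
    return np.where(emotions == "happy", "positive", "negative")


def crossmodal_classify(
    train: PatternSet,
    test: PatternSet,
    task: ClassificationTask,
    seed: int | np.random.Generator = 0,
    n_subsample_reps: int = N_SUBSAMPLE_REPS,
) -> float:
    """Accuracy of one cross-modal fold (train on one type, test on the other)."""
    if train.stim_type != task.train_type or test.stim_type != task.test_type:
        raise ValueError("pattern sets do not match the task's stimulus types")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if task.scheme == THREE_WAY:
        if np.unique(train.emotions).size < 2:
            raise ValueError("training set holds a single class")
        return _fit_and_score(train.x, train.emotions, test.x, test.emotions)
    accs = []
    for _ in range(n_subsample_reps):
        for _attempt in range(100):
            tr_keep = _valence_subsample(train.emotions, rng)
            te_keep = _valence_subsample(test.emotions, rng)
            tr_y = _to_valence(train.emotions[tr_keep])
            if np.unique(tr_y).size == 2:
                break
        else:
            raise ValueError("could not draw a two-class training subsample")
        accs.append(
            _fit_and_score(
                train.x[tr_keep],
                tr_y,
                test.x[te_keep],
                _to_valence(test.emotions[te_keep]),
            )
        )
    return float(np.mean(accs))


def pair_accuracy(
    patterns: dict[str, PatternSet],
    scheme: str,
    type_pair: tuple[str, str],
    seed: int | np.random.Generator = 0,
    n_subsample_reps: int = N_SUBSAMPLE_REPS,
) -> float:
    """Mean accuracy over the two cross-validation folds of a type pair."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    a, b = type_pair
    folds = [
        crossmodal_classify(
            patterns[a],
            patterns[b],
            ClassificationTask(scheme, a, b),
            rng,
            n_subsample_reps,
        ),
        crossmodal_classify(
            patterns[b],
            patterns[a],
            ClassificationTask(scheme, b, a),
            rng,
            n_subsample_reps,
        ),
    ]
    return float(np.mean(folds))


def significantly_above_chance(
    accuracies: np.ndarray, chance: float, alpha: float = 0.05
):
    """Group test of accuracies against chance.

    Returns (TestResult, significant).  Ordinary case: two-tailed
    one-sample t with the ``significant`` flag additionally requiring the
    mean to exceed chance.  A zero-variance accuracy vector is degenerate:
    exactly at chance it is maximally null (t=0, p=1, not significant);
    constant strictly above chance it is taken as significant (the t -> inf
    limit; e.g. every subject classifying perfectly).
    """
    accuracies = np.asarray(accuracies, dtype=float)
    res = one_sample_t(accuracies, mu0=chance, tail="two_sided")
    if res.degenerate:
        return res, bool(accuracies.mean() > chance)
    return res, bool(res.pvalue < alpha and accuracies.mean() > chance)


def evaluate_clusters(
    cohort: list[BetaPatterns],
    clusters: dict[int, np.ndarray],
    schemes: tuple[str, ...] = (THREE_WAY, VALENCE),
    type_pairs: tuple[tuple[str, str], ...] = TYPE_PAIRS,
    alpha: float = 0.05,
    seed: int = 0,
    n_subsample_reps: int = N_SUBSAMPLE_REPS,
) -> pd.DataFrame:
    """Group-level accuracy table per cluster x scheme x type pair.

    ``clusters`` maps cluster id to its voxel indices (flat or ijk).
    Significance per row follows :func:`significantly_above_chance`.
    """
    if len(cohort) < 2:
        raise ValueError("group evaluation needs at least 2 subjects")
    root = np.random.SeedSequence(seed)
    subject_rngs = [np.random.default_rng(c) for c in root.spawn(len(cohort))]
    rows = []
    for cid, voxels in clusters.items():
        per_subject = [extract_cluster_patterns(bp, voxels) for bp in cohort]
        for scheme in schemes:
            chance = 1.0 / 3.0 if scheme == THREE_WAY else 0.5
            for pair in type_pairs:
                accs = np.array(
                    [
                        pair_accuracy(pats, scheme, pair, rng, n_subsample_reps)
                        for pats, rng in zip(per_subject, subject_rngs)
                    ]
                )
                res, significant = significantly_above_chance(accs, chance, alpha)
                rows.append(
                    {
                        "cluster_id": cid,
                        "scheme": scheme,
                        "pair": f"{pair[0]}-{pair[1]}",
                        "mean_accuracy": float(accs.mean()),
                        "t": res.statistic,
                        "df": res.df,
                        "p": res.pvalue,
                        "significant": bool(significant),
                    }
                )
    return pd.DataFrame(rows)


def confirmed_clusters(results: pd.DataFrame, min_pairs: int = 2) -> list[int]:
    """Cluster ids passing the confirmation rule: at least ``min_pairs``
    significant stimulus-type pairs in at least one scheme."""
    confirmed = []
    for cid, sub in results.groupby("cluster_id"):
        by_scheme = sub.groupby("scheme")["significant"].sum()
        if (by_scheme >= min_pairs).any():
            confirmed.append(int(cid))
    return sorted(confirmed)
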