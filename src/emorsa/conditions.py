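"""Canonical condition ordering for the 3 emotions x 3 stimulus types design.

The 9 conditions are enumerated emotion-major: all stimulus types of the
first emotion, then of the second, and so on.  Every array in the package
whose axis is "condition" follows this ordering.
"""
from __future__ import annotations

EMOTIONS: tuple[str, ...] = ("happy", "angry", "fearful")
STIM_TYPES: tuple[str, ...] = ("face", "body", "whole_person")

#: the 9 (emotion, stimulus type) pairs in emotion-major order
CONDITION_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (e, t) for e in EMOTIONS for t in STIM_TYPES
)

#: flat condition labels, e.g. "happy_face"
CONDITIONS: tuple[str, ...] = tuple(f"{e}_{t}" for e, t in CONDITION_PAIRS)

N_CONDITIONS = len(CONDITIONS)


def condition_index(emotion: str, stim_type: str) -> int:
    """Index of a condition in the canonical ordering."""
    if emotion not in EMOTIONS:
        raise ValueError(f"unknown emotion {emotion!r}; expected one of {EMOTIONS}")
    if stim_type not in STIM_TYPES:
        raise ValueError(
            f"unknown stimulus type {stim_type!r}; expected one of {STIM_TYPES}"
        )
    return EMOTIONS.index(emotion) * len(STIM_TYPES) + STIM_TYPES.index(stim_type)


def emotion_of(condition: str) -> str:
    return condition.split("_", 1)[0]


def stim_type_of(condition: str) -> str:
    return condition.split("_", 1)[1]
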