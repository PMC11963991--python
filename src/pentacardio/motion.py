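"""Motion-state recognition from 10-s mechanical segments.

A segment's 30 mechanical channels are pooled into a timestamp sequence
(see :mod:`pentacardio.seqmodel`) and classified into composite
probabilities over sitting / walking / jogging / running; those
probabilities later weight the per-state combination filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import Segment
from .seqmodel import (
    FittedSequenceClassifier,
    SequenceModelConfig,
    evaluate_classifier,
    train_sequence_classifier,
)
from .synth import MOTION_STATES


@dataclass
class MotionStateProbs:
    """Composite probabilities over the motion states."""

    states: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.ndim != 1 or len(p) != len(self.states):
            raise ValueError("one probability per state required")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def argmax_state(self) -> str:
        return self.states[int(np.argmax(self.probabilities))]

    def as_dict(self) -> dict[str, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}

    @classmethod
    def one_hot(cls, state: str, states=MOTION_STATES) -> "MotionStateProbs":
        p = np.zeros(len(states))
        p[states.index(state)] = 1.0
        return cls(tuple(states), p)

    @classmethod
    def uniform(cls, states=MOTION_STATES) -> "MotionStateProbs":
        return cls(tuple(states), np.full(len(states), 1.0 / len(states)))


def train_motion_classifier(
    segments: list[Segment],
    labels: list[str] | None = None,
    model_kind: str = "transformer",
    config: SequenceModelConfig | None = None,
    seed: int = 0,
) -> FittedSequenceClassifier:
    """Fit a motion-state classifier on labeled mechanical segments.

    Labels default to each segment's annotated ``motion_state``.
    """
    if labels is None:
        labels = [s.motion_state for s in segments]
        if any(l is None for l in labels):
            raise ValueError("segments carry no motion-state labels")
    states = [s for s in MOTION_STATES if s in set(labels)]
    return train_sequence_classifier(
        segments,
        labels,
        model_kind=model_kind,
        config=config,
        seed=seed,
        channels=list(segments[0].layout.mech_channels),
        class_order=states,
    )


def classify_motion(model: FittedSequenceClassifier, segment: Segment) -> MotionStateProbs:
    """Composite motion-state probabilities for one segment."""
    proba = model.predict_proba([segment])[0]
    return MotionStateProbs(tuple(model.classes), proba)


def classify_motion_batch(
    model: FittedSequenceClassifier, segments: list[Segment]
) -> list[MotionStateProbs]:
    proba = model.predict_proba(segments)
    return [MotionStateProbs(tuple(model.classes), p) for p in proba]


__all__ = [
    "MotionStateProbs",
    "train_motion_classifier",
    "classify_motion",
    "classify_motion_batch",
    "evaluate_classifier",
]
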