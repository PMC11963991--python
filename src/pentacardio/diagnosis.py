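"""Heart-condition classification (normal / A-Fib / MI / HF).

The same transformer architecture as motion recognition, applied to the
trimodal cardiac channels (ECG + pad-5 SCG accelerometer + pad-5 GCG
gyroscope) of each 10-s segment, with an ablation harness that retrains
the model per modality subset under an identical budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layout import ChannelLayout
from .recording import Segment
from .seqmodel import (
    FittedSequenceClassifier,
    SequenceModelConfig,
    evaluate_classifier,
    train_sequence_classifier,
)
from .synth import DISEASE_LABELS

MODALITIES = ("ecg", "scg", "gcg")


def modality_channels(layout: ChannelLayout, modalities) -> list[str]:
    """Channel names carrying the requested modalities.

    ECG is the electrode channel(s); SCG the acquisition pad's
    accelerometer axes; GCG its gyroscope axes.
    """
    out: list[str] = []
    for m in modalities:
        if m == "ecg":
            out.extend(layout.ecg_channels)
        elif m == "scg":
            out.extend(layout.pad_channels(layout.acquisition_pad, "Acc"))
        elif m == "gcg":
            out.extend(layout.pad_channels(layout.acquisition_pad, "Rot"))
        else:
            raise ValueError(f"unknown modality {m!r}")
    return out


@dataclass
class DiagnosisProbs:
    """Probabilities over the heart-condition classes."""

    classes: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, float)
        if p.ndim != 1 or len(p) != len(self.classes):
            raise ValueError("one probability per class required")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        self.probabilities = np.clip(p, 0.0, None)

    @property
    def argmax_label(self) -> str:
        return self.classes[int(np.argmax(self.probabilities))]

    def as_dict(self) -> dict[str, float]:
        return {c: float(p) for c, p in zip(self.classes, self.probabilities)}


def train_diagnosis_model(
    segments: list[Segment],
    labels: list[str] | None = None,
    model_kind: str = "transformer",
    config: SequenceModelConfig | None = None,
    seed: int = 0,
    modalities=MODALITIES,
) -> FittedSequenceClassifier:
    """Fit a heart-condition classifier on labeled trimodal segments."""
    if labels is None:
        labels = [s.disease_label for s in segments]
        if any(l is None for l in labels):
            raise ValueError("segments carry no disease labels")
    channels = modality_channels(segments[0].layout, modalities)
    classes = [c for c in DISEASE_LABELS if c in set(labels)]
    fitted = train_sequence_classifier(
        segments,
        labels,
        model_kind=model_kind,
        config=config,
        seed=seed,
        channels=channels,
        class_order=classes,
    )
    fitted.training_log["modalities"] = tuple(modalities)
    return fitted


def diagnose(model: FittedSequenceClassifier, segment: Segment) -> DiagnosisProbs:
    """Heart-condition probabilities for one segment (stateless inference)."""
    proba = model.predict_proba([segment])[0]
    return DiagnosisProbs(tuple(model.classes), proba)


def diagnose_batch(model: FittedSequenceClassifier, segments: list[Segment]):
    proba = model.predict_proba(segments)
    return [DiagnosisProbs(tuple(model.classes), p) for p in proba]


def ablation_study(
    train_segments: list[Segment],
    train_labels: list[str],
    test_segments: list[Segment],
    test_labels: list[str],
    modal_subsets: list[tuple[str, ...]] | None = None,
    model_kind: str = "transformer",
    config: SequenceModelConfig | None = None,
    seed: int = 0,
) -> dict[str, dict]:
    """Paired modality ablation: one model per subset, identical budget.

    The same underlying train/test segments are reused for every subset;
    only the channel mask changes.  Returns per-subset evaluation dicts
    (confusion matrix, per-class accuracy, macro-F1).
    """
    if len(train_segments) != len(train_labels) or len(test_segments) != len(test_labels):
        raise ValueError("unpaired dataset: segments and labels differ in length")
    if modal_subsets is None:
        modal_subsets = [("ecg",), ("scg",), ("gcg",), ("ecg", "scg", "gcg")]
    results = {}
    for subset in modal_subsets:
        name = "+".join(subset)
        fitted = train_diagnosis_model(
            train_segments,
            train_labels,
            model_kind=model_kind,
            config=config,
            seed=seed,
            modalities=subset,
        )
        res = evaluate_classifier(fitted, test_segments, test_labels)
        res["modalities"] = subset
        res["n_channels"] = len(fitted.channels)
        results[name] = res
    return results


__all__ = [
    "DiagnosisProbs",
    "modality_channels",
    "train_diagnosis_model",
    "diagnose",
    "diagnose_batch",
    "ablation_study",
]
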