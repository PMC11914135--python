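"""Replay of copy-phrase sessions through the online filter and a model.

A saved calibration model is applied to a copy-phrase recording that is
processed exactly as it would arrive during closed-loop use: buffered
inquiry epochs through the online (OF) pipeline, never whole-record
filtering.  Per-trial likelihood ratios are scored into a confusion
matrix with a strict >1.0 positive rule (a likelihood of exactly 1.0
counts as a negative call).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filters import FilterSpec, online_pipeline
from .metrics import ConfusionMatrix, balanced_accuracy, matthews_cc
from .models import TrainedModel, predict_likelihoods
from .synthetic import RawSession

__all__ = [
    "ScoringRule",
    "SimulationResult",
    "score_likelihoods",
    "simulate_copy_phrase",
]


@dataclass
class ScoringRule:
    """Likelihood cutoff; positives are strictly greater than it."""

    threshold: float = 1.0


@dataclass
class SimulationResult:
    confusion: ConfusionMatrix
    ba: float
    mcc: float
    records: pd.DataFrame = field(default_factory=pd.DataFrame)


def score_likelihoods(likelihoods, labels,
                      rule: ScoringRule = ScoringRule()) -> ConfusionMatrix:
    """Count TP/FN/FP/TN from likelihoods and binary target labels.

    Targets with likelihood > threshold are TP, <= threshold FN;
    non-targets with likelihood > threshold are FP, <= threshold TN.
    """
    likelihoods = np.asarray(likelihoods, dtype=float)
    labels = np.asarray(labels)
    if likelihoods.shape != labels.shape:
        raise ValueError("likelihoods and labels must have equal length")
    return ConfusionMatrix.from_predictions(labels,
                                            likelihoods > rule.threshold)


def simulate_copy_phrase(model: TrainedModel, session: RawSession,
                         spec: FilterSpec,
                         rule: ScoringRule = ScoringRule(),
                         trial_window_s: float = 0.7,
                         buffer_s: float = 1.0) -> SimulationResult:
    """Score one copy-phrase session with a saved model.

    The session runs through ``online_pipeline`` only (asserted via the
    dataset's provenance tag); the model's likelihood ratios are scored
    into a confusion matrix, and BA/MCC are derived from it.  Per-trial
    likelihood records are kept so alternative decision rules can be
    evaluated later without re-simulation.
    """
    data = online_pipeline(session, spec, trial_window_s, buffer_s)
    assert data.provenance == "OF"
    if data.trials.shape[1:] != model.input_shape:
        raise ValueError(
            f"montage/window mismatch: model expects "
            f"{model.input_shape}, session yields {data.trials.shape[1:]}")
    lik = predict_likelihoods(model, data)
    cm = score_likelihoods(lik, data.labels, rule)
    records = pd.DataFrame({
        "inquiry": (data.inquiry_index if data.inquiry_index is not None
                    else np.zeros(data.n_trials, dtype=int)),
        "label": data.labels,
        "likelihood": lik,
    })
    ba = balanced_accuracy(cm) if cm.n_positive and cm.n_negative else float("nan")
    return SimulationResult(cm, ba, matthews_cc(cm), records)
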