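"""Filter chain and the two application orders (conventional vs online).

The chain is: zero-phase IIR notch at the power-line frequency (quality
factor 30, applied forward-backward), causal 5th-order Butterworth
bandpass (forward only, zero initial conditions), then decimation by
sample-keeping.

Conventional filtering (CF) runs the chain once over the whole continuous
record and then cuts trials.  Online-parity filtering (OF) first cuts each
inquiry out of the raw record with a transient-absorbing buffer on each
end, filters every buffered epoch independently — exactly as chunks arrive
during closed-loop use — and only then cuts trials.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import signal

from .synthetic import RawSession, StimulusSchedule

__all__ = [
    "FilterSpec",
    "DesignedFilters",
    "InquiryEpochs",
    "TrialDataset",
    "design_filter_chain",
    "apply_filter_chain",
    "conventional_pipeline",
    "online_pipeline",
    "epoch_inquiries",
    "save_trials",
    "load_trials",
]


@dataclass
class FilterSpec:
    """Parameters of the notch -> bandpass -> downsample chain."""

    notch_freq: float = 60.0
    notch_q: float = 30.0
    band_low: float = 1.0
    band_high: float = 20.0
    butter_order: int = 5
    downsample_factor: int = 2

    def validate(self, fs: float) -> None:
        nyq_out = fs / (2 * self.downsample_factor)
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if self.band_high >= nyq_out:
            raise ValueError(
                f"band_high {self.band_high} Hz must lie below the "
                f"post-downsample Nyquist {nyq_out} Hz")
        if self.notch_freq <= 0 or self.notch_q <= 0:
            raise ValueError("notch frequency and Q must be positive")
        if self.notch_freq >= fs / 2:
            raise ValueError("notch frequency must lie below Nyquist")
        if self.downsample_factor < 1 or self.butter_order < 1:
            raise ValueError("downsample_factor and butter_order must be >= 1")

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low, self.band_high)


@dataclass
class DesignedFilters:
    """Realized coefficients plus magnitude-response evaluators."""

    notch_b: np.ndarray
    notch_a: np.ndarray
    bandpass_sos: np.ndarray
    fs: float

    def notch_magnitude(self, freqs) -> np.ndarray:
        """Zero-phase (forward-backward) notch magnitude = |H|^2."""
        _, h = signal.freqz(self.notch_b, self.notch_a,
                            worN=np.atleast_1d(freqs), fs=self.fs)
        return np.abs(h) ** 2

    def bandpass_magnitude(self, freqs) -> np.ndarray:
        _, h = signal.sosfreqz(self.bandpass_sos,
                               worN=np.atleast_1d(freqs), fs=self.fs)
        return np.abs(h)

    @property
    def min_segment_len(self) -> int:
        """Shortest segment the chain accepts (3x the longest filter)."""
        ntaps = max(len(self.notch_b), self.bandpass_sos.shape[0] * 2 + 1)
        return 3 * ntaps + 1


def design_filter_chain(spec: FilterSpec, fs: float) -> DesignedFilters:
    """Design the notch and Butterworth bandpass for a sampling rate.

    The notch is a 2nd-order IIR with bandwidth ``notch_freq / notch_q``;
    the bandpass is an order-``butter_order`` Butterworth prototype
    transformed to the band (twice the poles), so the magnitude is exactly
    -3 dB at both band edges.
    """
    spec.validate(fs)
    notch_b, notch_a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=fs)
    sos = signal.butter(spec.butter_order, [spec.band_low, spec.band_high],
                        btype="bandpass", fs=fs, output="sos")
    return DesignedFilters(notch_b, notch_a, sos, fs)


def apply_filter_chain(segment: np.ndarray, filters: DesignedFilters,
                       spec: FilterSpec) -> np.ndarray:
    """Run one segment (channels x samples) through the chain.

    The notch runs forward-backward (zero net phase); the bandpass runs
    forward only with zero initial conditions; decimation keeps every
    ``downsample_factor``-th sample starting at index 0.
    """
    segment = np.atleast_2d(np.asarray(segment, dtype=float))
    n = segment.shape[1]
    if n <= filters.min_segment_len:
        raise ValueError(
            f"segment of {n} samples is too short to filter; need more "
            f"than {filters.min_segment_len} samples")
    out = signal.filtfilt(filters.notch_b, filters.notch_a, segment, axis=1)
    out = signal.sosfilt(filters.bandpass_sos, out, axis=1)
    return out[:, :: spec.downsample_factor]


# ---------------------------------------------------------------------------
# Trial containers
# ---------------------------------------------------------------------------

@dataclass
class TrialDataset:
    """Post-filter trial tensor with binary target labels."""

    trials: np.ndarray            # n x channels x samples
    labels: np.ndarray            # 1 = target, 0 = non-target
    trial_window_s: float
    effective_fs: float
    provenance: str               # "CF" | "OF"
    band: tuple[float, float]
    channel_names: list[str] = field(default_factory=list)
    inquiry_index: Optional[np.ndarray] = None  # per-trial inquiry id

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.trials.ndim != 3:
            raise ValueError("trials must be n x channels x samples")
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.provenance not in ("CF", "OF"):
            raise ValueError("provenance must be 'CF' or 'OF'")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_targets(self) -> int:
        return int(self.labels.sum())


@dataclass
class InquiryEpochs:
    """Buffered per-inquiry cuts of the raw record, pre-filtering."""

    epochs: list[np.ndarray]          # channels x samples, may differ in length
    start_samples: np.ndarray         # raw-record sample of each epoch start
    onset_samples: list[np.ndarray]   # per-inquiry stimulus onsets (raw samples)
    labels: list[np.ndarray]
    buffer_s: float
    fs: float


def _onset_samples(schedule: StimulusSchedule, fs: float) -> np.ndarray:
    return np.round(schedule.stimulus_onsets() * fs).astype(int)


def _extract(downsampled: np.ndarray, onset_samples_raw: np.ndarray,
             offset_raw: int, factor: int, n_keep: int) -> np.ndarray:
    """Cut trials from a decimated segment.

    ``onset_samples_raw`` are raw-record indices; ``offset_raw`` is the
    raw index of the segment's first sample (0 for whole-record CF).  The
    post-decimation index is the integer floor of the relative onset.
    """
    trials = []
    for onset in onset_samples_raw:
        start = (onset - offset_raw) // factor
        trials.append(downsampled[:, start:start + n_keep])
    return np.stack(trials) if trials else np.empty(
        (0, downsampled.shape[0], n_keep))


def conventional_pipeline(raw: RawSession, spec: FilterSpec,
                          trial_window_s: float = 0.7) -> TrialDataset:
    """Whole-record filtering, then trial segmentation (CF)."""
    filters = design_filter_chain(spec, raw.fs)
    factor = spec.downsample_factor
    onsets = _onset_samples(raw.schedule, raw.fs)
    win = int(trial_window_s * raw.fs)
    bad = onsets[onsets + win > raw.n_samples]
    if bad.size:
        raise ValueError(
            "stimulus onsets extend past the record at samples "
            f"{bad.tolist()}")
    filtered = apply_filter_chain(raw.data, filters, spec)
    n_keep = win // factor
    trials = _extract(filtered, onsets, 0, factor, n_keep)
    return TrialDataset(trials, raw.schedule.trial_labels(), trial_window_s,
                        raw.fs / factor, "CF", spec.band, raw.channel_names,
                        raw.schedule.inquiry_index_per_trial())


def epoch_inquiries(raw: RawSession, trial_window_s: float = 0.7,
                    buffer_s: float = 1.0, align: int = 2) -> InquiryEpochs:
    """Cut buffered inquiry epochs from the raw (unfiltered) record.

    Each epoch spans (first onset - buffer) to (last onset + trial window
    + buffer).  Epoch starts are snapped down to the decimation grid so OF
    and CF share the same post-downsample sample phase.  Overlapping
    epochs are cut independently, mirroring online chunk delivery.
    """
    if buffer_s < 0:
        raise ValueError("buffer_s must be >= 0")
    fs = raw.fs
    epochs, starts, onset_lists, labels = [], [], [], []
    for inq in raw.schedule.inquiries:
        onsets = np.round(inq.stimulus_onsets * fs).astype(int)
        start = int(np.floor((inq.stimulus_onsets[0] - buffer_s) * fs))
        start -= start % align  # decimation-grid alignment
        end = int(np.ceil((inq.stimulus_onsets[-1] + trial_window_s
                           + buffer_s) * fs))
        if start < 0 or end > raw.n_samples:
            raise ValueError(
                f"buffered inquiry epoch [{start}, {end}) falls outside "
                f"the record of {raw.n_samples} samples")
        epochs.append(raw.data[:, start:end])
        starts.append(start)
        onset_lists.append(onsets)
        lab = np.zeros(len(inq.stimulus_labels), dtype=int)
        if inq.target_position is not None:
            lab[inq.target_position] = 1
        labels.append(lab)
    return InquiryEpochs(epochs, np.asarray(starts, dtype=int), onset_lists,
                         labels, buffer_s, fs)


def online_pipeline(raw: RawSession, spec: FilterSpec,
                    trial_window_s: float = 0.7,
                    buffer_s: float = 1.0) -> TrialDataset:
    """Buffered-inquiry filtering, then trial segmentation (OF).

    Every inquiry epoch passes through the chain independently with zero
    initial filter state; the buffers absorb the causal bandpass
    transient and are discarded when trials are extracted.
    """
    filters = design_filter_chain(spec, raw.fs)
    factor = spec.downsample_factor
    inq = epoch_inquiries(raw, trial_window_s, buffer_s, align=factor)
    n_keep = int(trial_window_s * raw.fs) // factor
    per_inq = []
    for seg, start, onsets in zip(inq.epochs, inq.start_samples,
                                  inq.onset_samples):
        filtered = apply_filter_chain(seg, filters, spec)
        per_inq.append(_extract(filtered, onsets, start, factor, n_keep))
    trials = (np.concatenate(per_inq) if per_inq
              else np.empty((0, raw.data.shape[0], n_keep)))
    return TrialDataset(trials, raw.schedule.trial_labels(), trial_window_s,
                        raw.fs / factor, "OF", spec.band, raw.channel_names,
                        raw.schedule.inquiry_index_per_trial())


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_trials(data: TrialDataset, path: str | Path) -> None:
    """Write the trial tensor (.npz) and a JSON sidecar of its metadata."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), trials=data.trials,
                        labels=data.labels,
                        inquiry_index=(data.inquiry_index
                                       if data.inquiry_index is not None
                                       else np.empty(0, dtype=int)))
    sidecar = {
        "trial_window_s": data.trial_window_s,
        "effective_fs": data.effective_fs,
        "provenance": data.provenance,
        "band": list(data.band),
        "channel_names": data.channel_names,
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def load_trials(path: str | Path) -> TrialDataset:
    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    inq = arrays["inquiry_index"]
    return TrialDataset(arrays["trials"], arrays["labels"],
                        meta["trial_window_s"], meta["effective_fs"],
                        meta["provenance"], tuple(meta["band"]),
                        meta["channel_names"],
                        inq if inq.size else None)
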