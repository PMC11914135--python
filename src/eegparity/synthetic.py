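"""Synthetic RSVP calibration / copy-phrase EEG sessions.

The generator emulates the statistical structure a P300 speller calibration
recording is assumed to have: per-channel AR(1) background EEG, a 10 Hz
alpha rhythm, 60 Hz power-line interference, frontal blink artifacts, and
N200/P300 event-related deflections time-locked to attended (target)
stimuli.  Everything is deterministic given the seed so downstream pipeline
comparisons are exactly reproducible.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "CHANNELS_1020",
    "SYMBOLS",
    "Inquiry",
    "StimulusSchedule",
    "ErpParams",
    "NoiseParams",
    "ArtifactParams",
    "SynthesisParams",
    "RawSession",
    "build_calibration_schedule",
    "build_copy_phrase_schedule",
    "synthesize_session",
    "erp_template",
    "save_session",
    "load_session",
]

#: Deduplicated 19-channel 10-20 montage of the dry-electrode headset.
CHANNELS_1020 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
]

#: RSVP symbol set: the alphabet plus space ("_") and backspace ("<").
SYMBOLS = list(string.ascii_uppercase) + ["_", "<"]


# ---------------------------------------------------------------------------
# Stimulus schedules
# ---------------------------------------------------------------------------

@dataclass
class Inquiry:
    """One burst of sequential stimuli (the unit of online processing)."""

    stimulus_labels: list[str]
    target_label: Optional[str]
    target_position: Optional[int]  # 0-based index into stimulus_labels
    prompt_onset: Optional[float]   # s; None when the letter was not prompted
    fixation_onset: float           # s
    stimulus_onsets: np.ndarray     # s, one per stimulus

    def __post_init__(self) -> None:
        self.stimulus_onsets = np.asarray(self.stimulus_onsets, dtype=float)
        if self.target_position is not None:
            if not 0 <= self.target_position < len(self.stimulus_labels):
                raise ValueError("target_position outside the inquiry")
            if self.stimulus_labels[self.target_position] != self.target_label:
                raise ValueError("target_label does not match target_position")


@dataclass
class StimulusSchedule:
    """Ordered inquiries with their presentation timing."""

    inquiries: list[Inquiry]
    presentation_rate: float  # Hz
    inter_inquiry_gap: float  # s, blank screen between inquiries

    @property
    def n_inquiries(self) -> int:
        return len(self.inquiries)

    @property
    def n_stimuli(self) -> int:
        return sum(len(inq.stimulus_labels) for inq in self.inquiries)

    @property
    def n_target_free(self) -> int:
        return sum(1 for inq in self.inquiries if inq.target_position is None)

    def stimulus_onsets(self) -> np.ndarray:
        """All stimulus onsets (s), in presentation order."""
        if not self.inquiries:
            return np.empty(0)
        return np.concatenate([inq.stimulus_onsets for inq in self.inquiries])

    def trial_labels(self) -> np.ndarray:
        """Binary target (1) / non-target (0) label per stimulus."""
        out = []
        for inq in self.inquiries:
            lab = np.zeros(len(inq.stimulus_labels), dtype=int)
            if inq.target_position is not None:
                lab[inq.target_position] = 1
            out.append(lab)
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    def inquiry_index_per_trial(self) -> np.ndarray:
        out = [np.full(len(inq.stimulus_labels), i, dtype=int)
               for i, inq in enumerate(self.inquiries)]
        return np.concatenate(out) if out else np.empty(0, dtype=int)

    @property
    def duration(self) -> float:
        """Time (s) from 0 to the end of the last inquiry presentation."""
        if not self.inquiries:
            return 0.0
        return float(self.inquiries[-1].stimulus_onsets[-1]
                     + 1.0 / self.presentation_rate)


def _inquiry_onsets(start: float, n_stims: int, rate: float,
                    prompt_s: float, fixation_s: float):
    """Timing of one inquiry iteration starting at ``start`` seconds."""
    prompt = start if prompt_s > 0 else None
    fixation = start + prompt_s
    first_stim = fixation + fixation_s
    onsets = first_stim + np.arange(n_stims) / rate
    end = onsets[-1] + 1.0 / rate
    return prompt, fixation, onsets, end


def build_calibration_schedule(
    n_inquiries: int = 110,
    stims_per_inquiry: int = 10,
    no_target_fraction: float = 0.10,
    rate: float = 5.0,
    prompt_s: float = 1.0,
    fixation_s: float = 0.5,
    gap_s: float = 2.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Build an RSVP calibration schedule.

    Each iteration is a 1 s target prompt, a 0.5 s fixation, then
    ``stims_per_inquiry`` letters at ``rate`` Hz, followed by a blank gap.
    A fraction of inquiries contains no target at all; in the rest the
    target occupies a uniformly random position.
    """
    if n_inquiries < 0 or stims_per_inquiry < 0:
        raise ValueError("counts must be non-negative")
    if rate <= 0:
        raise ValueError("presentation rate must be positive")
    if not 0.0 <= no_target_fraction <= 1.0:
        raise ValueError("no_target_fraction must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_free = int(round(n_inquiries * no_target_fraction))
    free = np.zeros(n_inquiries, dtype=bool)
    free[rng.permutation(n_inquiries)[:n_free]] = True

    inquiries: list[Inquiry] = []
    t = 0.0
    for i in range(n_inquiries):
        labels = list(rng.choice(SYMBOLS, size=stims_per_inquiry, replace=False))
        prompt, fixation, onsets, end = _inquiry_onsets(
            t, stims_per_inquiry, rate, prompt_s, fixation_s)
        if free[i]:
            pos, target = None, None
        else:
            pos = int(rng.integers(stims_per_inquiry))
            target = labels[pos]
        inquiries.append(Inquiry(labels, target, pos, prompt, fixation, onsets))
        t = end + gap_s
    return StimulusSchedule(inquiries, rate, gap_s)


def build_copy_phrase_schedule(
    phrase: str,
    target_word: str,
    n_inquiries_per_letter: int = 5,
    rate: float = 5.0,
    fixation_s: float = 0.5,
    gap_s: float = 2.0,
    seed: int = 0,
) -> StimulusSchedule:
    """Build a copy-phrase (No-Preview) schedule.

    The user spells ``target_word`` (the tail of ``phrase``); each letter
    gets ``n_inquiries_per_letter`` inquiries of 10 distinct symbols that
    always include the current target letter.  Only the very first letter
    is preceded by a prompt.
    """
    if not phrase or not target_word:
        raise ValueError("phrase and target_word must be non-empty")
    if target_word.upper() not in phrase.upper():
        raise ValueError("target_word must occur within phrase")
    if n_inquiries_per_letter <= 0 or rate <= 0:
        raise ValueError("counts and rate must be positive")

    rng = np.random.default_rng(seed)
    letters = [c.upper() if c != " " else "_" for c in target_word]
    inquiries: list[Inquiry] = []
    t = 0.0
    for li, letter in enumerate(letters):
        for _ in range(n_inquiries_per_letter):
            others = [s for s in SYMBOLS if s != letter]
            labels = list(rng.choice(others, size=9, replace=False))
            pos = int(rng.integers(10))
            labels.insert(pos, letter)
            prompt_s = 1.0 if (li == 0 and not inquiries) else 0.0
            prompt, fixation, onsets, end = _inquiry_onsets(
                t, 10, rate, prompt_s, fixation_s)
            inquiries.append(Inquiry(labels, letter, pos, prompt, fixation, onsets))
            t = end + gap_s
    return StimulusSchedule(inquiries, rate, gap_s)


# ---------------------------------------------------------------------------
# Synthesis parameters
# ---------------------------------------------------------------------------

@dataclass
class ErpParams:
    """Event-related potential shape: Gaussian N200 and P300 bumps.

    Amplitudes are signed (the N200 is a negative deflection).  Each
    component has a spatial weighting over channels; the per-trial latency
    jitter is shared by both components.
    """

    n200_amp_uV: float = -2.0
    n200_latency_s: float = 0.20
    n200_width_s: float = 0.025
    p300_amp_uV: float = 5.0
    p300_latency_s: float = 0.35
    p300_width_s: float = 0.06
    latency_jitter_sd_s: float = 0.02
    n200_weights: dict = field(default_factory=lambda: {
        "O1": 1.0, "O2": 1.0, "P3": 0.6, "P4": 0.6})
    p300_weights: dict = field(default_factory=lambda: {
        "Pz": 1.0, "Cz": 0.8, "P3": 0.6, "P4": 0.6})


@dataclass
class NoiseParams:
    """Ongoing background activity: AR(1) noise plus an alpha rhythm."""

    background_sd_uV: float = 10.0
    ar_coefficient: float = 0.95
    alpha_amp_uV: float = 4.0
    alpha_freq_Hz: float = 10.0


@dataclass
class ArtifactParams:
    """Non-neural contaminants: power-line hum and eye blinks."""

    line_amp_uV: float = 5.0
    line_freq_Hz: float = 60.0
    blink_rate_per_s: float = 0.1
    blink_amp_uV: float = 100.0
    blink_duration_s: float = 0.4
    blink_weights: dict = field(default_factory=lambda: {
        "Fp1": 1.0, "Fp2": 1.0, "F3": 0.3, "Fz": 0.3, "F4": 0.3})


@dataclass
class SynthesisParams:
    fs: float = 300.0
    channel_names: list[str] = field(default_factory=lambda: list(CHANNELS_1020))
    erp: ErpParams = field(default_factory=ErpParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    artifacts: ArtifactParams = field(default_factory=ArtifactParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.noise.alpha_freq_Hz:
            raise ValueError("fs must exceed twice the alpha frequency")
        if self.fs <= 2 * self.artifacts.line_freq_Hz:
            raise ValueError("fs must exceed twice the line frequency")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        for name, val in [
            ("background_sd_uV", self.noise.background_sd_uV),
            ("alpha_amp_uV", self.noise.alpha_amp_uV),
            ("line_amp_uV", self.artifacts.line_amp_uV),
            ("blink_rate_per_s", self.artifacts.blink_rate_per_s),
            ("blink_amp_uV", self.artifacts.blink_amp_uV),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RawSession:
    """Continuous multichannel recording plus its stimulus schedule."""

    data: np.ndarray  # channels x samples, microvolts
    fs: float
    channel_names: list[str]
    schedule: StimulusSchedule
    seed_used: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be channels x samples matching channel_names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _channel_weight_vector(weights: dict, channel_names: Sequence[str]) -> np.ndarray:
    w = np.zeros(len(channel_names))
    for name, val in weights.items():
        if name in channel_names:
            w[list(channel_names).index(name)] = val
    return w


def _gaussian_bump(t: np.ndarray, onset: float, amp: float, latency: float,
                   width: float) -> np.ndarray:
    """Gaussian deflection truncated at +/- 4 widths (finite support)."""
    x = t - onset - latency
    out = np.zeros_like(t)
    # tiny slack keeps the boundary sample in or out consistently across
    # differently-originated time grids
    m = np.abs(x) <= 4 * width + 1e-9
    out[m] = amp * np.exp(-0.5 * (x[m] / width) ** 2)
    return out


def erp_template(params: SynthesisParams, window_s: float = 0.7) -> np.ndarray:
    """Noise-free single-trial ERP (channels x samples) at the native rate.

    The template is what the average target epoch converges to as noise
    vanishes and latency jitter is zero.
    """
    fs = params.fs
    t = np.arange(int(round(window_s * fs))) / fs
    e = params.erp
    n200 = _gaussian_bump(t, 0.0, e.n200_amp_uV, e.n200_latency_s, e.n200_width_s)
    p300 = _gaussian_bump(t, 0.0, e.p300_amp_uV, e.p300_latency_s, e.p300_width_s)
    wn = _channel_weight_vector(e.n200_weights, params.channel_names)
    wp = _channel_weight_vector(e.p300_weights, params.channel_names)
    return np.outer(wn, n200) + np.outer(wp, p300)


def synthesize_session(schedule: StimulusSchedule,
                       params: SynthesisParams,
                       tail_s: float = 2.5) -> RawSession:
    """Render a continuous EEG recording for a stimulus schedule.

    The signal is the sum of independent per-channel AR(1) background
    noise, an alpha sinusoid with random per-channel phase, a common-phase
    line-noise sinusoid, Poisson-timed frontal half-sine blink pulses, and
    one jittered N200+P300 complex per target stimulus.  The random draw
    order is fixed and independent of amplitude values, so scaling any
    amplitude rescales exactly that component of the output.
    """
    fs = params.fs
    duration = schedule.duration + tail_s
    if duration < 1.0:
        duration = 1.0
    n = int(np.ceil(duration * fs))
    n_ch = len(params.channel_names)
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / fs

    # background AR(1), independent per channel
    innovations = rng.normal(0.0, params.noise.background_sd_uV, size=(n_ch, n))
    data = lfilter([1.0], [1.0, -params.noise.ar_coefficient],
                   innovations, axis=1)

    # alpha rhythm, random phase per channel
    phases = rng.uniform(0, 2 * np.pi, size=n_ch)
    data += params.noise.alpha_amp_uV * np.sin(
        2 * np.pi * params.noise.alpha_freq_Hz * t[None, :] + phases[:, None])

    # line noise, one phase shared by all channels
    line_phase = rng.uniform(0, 2 * np.pi)
    data += params.artifacts.line_amp_uV * np.sin(
        2 * np.pi * params.artifacts.line_freq_Hz * t + line_phase)[None, :]

    # blinks: Poisson event times, half-sine pulse, frontal weighting
    a = params.artifacts
    n_blinks = rng.poisson(a.blink_rate_per_s * duration)
    blink_times = np.sort(rng.uniform(0, duration, size=n_blinks))
    blink_w = _channel_weight_vector(a.blink_weights, params.channel_names)
    blink_len = int(round(a.blink_duration_s * fs))
    pulse = a.blink_amp_uV * np.sin(np.pi * np.arange(blink_len) / max(blink_len, 1))
    for bt in blink_times:
        i0 = int(round(bt * fs))
        i1 = min(i0 + blink_len, n)
        if i0 < n:
            data[:, i0:i1] += np.outer(blink_w, pulse[: i1 - i0])

    # ERPs at target stimuli, with shared per-trial latency jitter
    e = params.erp
    wn = _channel_weight_vector(e.n200_weights, params.channel_names)
    wp = _channel_weight_vector(e.p300_weights, params.channel_names)
    target_onsets = [inq.stimulus_onsets[inq.target_position]
                     for inq in schedule.inquiries
                     if inq.target_position is not None]
    jitters = rng.normal(0.0, e.latency_jitter_sd_s, size=len(target_onsets))
    for onset, jit in zip(target_onsets, jitters):
        if onset >= duration:
            raise ValueError(
                f"stimulus at {onset:.3f} s extends past the allocated "
                f"{duration:.3f} s recording")
        lo = onset + jit
        bump = (_gaussian_bump(t, lo, e.n200_amp_uV, e.n200_latency_s,
                               e.n200_width_s)[None, :] * wn[:, None]
                + _gaussian_bump(t, lo, e.p300_amp_uV, e.p300_latency_s,
                                 e.p300_width_s)[None, :] * wp[:, None])
        data += bump

    return RawSession(data, fs, list(params.channel_names), schedule,
                      params.seed)


# ---------------------------------------------------------------------------
# Session serialization (CSV data + JSON triggers + JSON metadata)
# ---------------------------------------------------------------------------

def _schedule_to_dict(s: StimulusSchedule) -> dict:
    return {
        "presentation_rate": s.presentation_rate,
        "inter_inquiry_gap": s.inter_inquiry_gap,
        "inquiries": [
            {
                "stimulus_labels": inq.stimulus_labels,
                "target_label": inq.target_label,
                "target_position": inq.target_position,
                "prompt_onset": inq.prompt_onset,
                "fixation_onset": inq.fixation_onset,
                "stimulus_onsets": [round(float(x), 9) for x in inq.stimulus_onsets],
            }
            for inq in s.inquiries
        ],
    }


def _schedule_from_dict(d: dict) -> StimulusSchedule:
    inquiries = [
        Inquiry(q["stimulus_labels"], q["target_label"], q["target_position"],
                q["prompt_onset"], q["fixation_onset"],
                np.asarray(q["stimulus_onsets"]))
        for q in d["inquiries"]
    ]
    return StimulusSchedule(inquiries, d["presentation_rate"],
                            d["inter_inquiry_gap"])


def save_session(session: RawSession, outdir: str | Path) -> None:
    """Write a session as data.csv + triggers.json + session.json.

    Output bytes are stable for a fixed seed: floats are written with fixed
    formatting and JSON keys are sorted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    header = ",".join(session.channel_names)
    np.savetxt(outdir / "data.csv", session.data.T, fmt="%.6f",
               delimiter=",", header=header, comments="")

    triggers = []
    for inq in session.schedule.inquiries:
        if inq.prompt_onset is not None:
            triggers.append({"label": inq.target_label or "",
                             "type": "prompt",
                             "onset_s": round(float(inq.prompt_onset), 9)})
        triggers.append({"label": "+", "type": "fixation",
                         "onset_s": round(float(inq.fixation_onset), 9)})
        for k, (lab, onset) in enumerate(
                zip(inq.stimulus_labels, inq.stimulus_onsets)):
            kind = "target" if k == inq.target_position else "nontarget"
            triggers.append({"label": lab, "type": kind,
                             "onset_s": round(float(onset), 9)})
    (outdir / "triggers.json").write_text(
        json.dumps(triggers, indent=1, sort_keys=True) + "\n")

    meta = {
        "fs": session.fs,
        "seed": session.seed_used,
        "channel_names": session.channel_names,
        "schedule": _schedule_to_dict(session.schedule),
    }
    (outdir / "session.json").write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n")


def load_session(indir: str | Path) -> RawSession:
    indir = Path(indir)
    meta = json.loads((indir / "session.json").read_text())
    data = np.loadtxt(indir / "data.csv", delimiter=",", skiprows=1).T
    schedule = _schedule_from_dict(meta["schedule"])
    return RawSession(data, meta["fs"], meta["channel_names"], schedule,
                      meta["seed"])
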