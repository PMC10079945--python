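"""Simulated extracellular spike recordings and EEG-like binary epochs.

Action potentials are modelled as a cosine carrier under a Gaussian
envelope,

    V(t) = A cos(2*pi*(t - tau_ph)/tau1) * exp(-(2.3548*t/tau2)**2)

sampled at ``fs``.  The constant 2.3548 = 2*sqrt(2*ln 2) converts the
envelope width ``tau2`` into a full-width-at-half-maximum scale; it is a
fixed property of the waveform, not a parameter.  A recording superposes
three such template shapes at Poisson-random, non-overlapping times on a
zero baseline and adds Gaussian white noise whose standard deviation is
set by the signal-to-noise ratio

    snr = max_k max_t |template_k(t)| / sigma_noise.

Every placed spike is annotated with its peak sample index and class, so
downstream windowing needs no spike detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FWHM_CONSTANT",
    "SpikeParams",
    "SpikeTemplate",
    "SimulationConfig",
    "Annotation",
    "Recording",
    "DEFAULT_SPIKE_PARAMS",
    "DEFAULT_SNR_LEVELS",
    "make_spike_template",
    "simulate_recording",
    "simulate_binary_epochs",
    "write_binary_epochs_csv",
    "save_recording",
    "load_recording",
]

#: 2*sqrt(2*ln 2) — maps the Gaussian envelope width to FWHM units.
FWHM_CONSTANT = 2.3548

#: SNR levels swept in the reference experiment.
DEFAULT_SNR_LEVELS = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class SpikeParams:
    """Parameters of one action-potential template.

    amplitude
        Peak scale ``A`` of the carrier, in signal units (sign = polarity).
    tau1
        Oscillation period of the cosine carrier, seconds.
    tau2
        Gaussian-envelope width, seconds (FWHM scale via 2.3548).
    tau_ph
        Phase offset of the carrier, seconds.
    class_id
        Integer spike class label (1-3 in the default set).
    """

    amplitude: float
    tau1: float
    tau2: float
    tau_ph: float
    class_id: int

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be positive")


#: Three default spike shapes (~1-2 ms at 20 kHz), chosen to be visibly
#: distinct (pairwise normalized cross-correlation < 0.9): a positive
#: biphasic spike, a negative-leading triphasic spike, and a broad
#: slow-carrier spike.
DEFAULT_SPIKE_PARAMS = (
    SpikeParams(amplitude=1.0, tau1=1.0e-3, tau2=1.0e-3, tau_ph=0.0, class_id=1),
    SpikeParams(amplitude=-0.9, tau1=0.55e-3, tau2=1.3e-3, tau_ph=0.1e-3, class_id=2),
    SpikeParams(amplitude=1.1, tau1=2.2e-3, tau2=0.9e-3, tau_ph=0.55e-3, class_id=3),
)


@dataclass(frozen=True)
class SpikeTemplate:
    """A sampled spike waveform with its generating parameters."""

    params: SpikeParams
    fs: float
    waveform: np.ndarray

    def __post_init__(self) -> None:
        if self.waveform.size == 0 or not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform must be non-empty and finite")


@dataclass(frozen=True)
class Annotation:
    """Ground-truth spike event: peak sample index and class."""

    time_index: int
    class_id: int


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of one simulated recording trial.

    Defaults reproduce the reference recording conditions: 20 kHz
    sampling, 200 s duration, 3.3 Hz mean firing rate per spike class,
    ten recordings per SNR trial, and 56-sample (2.8 ms) template
    support.
    """

    fs: float = 20_000.0
    duration: float = 200.0
    firing_rate: float = 3.3
    snr: float = 1.0
    templates: tuple[SpikeParams, ...] = DEFAULT_SPIKE_PARAMS
    support_samples: int = 56
    n_recordings: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0 or self.firing_rate <= 0:
            raise ValueError("fs, duration and firing_rate must be positive")
        if not (self.snr > 0):
            raise ValueError("snr must be positive")
        ids = [p.class_id for p in self.templates]
        if len(set(ids)) != len(ids):
            raise ValueError("template class_ids must be distinct")


@dataclass(frozen=True)
class Recording:
    """One simulated trace with ground-truth annotations."""

    samples: np.ndarray
    fs: float
    annotations: tuple[Annotation, ...]
    snr: float
    seed: int

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


def make_spike_template(
    params: SpikeParams, fs: float, support: float | None = None,
    support_samples: int | None = None,
) -> SpikeTemplate:
    """Sample the cosine-times-Gaussian waveform on a centered support.

    The support is centered on t = 0 so the envelope peak lies
    mid-support.  Either ``support`` (seconds) or ``support_samples``
    may be given; the default is 56 samples (2.8 ms at 20 kHz).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if support_samples is None:
        if support is None:
            support_samples = 56
        else:
            support_samples = int(round(support * fs))
    if support_samples < 1:
        raise ValueError("support must cover at least one sample")
    n = support_samples
    # indices centered on the envelope peak; for even n the peak sits at n//2
    t = (np.arange(n) - n // 2) / fs
    carrier = np.cos(2.0 * np.pi * (t - params.tau_ph) / params.tau1)
    envelope = np.exp(-((FWHM_CONSTANT * t / params.tau2) ** 2))
    return SpikeTemplate(params=params, fs=fs, waveform=params.amplitude * carrier * envelope)


def _noise_sigma(templates: list[SpikeTemplate], snr: float) -> float:
    """Noise standard deviation implied by snr = peak amplitude / sigma."""
    peak = max(float(np.max(np.abs(t.waveform))) for t in templates)
    if not np.isfinite(snr):
        return 0.0
    return peak / snr


def simulate_recording(config: SimulationConfig, recording_index: int = 0) -> Recording:
    """Simulate one recording: Poisson spike trains, no overlaps, noise.

    Spike peak times are drawn per class as a homogeneous Poisson
    process at ``firing_rate``; a placement whose support would overlap
    an already placed spike (any class) is redrawn.  Templates are added
    to a zero baseline, then Gaussian white noise with the SNR-implied
    sigma.  ``recording_index`` decorrelates the recordings of one trial
    while keeping the whole trial a function of ``config.seed``.
    """
    rng = np.random.default_rng((config.seed, recording_index))
    n_samples = int(round(config.duration * config.fs))
    half = config.support_samples // 2
    templates = [
        make_spike_template(p, config.fs, support_samples=config.support_samples)
        for p in config.templates
    ]

    occupied = np.zeros(n_samples, dtype=bool)
    samples = np.zeros(n_samples)
    events: list[Annotation] = []
    for tmpl in templates:
        n_spikes = rng.poisson(config.firing_rate * config.duration)
        placed = 0
        attempts = 0
        max_attempts = 200 * max(n_spikes, 1)
        while placed < n_spikes:
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "could not place spikes without overlap; "
                    "firing_rate too high for the support length"
                )
            peak = int(rng.integers(half, n_samples - (config.support_samples - half)))
            start = peak - half
            stop = start + config.support_samples
            if occupied[start:stop].any():
                continue
            occupied[start:stop] = True
            samples[start:stop] += tmpl.waveform
            events.append(Annotation(time_index=peak, class_id=tmpl.params.class_id))
            placed += 1

    sigma = _noise_sigma(templates, config.snr)
    if sigma > 0:
        samples = samples + rng.normal(0.0, sigma, n_samples)
    events.sort(key=lambda a: a.time_index)
    return Recording(
        samples=samples, fs=config.fs, annotations=tuple(events),
        snr=config.snr, seed=config.seed,
    )


def simulate_binary_epochs(
    n_per_class: int, window_len: int = 178, seed: int = 0
) -> pd.DataFrame:
    """Synthetic stand-in for pre-windowed EEG seizure/non-seizure epochs.

    Produces a table in the common EEG-epoch CSV dialect: ``window_len``
    sample columns ``X1..Xn`` plus an integer label column ``y`` (1 =
    seizure, 0 = non-seizure).  Non-seizure rows are low-amplitude
    1/f-like background; seizure rows add high-amplitude rhythmic
    spike-wave bursts.  This emulates only the gross amplitude/rhythm
    contrast of real ictal EEG, not its full morphology.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    rng = np.random.default_rng(seed)

    def pink_rows(n_rows: int, scale: float) -> np.ndarray:
        # 1/f-like spectrum: shape white noise in the frequency domain
        white = rng.normal(size=(n_rows, window_len))
        spec = np.fft.rfft(white, axis=1)
        freqs = np.fft.rfftfreq(window_len)
        freqs[0] = freqs[1] if window_len > 1 else 1.0
        spec /= np.sqrt(freqs)
        rows = np.fft.irfft(spec, n=window_len, axis=1)
        rows /= np.std(rows, axis=1, keepdims=True)
        return scale * rows

    non_seizure = pink_rows(n_per_class, scale=15.0)

    t = np.arange(window_len)
    freq = rng.uniform(0.02, 0.06, size=(n_per_class, 1))  # cycles/sample
    phase = rng.uniform(0, 2 * np.pi, size=(n_per_class, 1))
    burst = np.sin(2 * np.pi * freq * t + phase)
    burst += 0.5 * np.sign(np.sin(4 * np.pi * freq * t + phase))  # sharp component
    amp = rng.uniform(120.0, 250.0, size=(n_per_class, 1))
    seizure = amp * burst + pink_rows(n_per_class, scale=20.0)

    values = np.vstack([seizure, non_seizure])
    labels = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    order = rng.permutation(values.shape[0])
    frame = pd.DataFrame(
        np.round(values[order], 4), columns=[f"X{i + 1}" for i in range(window_len)]
    )
    frame["y"] = labels[order]
    return frame


def write_binary_epochs_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write epochs in the header + feature columns + label column dialect."""
    frame.to_csv(path, index=False, lineterminator="\n")


def save_recording(rec: Recording, stem: str | Path) -> None:
    """Write samples (.txt), annotations (.annotations.csv) and a JSON sidecar."""
    stem = Path(stem)
    np.savetxt(stem.with_suffix(".txt"), rec.samples, fmt="%.17g")
    pd.DataFrame(
        {"time_index": [a.time_index for a in rec.annotations],
         "class_id": [a.class_id for a in rec.annotations]}
    ).to_csv(stem.with_suffix(".annotations.csv"), index=False)
    meta = {"fs": rec.fs, "snr": rec.snr, "seed": rec.seed}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(stem: str | Path) -> Recording:
    stem = Path(stem)
    samples = np.loadtxt(stem.with_suffix(".txt"))
    ann = pd.read_csv(stem.with_suffix(".annotations.csv"))
    meta = json.loads(stem.with_suffix(".json").read_text())
    annotations = tuple(
        Annotation(int(t), int(c)) for t, c in zip(ann["time_index"], ann["class_id"])
    )
    return Recording(
        samples=np.atleast_1d(samples), fs=float(meta["fs"]),
        annotations=annotations, snr=float(meta["snr"]), seed=int(meta["seed"]),
    )


def trial_configs(base: SimulationConfig, snr_levels=DEFAULT_SNR_LEVELS):
    """One SimulationConfig per SNR level of the sweep."""
    return [replace(base, snr=s) for s in snr_levels]
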