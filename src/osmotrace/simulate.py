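"""Synthetic nanopore trace generator with ground-truth event manifests.

Generates seeded current traces having the statistical structure the analysis
stages assume: a steady open-pore baseline set by pore geometry, electrolyte
conductivity and bias; transient rectangular current reductions drawn from a
mixture of event populations (shallow "collision" events that fail to enter
the pore and deeper "translocation" events); per-population log-normal dwell
times spanning decades; additive band-limited Gaussian noise. Every rendered
event is recorded in a manifest so detectors can be benchmarked against known
truth. Identical seed and config give bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.optimize import brentq

from .conductance import PoreGeometry, SolutionConditions, baseline_current

__all__ = [
    "EventPopulation",
    "SimulationConfig",
    "CurrentTrace",
    "GroundTruthEvent",
    "simulate_trace",
    "apply_lowpass",
]

TRANSLOCATION = "translocation"
COLLISION = "collision"


@dataclass(frozen=True)
class EventPopulation:
    """One blockade population: weight, depth distribution, dwell distribution.

    Blockades are drawn from N(blockade_mean, blockade_sd) truncated to (0, 1);
    dwell times are log-normal, 10**N(log10_dwell_mean, log10_dwell_sd)
    seconds, truncated below at 2 samples.
    """

    label: str
    weight: float
    blockade_mean: float
    blockade_sd: float
    log10_dwell_mean: float
    log10_dwell_sd: float

    def __post_init__(self):
        if not 0.0 < self.blockade_mean < 1.0:
            raise ValueError(f"blockade_mean must be in (0,1), got {self.blockade_mean}")
        if self.blockade_sd <= 0:
            raise ValueError("blockade_sd must be > 0")
        if self.weight <= 0:
            raise ValueError("population weight must be > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulated acquisition.

    The desk-scale default profile (500 kHz sampling, 50 kHz low-pass) keeps
    simulations fast; the high-bandwidth acquisition profile (4.16 MHz
    sampled, 250 kHz filtered) is available by overriding ``sampling_rate``
    and ``filter_cutoff``.
    """

    geometry: PoreGeometry
    solution: SolutionConditions
    populations: tuple[EventPopulation, ...]
    event_rate: float  # events per second (Poisson)
    duration: float  # seconds
    sampling_rate: float = 500e3  # Hz
    noise_sd: float = 0.02  # nA, before filtering
    filter_cutoff: float | None = 50e3  # Hz; None disables filtering
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be > 0")
        if self.event_rate < 0:
            raise ValueError("event_rate must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.filter_cutoff is not None and self.sampling_rate <= 2 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed 2 x filter_cutoff")
        if self.populations:
            total = sum(p.weight for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"population weights must sum to 1, got {total}")
        object.__setattr__(self, "populations", tuple(self.populations))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"] = dataclasses.asdict(self.geometry)
        d["solution"] = dataclasses.asdict(self.solution)
        d["populations"] = [dataclasses.asdict(p) for p in self.populations]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["geometry"] = PoreGeometry(**d["geometry"])
        d["solution"] = SolutionConditions(**d["solution"])
        d["populations"] = tuple(EventPopulation(**p) for p in d["populations"])
        return cls(**d)


@dataclass
class CurrentTrace:
    """Uniformly sampled ion-current series (nA) with provenance metadata."""

    samples: np.ndarray
    sampling_rate: float
    baseline_true: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class GroundTruthEvent:
    """One simulated event: half-open sample bounds, label, true depth and dwell."""

    start_index: int
    end_index: int
    label: str
    true_blockade: float
    true_dwell_s: float


def _zero_phase_bessel_sos(sampling_rate: float, cutoff: float) -> np.ndarray:
    """2nd-order mag-normalized Bessel biquad, cutoff pre-corrected so the
    forward-backward (4-pole, zero-phase) response is -3 dB at ``cutoff``."""

    def combined_power(f_design: float) -> float:
        sos = signal.bessel(2, f_design, btype="low", norm="mag", fs=sampling_rate, output="sos")
        _, h = signal.sosfreqz(sos, worN=[cutoff], fs=sampling_rate)
        return abs(h[0]) ** 2  # two passes square the magnitude

    upper = min(4.0 * cutoff, 0.499 * sampling_rate)
    f_design = brentq(lambda f: combined_power(f) - 2 ** -0.5, cutoff, upper)
    return signal.bessel(2, f_design, btype="low", norm="mag", fs=sampling_rate, output="sos")


def apply_lowpass(trace: CurrentTrace, cutoff: float) -> CurrentTrace:
    """Zero-phase low-pass filter a trace (DC gain 1, length preserved).

    Emulates the Bessel anti-alias chain of a patch-clamp acquisition as a
    forward-backward biquad cascade; being zero-phase it adds no group delay,
    so event bounds stay aligned with the unfiltered trace.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if cutoff >= trace.sampling_rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist ({trace.sampling_rate / 2} Hz)"
        )
    sos = _zero_phase_bessel_sos(trace.sampling_rate, cutoff)
    filtered = signal.sosfiltfilt(sos, trace.samples)
    meta = dict(trace.metadata)
    meta["filter_cutoff"] = float(cutoff)
    return CurrentTrace(
        samples=filtered,
        sampling_rate=trace.sampling_rate,
        baseline_true=trace.baseline_true,
        metadata=meta,
    )


def simulate_trace(config: SimulationConfig) -> tuple[CurrentTrace, list[GroundTruthEvent]]:
    """Render a seeded synthetic trace plus its ground-truth event manifest.

    Event start times follow a Poisson process of rate ``event_rate``,
    thinned so events never overlap (rejected candidates are counted in
    metadata, with a warning entry when more than half are rejected). Each
    kept event draws a population by weight, a depth dI = blockade * I0 and a
    log-normal dwell, and is rendered as a rectangular current drop. Gaussian
    noise is added, then the optional low-pass filter is applied to the whole
    trace.
    """
    rng = np.random.default_rng(config.seed)
    n = round(config.duration * config.sampling_rate)
    i0 = baseline_current(config.geometry, config.solution)
    if i0 <= 0:
        raise ValueError("baseline current must be positive; check voltage sign")

    weights = np.array([p.weight for p in config.populations]) if config.populations else None

    # Poisson arrivals via exponential gaps, in time order.
    starts = []
    if config.event_rate > 0 and config.populations:
        t = 0.0
        while True:
            t += rng.exponential(1.0 / config.event_rate)
            if t >= config.duration:
                break
            starts.append(t)

    samples = np.full(n, i0)
    manifest: list[GroundTruthEvent] = []
    n_rejected = 0
    last_end = -1
    min_samples = 2
    for t_start in starts:
        k = int(rng.choice(len(config.populations), p=weights))
        pop = config.populations[k]
        blockade = float(np.clip(rng.normal(pop.blockade_mean, pop.blockade_sd), 1e-6, 1.0))
        dwell = 10.0 ** rng.normal(pop.log10_dwell_mean, pop.log10_dwell_sd)
        start = int(round(t_start * config.sampling_rate))
        length = max(int(round(dwell * config.sampling_rate)), min_samples)
        end = start + length
        if start <= last_end or end > n:
            n_rejected += 1
            continue
        samples[start:end] -= blockade * i0
        manifest.append(
            GroundTruthEvent(
                start_index=start,
                end_index=end,
                label=pop.label,
                true_blockade=blockade,
                true_dwell_s=length / config.sampling_rate,
            )
        )
        last_end = end

    metadata = {
        "seed": config.seed,
        "config": config.to_dict(),
        "n_candidate_events": len(starts),
        "n_rejected_events": n_rejected,
    }
    if starts and n_rejected > 0.5 * len(starts):
        metadata["warning"] = (
            f"event rate too high: {n_rejected}/{len(starts)} candidate events "
            "rejected by overlap thinning"
        )

    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, n)

    trace = CurrentTrace(
        samples=samples,
        sampling_rate=config.sampling_rate,
        baseline_true=i0,
        metadata=metadata,
    )
    if config.filter_cutoff is not None:
        trace = apply_lowpass(trace, config.filter_cutoff)
    return trace, manifest
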