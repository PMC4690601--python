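"""End-to-end experiment-series pipeline: simulate -> detect -> fit -> trend.

An :class:`ExperimentSeries` describes a set of samples sharing one pore and
solution (mirroring how an oligo series is run on a single nanopore chip);
each sample either carries event populations to simulate or points at an
existing event table. :func:`run_pipeline` processes every sample through
detection and mixture fitting, extracts the most-probable blockade peaks, and
fits the translocation-peak-versus-osmylation-fraction trend across the
series. Everything derives from one global seed via stable per-stage
substreams, so a report is byte-reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .blockade import TRANSLOCATION, fit_blockade_mixture, fit_osmylation_trend
from .conductance import PoreGeometry, SolutionConditions
from .detect import DetectionParams, detect_events, estimate_baseline
from .io import read_events_tsv, write_events_tsv, write_json
from .simulate import EventPopulation, SimulationConfig, simulate_trace

__all__ = [
    "SCHEMA_VERSION",
    "SeriesSample",
    "ExperimentSeries",
    "RunConfig",
    "substream_seed",
    "run_pipeline",
]

SCHEMA_VERSION = 1
logger = logging.getLogger("osmotrace")


def substream_seed(seed: int, stage: str, sample_id: str) -> int:
    """Deterministic per-(stage, sample) substream seed below 2**31."""
    digest = hashlib.sha256(f"{seed}|{stage}|{sample_id}".encode()).hexdigest()
    return int(digest, 16) % (2 ** 31)


@dataclass(frozen=True)
class SeriesSample:
    """One sample: either populations to simulate or a pre-detected event table."""

    sample_id: str
    osmylation_fraction: float
    populations: tuple[EventPopulation, ...] | None = None
    events_path: str | None = None

    def __post_init__(self):
        if (self.populations is None) == (self.events_path is None):
            raise ValueError(
                f"sample {self.sample_id!r}: provide exactly one of populations or events_path"
            )
        if self.populations is not None:
            object.__setattr__(self, "populations", tuple(self.populations))


@dataclass(frozen=True)
class ExperimentSeries:
    """Samples sharing one pore geometry, solution, and acquisition settings."""

    samples: tuple[SeriesSample, ...]
    geometry: PoreGeometry
    solution: SolutionConditions
    event_rate: float = 40.0
    duration: float = 30.0
    sampling_rate: float = 500e3
    noise_sd: float = 0.02
    filter_cutoff: float | None = 50e3

    def __post_init__(self):
        if not self.samples:
            raise ValueError("experiment series has no samples")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids in series: {ids}")
        object.__setattr__(self, "samples", tuple(self.samples))


def series_from_dict(d: dict) -> ExperimentSeries:
    """Build an :class:`ExperimentSeries` from a plain (e.g. YAML-loaded) dict."""
    d = dict(d)
    samples = []
    for s in d.pop("samples"):
        s = dict(s)
        pops = s.pop("populations", None)
        if pops is not None:
            pops = tuple(EventPopulation(**p) for p in pops)
        samples.append(SeriesSample(populations=pops, **s))
    geometry = PoreGeometry(**d.pop("geometry"))
    solution = SolutionConditions(**d.pop("solution"))
    return ExperimentSeries(samples=tuple(samples), geometry=geometry, solution=solution, **d)


@dataclass
class RunConfig:
    """Pipeline run parameters: global seed, output dir, per-stage settings."""

    seed: int = 0
    outdir: str | None = None
    n_components: int | str = "auto"
    detection: DetectionParams = field(default_factory=DetectionParams)


def _process_sample(sample, series, config):
    if sample.events_path is not None:
        df = read_events_tsv(sample.events_path)
        blockades = df["frac_blockade"].to_numpy()
        dwells = df["dwell_s"].to_numpy()
        logger.info("sample %s: loaded %d events from %s", sample.sample_id, len(df), sample.events_path)
        sample_report = {"n_events": int(len(df)), "source": "file"}
        events = None
    else:
        sim = SimulationConfig(
            geometry=series.geometry,
            solution=series.solution,
            populations=sample.populations,
            event_rate=series.event_rate,
            duration=series.duration,
            sampling_rate=series.sampling_rate,
            noise_sd=series.noise_sd,
            filter_cutoff=series.filter_cutoff,
            seed=substream_seed(config.seed, "simulate", sample.sample_id),
        )
        trace, manifest = simulate_trace(sim)
        baseline = estimate_baseline(trace)
        detection = detect_events(trace, baseline, config.detection)
        events = detection.events
        blockades = [e.frac_blockade for e in events]
        dwells = [e.dwell_s for e in events]
        logger.info(
            "sample %s: simulated %d true events, detected %d",
            sample.sample_id,
            len(manifest),
            len(events),
        )
        sample_report = {
            "n_events": len(events),
            "n_true_events": len(manifest),
            "source": "simulated",
            "detection": detection.report(),
        }

    fit = fit_blockade_mixture(
        blockades,
        n_components=config.n_components,
        seed=substream_seed(config.seed, "fit", sample.sample_id),
    )
    peaks = fit.most_probable_blockade()
    sample_report.update(
        {
            "sample_id": sample.sample_id,
            "osmylation_fraction": sample.osmylation_fraction,
            "n_components": fit.n_components,
            "bic": {str(k): v for k, v in fit.bic.items()},
            "peaks": {c.label: c.mean for c in fit.components},
            "component_sds": {c.label: c.sd for c in fit.components},
            "component_weights": {c.label: c.weight for c in fit.components},
            "most_probable_blockade": list(peaks),
        }
    )
    translocation_peak = fit.component(TRANSLOCATION).mean
    return sample_report, translocation_peak, events, dwells


def run_pipeline(series: ExperimentSeries, config: RunConfig | None = None) -> dict:
    """Run the full series workflow and return (and optionally write) a report.

    Per sample: simulate (unless an event table is supplied), detect events,
    fit the blockade mixture, extract most-probable peaks; then fit the
    translocation-peak trend across the series. With ``config.outdir`` set,
    writes ``report.json`` and per-sample ``<id>.events.tsv``. Identical seed
    and series give byte-identical reports.
    """
    if config is None:
        config = RunConfig()
    logger.info(
        "pipeline: %d samples, seed %d, pore %.3g/%.3g nm",
        len(series.samples),
        config.seed,
        series.geometry.diameter,
        series.geometry.effective_thickness,
    )
    sample_reports = []
    trend_points = []
    per_sample_events = {}
    for sample in series.samples:
        try:
            report, trans_peak, events, _ = _process_sample(sample, series, config)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at sample {sample.sample_id!r}: {exc}"
            ) from exc
        sample_reports.append(report)
        trend_points.append((sample.osmylation_fraction, trans_peak))
        if events is not None:
            per_sample_events[sample.sample_id] = events

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "n_samples": len(series.samples),
        "geometry": {
            "diameter_nm": series.geometry.diameter,
            "effective_thickness_nm": series.geometry.effective_thickness,
        },
        "samples": sample_reports,
    }
    if len(trend_points) >= 2:
        trend = fit_osmylation_trend(trend_points)
        report["trend"] = {
            "slope": trend.slope,
            "intercept": trend.intercept,
            "slope_stderr": trend.slope_stderr,
            "points": [[f, p] for f, p in trend.points],
        }

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample_id, events in per_sample_events.items():
            write_events_tsv(events, series.sampling_rate, outdir / f"{sample_id}.events.tsv")
        write_json(report, outdir / "report.json")
        logger.info("pipeline: report written to %s", outdir / "report.json")
    return report
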