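"""Readers and writers for the pipeline's file formats.

FASTA for sequences (via Biopython), HDF5 or two-column CSV for current
traces, TSV for event tables and ground-truth manifests, JSON for fit results
and reports, YAML for simulation configs. All numeric text output is written
at 9 significant digits and round-trips losslessly (write -> read -> write is
byte-identical).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .sequences import NucleotideSequence
from .simulate import CurrentTrace, GroundTruthEvent, SimulationConfig

__all__ = [
    "read_fasta",
    "write_trace",
    "read_trace",
    "write_events_tsv",
    "read_events_tsv",
    "write_manifest_tsv",
    "read_manifest_tsv",
    "write_json",
    "read_json",
    "load_simulation_config",
]

_EVENT_COLUMNS = ["start_s", "dwell_s", "delta_I_nA", "frac_blockade"]
_MANIFEST_COLUMNS = ["start_index", "end_index", "label", "true_blockade", "true_dwell_s"]


def _g9(v: float) -> str:
    return format(float(v), ".9g")


def read_fasta(path) -> list[NucleotideSequence]:
    """Read and validate a multi-record FASTA file.

    Residues are case-folded; anything outside {A, C, G, T} raises with the
    record id and 1-based position. Duplicate ids are rejected. A file whose
    first non-blank line is not a header raises with the line number.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path.name}: malformed FASTA, line {lineno} is not a header"
                    )
                break
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path.name}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(NucleotideSequence(rec.id, str(rec.seq)))
    return records


def write_trace(trace: CurrentTrace, path) -> None:
    """Write a trace as HDF5 (.h5/.hdf5) or two-column CSV (time_s, current_nA)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("current_nA", data=trace.samples)
            f.attrs["sampling_rate"] = trace.sampling_rate
            if trace.baseline_true is not None:
                f.attrs["baseline_true"] = trace.baseline_true
            f.attrs["metadata_json"] = json.dumps(trace.metadata, sort_keys=True)
    elif path.suffix == ".csv":
        t = np.arange(trace.n_samples) / trace.sampling_rate
        with open(path, "w") as fh:
            fh.write("time_s\tcurrent_nA\n")
            for ti, ci in zip(t, trace.samples):
                fh.write(f"{_g9(ti)}\t{_g9(ci)}\n")
    else:
        raise ValueError(f"unsupported trace format {path.suffix!r} (use .h5 or .csv)")


def read_trace(path, sampling_rate: float | None = None) -> CurrentTrace:
    """Read a trace written by :func:`write_trace`.

    For CSV the sampling rate is inferred from the time column unless given.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            samples = f["current_nA"][:]
            sr = float(f.attrs["sampling_rate"])
            baseline = float(f.attrs["baseline_true"]) if "baseline_true" in f.attrs else None
            meta = json.loads(f.attrs.get("metadata_json", "{}"))
        return CurrentTrace(samples, sr, baseline_true=baseline, metadata=meta)
    if path.suffix == ".csv":
        df = pd.read_csv(path, sep="\t")
        if sampling_rate is None:
            dt = np.diff(df["time_s"].to_numpy()[:2])
            if dt.size == 0 or dt[0] <= 0:
                raise ValueError(f"{path.name}: cannot infer sampling rate")
            sampling_rate = 1.0 / dt[0]
        return CurrentTrace(df["current_nA"].to_numpy(), sampling_rate)
    raise ValueError(f"unsupported trace format {path.suffix!r}")


def _write_tsv(path, columns, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_events_tsv(events, sampling_rate: float, path) -> None:
    """Write detected events as TSV (start_s, dwell_s, delta_I_nA, frac_blockade)."""
    rows = (
        [
            _g9(e.start_index / sampling_rate),
            _g9(e.dwell_s),
            _g9(e.depth_nA),
            _g9(e.frac_blockade),
        ]
        for e in events
    )
    _write_tsv(path, _EVENT_COLUMNS, rows)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing event columns {missing}")
    return df


def rewrite_events_tsv(df: pd.DataFrame, path) -> None:
    """Write an events DataFrame back to TSV with the canonical formatting."""
    rows = (
        [_g9(r.start_s), _g9(r.dwell_s), _g9(r.delta_I_nA), _g9(r.frac_blockade)]
        for r in df.itertuples()
    )
    _write_tsv(path, _EVENT_COLUMNS, rows)


def write_manifest_tsv(manifest, path) -> None:
    """Write a ground-truth manifest as TSV."""
    rows = (
        [str(e.start_index), str(e.end_index), e.label, _g9(e.true_blockade), _g9(e.true_dwell_s)]
        for e in manifest
    )
    _write_tsv(path, _MANIFEST_COLUMNS, rows)


def read_manifest_tsv(path) -> list[GroundTruthEvent]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing manifest columns {missing}")
    return [
        GroundTruthEvent(
            start_index=int(r.start_index),
            end_index=int(r.end_index),
            label=str(r.label),
            true_blockade=float(r.true_blockade),
            true_dwell_s=float(r.true_dwell_s),
        )
        for r in df.itertuples()
    ]


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_simulation_config(path) -> SimulationConfig:
    """Load a :class:`SimulationConfig` from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SimulationConfig.from_dict(d)
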