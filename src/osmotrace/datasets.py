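"""Built-in study data: oligonucleotide panel, 202-bp amplicon, pore presets.

These are the published inputs of the osmylation nanopore study this package
analyses: four synthetic deoxyoligonucleotides (ODN1-ODN4) characterised at
several osmylation levels by capillary electrophoresis (the R(312/272)
absorbance ratio) and by nanopore translocation (most-probable fractional
blockades), plus the 202-bp PCR amplicon used for the duplex experiments.
They parameterize calibrations, simulations and benchmarks; no raw current
traces exist, so trace-level data are always simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conductance import PoreGeometry, SolutionConditions
from .sequences import PROTOCOL_A, PROTOCOL_B, NucleotideSequence, OsmylationProtocol
from .simulate import COLLISION, TRANSLOCATION, EventPopulation

__all__ = [
    "OligoRecord",
    "OLIGO_PANEL",
    "AMPLICON_202BP",
    "r_calibration_points",
    "SSDNA_PORE_SMALL",
    "SSDNA_PORE_THICK",
    "DSDNA_PORE",
    "UREA_BUFFER_300MV",
    "UREA_BUFFER_200MV",
    "KCL_BUFFER_300MV",
    "series_80mer",
    "series_20mer",
]


@dataclass(frozen=True)
class OligoRecord:
    """One panel entry: sequence, protocol, CE ratio and blockade peak(s)."""

    sample_id: str
    sequence: NucleotideSequence
    protocol: OsmylationProtocol | None  # None = unreacted
    r_ratio: float  # CE peak-area ratio at 312 nm / 272 nm
    osbipy_count: int  # reported number of osbipy-modified residues
    collision_peak: float | None  # most-probable dI/I0, collision population
    translocation_peak: float  # most-probable dI/I0, translocation population

    @property
    def osmylation_fraction(self) -> float:
        return self.osbipy_count / len(self.sequence)


_ODN1 = "CGCGAAGTGGAGCAGCCTGG"
_ODN2 = "AGGTGAGATGACAGGAGATC"
_ODN3 = "AGAGTTTGATCCTGGCTCAG"
_ODN4 = (
    "CTCAGAGTTCCAAGGTGAGTGAGTGAGTGGTCCTTCCTTCCTTCCTTCC"
    "GGTGAGTGAGTGAGTGGACGGTAAGCCATTT"
)

#: The four study oligos at each characterised osmylation level.
OLIGO_PANEL: tuple[OligoRecord, ...] = (
    OligoRecord("ODN1", NucleotideSequence("ODN1", _ODN1), None, 0.03, 0, None, 0.583),
    OligoRecord("ODN1-R1", NucleotideSequence("ODN1", _ODN1), PROTOCOL_A, 0.24, 2, None, 0.582),
    OligoRecord("ODN2-R1", NucleotideSequence("ODN2", _ODN2), PROTOCOL_A, 0.32, 3, None, 0.624),
    OligoRecord("ODN3-R1", NucleotideSequence("ODN3", _ODN3), PROTOCOL_A, 0.64, 6, 0.60, 0.667),
    OligoRecord("ODN3-R2", NucleotideSequence("ODN3", _ODN3), PROTOCOL_B, 1.05, 10, 0.58, 0.69),
    OligoRecord("ODN4", NucleotideSequence("ODN4", _ODN4), None, 0.03, 0, 0.42, 0.57),
    OligoRecord("ODN4-R1", NucleotideSequence("ODN4", _ODN4), PROTOCOL_A, 0.60, 24, 0.43, 0.63),
    OligoRecord("ODN4-R2", NucleotideSequence("ODN4", _ODN4), PROTOCOL_B, 1.18, 41, 0.46, 0.74),
)

#: One strand of the 202-bp PCR amplicon used for the duplex experiments
#: (primer regions at either end).
AMPLICON_202BP = NucleotideSequence(
    "amplicon-202bp",
    "TTGGTAGCAAAAACGAACTGGGT"
    "TCAATCTTGGCTCTGCCACCCATTCCTGGACAAAATACTTAACTCTCTCC"
    "ATCTTCCAAATGTGACCTACACCTTACAGGACTGCCAGGAGAATTAAGGA"
    "AGCACATACACAGTGCCTGACACACAAGTGAGTAAACACCTTAAACTATG"
    "TTTAGCCA"
    "CAGAACCAGAGTGGTTGGAGG",
)


def r_calibration_points() -> list[tuple[float, float]]:
    """(osmylation fraction, R(312/272)) pairs from the oligo panel."""
    return [(rec.osmylation_fraction, rec.r_ratio) for rec in OLIGO_PANEL]


# Pore geometries used in the study (diameter nm / effective thickness nm).
SSDNA_PORE_SMALL = PoreGeometry(diameter=1.6, effective_thickness=3.0)
SSDNA_PORE_THICK = PoreGeometry(diameter=1.6, effective_thickness=10.0)
DSDNA_PORE = PoreGeometry(diameter=4.4, effective_thickness=10.0)

# Electrolyte conductivity is not part of the published record; 0.4 M KCl is
# ~4.6 S/m at room temperature, and the 4.8 M urea of the ssDNA buffer raises
# viscosity enough to bring that down to roughly 3 S/m.
UREA_BUFFER_300MV = SolutionConditions(conductivity=3.0, voltage_mV=300.0)
UREA_BUFFER_200MV = SolutionConditions(conductivity=3.0, voltage_mV=200.0)
KCL_BUFFER_300MV = SolutionConditions(conductivity=4.6, voltage_mV=300.0)

# Dwell-time log-normal parameters emulating the published dwell histograms
# at desk scale: most-probable dwell ~0.2 ms, spread ~half a decade.
_LOG10_DWELL_MEAN = -3.7
_LOG10_DWELL_SD = 0.25
_COLLISION_WEIGHT = 0.3
_COLLISION_PEAK_80MER = 0.44  # shared collision peak of the 80-mer histograms
_COLLISION_SD = 0.04
_TRANSLOCATION_SD = 0.03


def _populations(translocation_peak: float, collision_peak: float | None):
    pops = []
    if collision_peak is not None:
        pops.append(
            EventPopulation(
                label=COLLISION,
                weight=_COLLISION_WEIGHT,
                blockade_mean=collision_peak,
                blockade_sd=_COLLISION_SD,
                log10_dwell_mean=_LOG10_DWELL_MEAN,
                log10_dwell_sd=_LOG10_DWELL_SD + 0.05,
            )
        )
    pops.append(
        EventPopulation(
            label=TRANSLOCATION,
            weight=1.0 - (_COLLISION_WEIGHT if collision_peak is not None else 0.0),
            blockade_mean=translocation_peak,
            blockade_sd=_TRANSLOCATION_SD,
            log10_dwell_mean=_LOG10_DWELL_MEAN,
            log10_dwell_sd=_LOG10_DWELL_SD,
        )
    )
    return tuple(pops)


def series_80mer():
    """The 80-mer experiment series: (sample_id, osmylation fraction, populations).

    Unreacted, T-osmylated (24/80) and T+C-osmylated (41/80) ODN4, with the
    panel's translocation peaks (0.57, 0.63, 0.74) and the shared collision
    population at dI/I0 = 0.44.
    """
    out = []
    for rec in OLIGO_PANEL:
        if rec.sample_id.startswith("ODN4"):
            out.append(
                (
                    rec.sample_id,
                    rec.osmylation_fraction,
                    _populations(rec.translocation_peak, _COLLISION_PEAK_80MER),
                )
            )
    return out


def series_20mer():
    """The 20-mer experiment series with per-sample collision peaks where reported."""
    out = []
    for rec in OLIGO_PANEL:
        if rec.sample_id.startswith(("ODN1", "ODN2", "ODN3")):
            out.append(
                (
                    rec.sample_id,
                    rec.osmylation_fraction,
                    _populations(rec.translocation_peak, rec.collision_peak),
                )
            )
    return out
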