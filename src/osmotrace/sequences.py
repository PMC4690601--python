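"""Sequence-level osmylation accounting.

Osmium tetroxide 2,2'-bipyridine (osbipy) adds across the C5-C6 double bond of
pyrimidines: thymine reacts readily, cytosine only under prolonged conditions,
and purines are untouched. This module counts osmylatable residues under the
two labeling protocols (A: T only; B: T and C), builds per-position
modification profiles (deterministic or Bernoulli-stochastic), summarises
partial duplex osmylation, and calibrates the capillary-electrophoresis
absorbance ratio R(312 nm / 272 nm) against osmylation fraction.

Positions are 1-based in every user-facing report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "NucleotideSequence",
    "OsmylationProtocol",
    "OsmylationProfile",
    "PROTOCOL_A",
    "PROTOCOL_B",
    "DUPLEX_PARTIAL",
    "count_osmylatable",
    "label_positions",
    "osmylation_fraction",
    "DuplexOsmylationSummary",
    "duplex_osmylation_summary",
    "RCalibration",
    "RCalibrationResults",
    "fit_r_calibration",
]

_VALID_BASES = frozenset("ACGT")


class SequenceValidationError(ValueError):
    """A residue outside {A, C, G, T} was found; carries its 1-based position."""

    def __init__(self, identifier: str, position: int, residue: str):
        self.identifier = identifier
        self.position = position
        self.residue = residue
        super().__init__(
            f"sequence {identifier!r}: invalid residue {residue!r} at position "
            f"{position} (1-based); only A, C, G, T are allowed"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """A validated DNA sequence.

    Whitespace is stripped and case folded on construction; any residue
    outside {A, C, G, T} raises :class:`SequenceValidationError` naming the
    offending 1-based position (U is rejected: DNA only).
    """

    identifier: str
    bases: str

    def __post_init__(self):
        cleaned = "".join(self.bases.split()).upper()
        for i, b in enumerate(cleaned, start=1):
            if b not in _VALID_BASES:
                raise SequenceValidationError(self.identifier, i, b)
        if not cleaned:
            raise ValueError(f"sequence {self.identifier!r} is empty")
        object.__setattr__(self, "bases", cleaned)

    def __len__(self) -> int:
        return len(self.bases)

    def count(self, base: str) -> int:
        return self.bases.count(base.upper())

    @property
    def at_fraction(self) -> float:
        """Fraction of residues that are A or T (AT-pair fraction of the duplex)."""
        return (self.count("A") + self.count("T")) / len(self)


@dataclass(frozen=True)
class OsmylationProtocol:
    """Labeling protocol: which pyrimidines are targeted and how efficiently.

    ``t_efficiency`` / ``c_efficiency`` are per-base reaction probabilities in
    [0, 1] used by the stochastic labeling mode; the deterministic mode labels
    every targeted base (every T when t_efficiency > 0, every C when
    c_efficiency > 0), which is the convention of the study's reported
    per-oligo modification counts.
    """

    name: str
    t_efficiency: float = 1.0
    c_efficiency: float = 0.0

    def __post_init__(self):
        for attr in ("t_efficiency", "c_efficiency"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")

    @property
    def targets(self) -> str:
        """Bases targeted by this protocol ('T', 'TC' or '')."""
        t = "T" if self.t_efficiency > 0 else ""
        c = "C" if self.c_efficiency > 0 else ""
        return t + c


#: Protocol A — labels all T residues (deterministic mode).
PROTOCOL_A = OsmylationProtocol("A", t_efficiency=1.0, c_efficiency=0.0)
#: Protocol B — labels all T and C residues.
PROTOCOL_B = OsmylationProtocol("B", t_efficiency=1.0, c_efficiency=1.0)
#: Partial duplex labeling — about half of the T residues react.
DUPLEX_PARTIAL = OsmylationProtocol("duplex-partial", t_efficiency=0.5, c_efficiency=0.0)


def count_osmylatable(sequence: NucleotideSequence, protocol: OsmylationProtocol) -> int:
    """Number of osmylatable residues under ``protocol`` (deterministic mode).

    Counts every T when the protocol targets T, plus every C when it targets
    C. For the study oligos this reproduces the reported per-oligo osbipy
    counts exactly.
    """
    return sum(sequence.count(b) for b in protocol.targets)


@dataclass(frozen=True)
class OsmylationProfile:
    """A sequence plus the set of osbipy-modified positions (1-based)."""

    sequence: NucleotideSequence
    protocol: OsmylationProtocol
    modified_positions: frozenset[int]

    def __post_init__(self):
        targets = set(self.protocol.targets)
        for pos in self.modified_positions:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modified position {pos} outside sequence of length {len(self.sequence)}")
            base = self.sequence.bases[pos - 1]
            if base not in targets:
                raise ValueError(
                    f"position {pos} carries {base!r}, not a target of protocol {self.protocol.name!r}"
                )

    @property
    def osbipy_count(self) -> int:
        return len(self.modified_positions)

    @property
    def osmylation_fraction(self) -> float:
        return self.osbipy_count / len(self.sequence)


def label_positions(
    sequence: NucleotideSequence,
    protocol: OsmylationProtocol,
    rng: np.random.Generator | None = None,
) -> OsmylationProfile:
    """Build an :class:`OsmylationProfile` for ``sequence`` under ``protocol``.

    With ``rng=None`` labeling is deterministic: every targeted base is
    modified. With an ``rng``, each T is modified with probability
    ``t_efficiency`` and each C with ``c_efficiency`` (independent Bernoulli
    draws in sequence order), which models incomplete reactions such as
    partial duplex osmylation.
    """
    positions = []
    for i, base in enumerate(sequence.bases, start=1):
        if base == "T" and protocol.t_efficiency > 0:
            p = protocol.t_efficiency
        elif base == "C" and protocol.c_efficiency > 0:
            p = protocol.c_efficiency
        else:
            continue
        if rng is None or rng.random() < p:
            positions.append(i)
    return OsmylationProfile(sequence, protocol, frozenset(positions))


def osmylation_fraction(profile: OsmylationProfile) -> float:
    """Fraction of residues carrying an osbipy adduct (count / length)."""
    return profile.osmylation_fraction


@dataclass(frozen=True)
class DuplexOsmylationSummary:
    """Expected labeling of a duplex under partial T-osmylation.

    Each A:T pair contributes exactly one osmylatable T across the two
    strands, so the AT-pair fraction of either strand times the per-T
    reaction efficiency gives the fraction of base pairs carrying a tag.
    """

    length_bp: int
    at_pair_fraction: float
    t_efficiency: float

    @property
    def strand_osmylation_percent(self) -> float:
        return self.at_pair_fraction * self.t_efficiency * 100.0

    @property
    def expected_osmylated_bp(self) -> float:
        return self.length_bp * self.at_pair_fraction * self.t_efficiency

    @property
    def expected_osmylated_bp_rounded(self) -> int:
        return round(self.expected_osmylated_bp)


def duplex_osmylation_summary(
    sequence: NucleotideSequence, t_efficiency: float
) -> DuplexOsmylationSummary:
    """Summarise partial duplex osmylation for one strand of a duplex.

    ``t_efficiency`` is the fraction of T bases that react (0-1). The summary
    is linear in ``t_efficiency``; at 1 it returns the full AT-pair count.
    """
    if not 0.0 <= t_efficiency <= 1.0:
        raise ValueError(f"t_efficiency must be in [0, 1], got {t_efficiency}")
    return DuplexOsmylationSummary(
        length_bp=len(sequence),
        at_pair_fraction=sequence.at_fraction,
        t_efficiency=t_efficiency,
    )


class RCalibration:
    """Linear calibration of the CE absorbance ratio R(312/272) vs osmylation fraction.

    Unmodified DNA does not absorb at 312 nm, so R grows essentially linearly
    with the fraction of osmylated residues; an ordinary least-squares line
    turns measured R values into an osmylation-extent proxy.

    Parameters
    ----------
    points : sequence of (osmylation_fraction, R)
        At least two points with distinct fractions.
    """

    def __init__(self, points):
        pts = [(float(f), float(r)) for f, r in points]
        if len(pts) < 2:
            raise ValueError("calibration needs at least 2 points")
        fracs = {f for f, _ in pts}
        if len(fracs) < 2:
            raise ValueError("degenerate design: all osmylation fractions identical")
        self.points = pts

    def fit(self) -> "RCalibrationResults":
        x = np.array([f for f, _ in self.points])
        y = np.array([r for _, r in self.points])
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        dof = max(len(x) - 2, 1)
        residual_sd = math.sqrt(float(res.ssr) / dof)
        return RCalibrationResults(
            slope=float(slope),
            intercept=float(intercept),
            residual_sd=residual_sd,
            points=self.points,
            _ols=res,
        )


@dataclass
class RCalibrationResults:
    slope: float
    intercept: float
    residual_sd: float
    points: list
    _ols: object = field(default=None, repr=False)

    def predict_R(self, fraction: float) -> float:
        """Predicted R(312/272) at a given osmylation fraction."""
        return self.intercept + self.slope * float(fraction)

    def summary(self) -> str:
        lines = [
            "R(312/272) calibration (ordinary least squares)",
            f"  n points     : {len(self.points)}",
            f"  slope        : {self.slope:.4f}  R-units per osmylation fraction",
            f"  intercept    : {self.intercept:.4f}  R-units",
            f"  residual sd  : {self.residual_sd:.4f}  R-units",
        ]
        return "\n".join(lines)


def fit_r_calibration(points) -> RCalibrationResults:
    """OLS line through (osmylation_fraction, R) points. See :class:`RCalibration`."""
    return RCalibration(points).fit()
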