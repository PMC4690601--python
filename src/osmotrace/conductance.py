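"""Geometric nanopore conductance model.

The pore is modeled as an electrolyte-filled cylinder (diameter d, effective
thickness L) in series with the access resistance of the hemispherical
solution regions at its mouths:

    G_open = sigma * [ 4 L / (pi d^2) + 1/d ]^-1

with d and L in nm and sigma in S/m, giving G in nS. A molecule residing in
the pore is a coaxial cylinder of effective diameter d_mol; it reduces the
open cross-section to an annulus, modeled by substituting the annular
effective diameter d_b, d_b^2 = d^2 - d_mol^2, for d in both terms. The
fractional blockade

    dI/I0 = 1 - G_blocked / G_open

is independent of sigma and strictly increasing in d_mol, so it can be
inverted by a bracketed 1-D root search to size the molecule from a measured
blockade. A no-access-resistance variant (``model="simple"``, pure cylinder)
is provided for comparison; in the L -> infinity limit both reduce to the
area ratio d_mol^2 / d^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "PoreGeometry",
    "SolutionConditions",
    "MoleculeModel",
    "open_pore_conductance",
    "blocked_pore_conductance",
    "fractional_blockade",
    "invert_effective_diameter",
    "baseline_current",
]

_MODELS = ("access", "simple")


@dataclass(frozen=True)
class PoreGeometry:
    """Pore diameter and effective thickness, both in nm."""

    diameter: float
    effective_thickness: float

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError(f"pore diameter must be > 0 nm, got {self.diameter}")
        if self.effective_thickness <= 0:
            raise ValueError(
                f"effective thickness must be > 0 nm, got {self.effective_thickness}"
            )


@dataclass(frozen=True)
class SolutionConditions:
    """Electrolyte conductivity (S/m) and applied bias (mV)."""

    conductivity: float
    voltage_mV: float

    def __post_init__(self):
        if self.conductivity <= 0:
            raise ValueError(f"conductivity must be > 0 S/m, got {self.conductivity}")


@dataclass(frozen=True)
class MoleculeModel:
    """Equivalent cylinder whose presence reproduces an observed blockade."""

    effective_diameter: float

    def __post_init__(self):
        if self.effective_diameter < 0:
            raise ValueError(
                f"effective diameter must be >= 0 nm, got {self.effective_diameter}"
            )


def _conductance(d: float, L: float, sigma: float, model: str) -> float:
    if model == "access":
        return sigma / (4.0 * L / (math.pi * d * d) + 1.0 / d)
    return sigma * math.pi * d * d / (4.0 * L)


def open_pore_conductance(
    geom: PoreGeometry, sol: SolutionConditions, model: str = "access"
) -> float:
    """Open-pore conductance in nS (d, L in nm; sigma in S/m).

    Strictly increasing in diameter, strictly decreasing in thickness; in the
    L -> 0 limit of the access model, G -> sigma * d.
    """
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    return _conductance(geom.diameter, geom.effective_thickness, sol.conductivity, model)


def blocked_pore_conductance(
    geom: PoreGeometry, mol: MoleculeModel, sol: SolutionConditions, model: str = "access"
) -> float:
    """Conductance (nS) with a coaxial cylindrical molecule inside the pore."""
    d, dm = geom.diameter, mol.effective_diameter
    if dm >= d:
        raise ValueError(f"molecule diameter {dm} nm must be < pore diameter {d} nm")
    db = math.sqrt(d * d - dm * dm)
    return _conductance(db, geom.effective_thickness, sol.conductivity, model)


def fractional_blockade(
    geom: PoreGeometry, mol: MoleculeModel | float, model: str = "access"
) -> float:
    """Fractional current blockade dI/I0 for a molecule in the pore.

    Independent of conductivity (it cancels); 0 at d_mol = 0, -> 1 as d_mol
    approaches the pore diameter, strictly increasing in between.
    """
    if not isinstance(mol, MoleculeModel):
        mol = MoleculeModel(float(mol))
    sol = SolutionConditions(conductivity=1.0, voltage_mV=0.0)
    g0 = open_pore_conductance(geom, sol, model)
    gb = blocked_pore_conductance(geom, mol, sol, model)
    return 1.0 - gb / g0


def invert_effective_diameter(
    geom: PoreGeometry, blockade: float, model: str = "access", xtol: float = 1e-12
) -> MoleculeModel:
    """Effective molecular diameter (nm) reproducing a measured dI/I0.

    Solves fractional_blockade(geom, d_mol) = blockade by a bracketed root
    search on [0, d); the blockade is strictly monotone in d_mol so the root
    is unique. Raises if the blockade lies outside the attainable range,
    reporting the attainable supremum.
    """
    if blockade == 0:
        return MoleculeModel(0.0)
    d = geom.diameter
    upper = d * (1.0 - 1e-9)
    sup = fractional_blockade(geom, MoleculeModel(upper), model)
    if not 0.0 <= blockade < sup:
        raise ValueError(
            f"blockade {blockade} outside attainable range [0, {sup:.9f}) for this pore"
        )
    root = brentq(
        lambda dm: fractional_blockade(geom, MoleculeModel(dm), model) - blockade,
        0.0,
        upper,
        xtol=xtol,
    )
    return MoleculeModel(float(root))


def baseline_current(geom: PoreGeometry, sol: SolutionConditions, model: str = "access") -> float:
    """Open-pore current I0 in nA at the applied bias (G in nS times V in volts)."""
    return open_pore_conductance(geom, sol, model) * sol.voltage_mV * 1e-3
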