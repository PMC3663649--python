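"""Equilibrium binding solvers shared by every fitting stage.

All concentrations are carried in mol/L; unit conversion happens only at
I/O boundaries (:mod:`nucbind.units`).  Two schemes are supported:

* 1:1 binding with ligand depletion (the substrate of the fast-exchange
  chemical-shift-perturbation isotherm), solved in closed form from the
  quadratic mass balance.
* Two equivalent, independent sites per receptor (a nucleosome presents two
  symmetric H3 tails to a PWWP-type reader), solved for the free-ligand
  concentration and expanded into a binomial species distribution over the
  0/1/2-bound states.

The avidity arithmetic for bipartite binding (effective concentration,
fold enhancement, complex lifetime) lives here as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumParams",
    "MixtureState",
    "solve_1to1_complex",
    "solve_two_site",
    "effective_concentration",
    "fold_enhancement",
    "complex_lifetime",
]


def _require_positive(name: str, value: float) -> None:
    if not np.all(np.asarray(value) > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not np.all(np.asarray(value) >= 0):
        raise ValueError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class EquilibriumParams:
    """Microscopic binding parameters of a receptor.

    Parameters
    ----------
    kd_micro : float
        Microscopic (per-site) dissociation constant, mol/L.
    n_sites : int
        Number of equivalent ligand-binding sites per receptor (1 or 2).
    """

    kd_micro: float
    n_sites: int = 1

    def __post_init__(self) -> None:
        _require_positive("kd_micro", self.kd_micro)
        if self.n_sites not in (1, 2):
            raise ValueError(f"n_sites must be 1 or 2, got {self.n_sites}")


@dataclass(frozen=True)
class MixtureState:
    """Equilibrium composition of one titration point.

    ``species_fractions`` is the (f0, f1, f2) distribution of receptors
    carrying 0, 1 or 2 ligands; for a single-site receptor f2 is zero.
    """

    receptor_total: float
    ligand_total: float
    free_ligand: float
    site_occupancy: float
    species_fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not (-1e-15 <= self.free_ligand <= self.ligand_total * (1 + 1e-9) + 1e-30):
            raise ValueError("free_ligand outside [0, ligand_total]")
        if not (0.0 <= self.site_occupancy <= 1.0 + 1e-12):
            raise ValueError("site_occupancy outside [0, 1]")
        if abs(sum(self.species_fractions) - 1.0) > 1e-12:
            raise ValueError("species fractions must sum to 1")


def solve_1to1_complex(receptor_total, ligand_total, kd):
    """Complex concentration for 1:1 binding with ligand depletion.

    Solves ``[PL]^2 - (P0 + L0 + KD)[PL] + P0*L0 = 0`` for the physically
    admissible root.  Vectorised over ``ligand_total``.

    Parameters are in mol/L (any single consistent unit works since the
    equation is homogeneous of degree one in concentration).
    """
    p0 = np.asarray(receptor_total, dtype=float)
    l0 = np.asarray(ligand_total, dtype=float)
    _require_nonnegative("receptor_total", p0)
    _require_nonnegative("ligand_total", l0)
    _require_positive("kd", kd)
    b = p0 + l0 + kd
    disc = b * b - 4.0 * p0 * l0
    # product/sum form of the smaller quadratic root: numerically stable in
    # the stoichiometric limit kd << max(P0, L0) where b - sqrt(disc) cancels
    pl = 2.0 * p0 * l0 / (b + np.sqrt(np.maximum(disc, 0.0)))
    return pl if pl.ndim else float(pl)


def solve_two_site(receptor_total: float, ligand_total: float, kd_micro: float) -> MixtureState:
    """Equilibrium of a receptor with two equivalent, independent sites.

    Free ligand ``x`` solves the mass balance
    ``x + 2*N0*x/(kd + x) = L0`` (a quadratic); the per-site occupancy is
    ``theta = x/(kd + x)`` and the 0/1/2-bound species follow the binomial
    distribution ``((1-theta)^2, 2*theta*(1-theta), theta^2)``.
    """
    _require_nonnegative("receptor_total", receptor_total)
    _require_nonnegative("ligand_total", ligand_total)
    _require_positive("kd_micro", kd_micro)
    n0, l0, kd = float(receptor_total), float(ligand_total), float(kd_micro)
    if l0 == 0.0:
        return MixtureState(n0, 0.0, 0.0, 0.0, (1.0, 0.0, 0.0))
    # x^2 + (kd + 2 N0 - L0) x - kd L0 = 0, positive root, stable form
    b = kd + 2.0 * n0 - l0
    disc = b * b + 4.0 * kd * l0
    if b >= 0.0:
        x = 2.0 * kd * l0 / (b + math.sqrt(disc))
    else:
        x = (-b + math.sqrt(disc)) / 2.0
    assert x > 0.0, "free ligand must be positive for valid inputs"
    theta = x / (kd + x)
    fractions = ((1.0 - theta) ** 2, 2.0 * theta * (1.0 - theta), theta**2)
    return MixtureState(n0, l0, x, theta, fractions)


def effective_concentration(kd_tail: float, kd_dna: float, kd_nucleosome: float) -> float:
    """Avidity effective concentration of bipartite binding, mol/L.

    For a reader engaging two linked epitopes (here the methylated histone
    tail and the nucleosomal DNA), the apparent local concentration one
    epitope presents to its partner while the other is engaged is
    ``kd_tail * kd_dna / kd_nucleosome``.
    """
    _require_positive("kd_tail", kd_tail)
    _require_positive("kd_dna", kd_dna)
    _require_positive("kd_nucleosome", kd_nucleosome)
    return kd_tail * kd_dna / kd_nucleosome


def fold_enhancement(kd_reference: float, kd_complex: float) -> tuple[float, float]:
    """Affinity enhancement of the assembled complex over a reference.

    Returns ``(ratio, nearest_power_of_ten)`` with
    ``ratio = kd_reference / kd_complex``.
    """
    _require_positive("kd_reference", kd_reference)
    _require_positive("kd_complex", kd_complex)
    ratio = kd_reference / kd_complex
    return ratio, 10.0 ** round(math.log10(ratio))


def complex_lifetime(koff: float) -> float:
    """Mean lifetime of the bound complex, seconds: ``1 / koff``."""
    _require_positive("koff", koff)
    return 1.0 / koff
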