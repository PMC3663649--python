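"""Seeded generators of synthetic titration datasets.

These emulate the three experiment types the fitters consume:

* ``csp_peptide`` / ``csp_dna`` / ``csp_mla`` — fast-exchange CSP
  titrations of a 0.3 mM receptor.  The peptide run reaches 30 mM ligand
  against a 17 mM K_D; the DNA run reaches 1.2 mM against 150 μM; the
  methyl-lysine-analogue (MLA) peptide run reaches 4 mM against 11 mM,
  matching the restricted fitting interval used for that sample.
* ``lineshape_nucleosome`` — a methyl-group line-shape titration of a
  116 μM nucleosome with reader added to 2.7 molar equivalents, in the
  intermediate-fast exchange regime (K_D 1.5 μM, k_off 500 1/s).
* ``emsa`` — gel lanes at 0/0.5/1/2/3 molar equivalents of reader over
  0.375 μM nucleosome (3 pmol in 8 μL), K_D 0.5 μM.

Exact titration schedules were not published for the NMR experiments;
the defaults here are documented assumptions (see docs/methods.md).
Identical (spec, seed) pairs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .csp import CspCurve, ShiftRecord
from .emsa import LaneDensities
from .equilibria import EquilibriumParams, solve_1to1_complex, solve_two_site
from .lineshape import AcquisitionParams, ExchangeState, SpectrumTrace, titration_lineshapes

__all__ = [
    "GeneratorSpec",
    "make_csp_dataset",
    "make_lineshape_dataset",
    "make_emsa_dataset",
    "DEFAULT_CSP_MAX",
    "FREE_SHIFTS",
]

#: saturation CSP amplitude (ppm, combined) per reporter residue.  Chosen to
#: span the 0.05–0.3 ppm range typical of a shallow peptide-binding surface;
#: residue numbers follow the reader-domain binding-site reporters.
DEFAULT_CSP_MAX = {15: 0.18, 18: 0.22, 21: 0.30, 44: 0.12, 49: 0.08, 74: 0.15}

#: free-state amide positions (1H, 15N ppm) for the synthetic peak lists
FREE_SHIFTS = {
    15: ("MET", 8.42, 118.3),
    18: ("TYR", 9.01, 121.7),
    21: ("TRP", 8.77, 126.4),
    44: ("PHE", 8.15, 115.2),
    49: ("GLU", 7.93, 119.8),
    74: ("ARG", 8.60, 123.1),
}

#: fixed direction (degrees) along which a combined CSP splits into
#: (1H, X) components in peak-list mode
CSP_SPLIT_ANGLE_DEG = 35.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Ground truth + schedule + noise for one synthetic dataset."""

    experiment: str  # csp_peptide | csp_dna | csp_mla | lineshape_nucleosome | emsa
    kd: float  # mol/L (microscopic for two-site experiments)
    receptor_total: float  # mol/L
    schedule: tuple  # ligand totals (M) for csp; molar ratios/equivalents otherwise
    noise: float  # ppm (csp), fraction of peak height (lineshape), fraction (emsa)
    seed: int = 0
    # line-shape truth
    koff: float = 500.0
    delta_omega_ppm: float = 0.35
    r2_free: float = 8.0
    r2_bound: float = 40.0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    # csp truth
    csp_max: dict = field(default_factory=lambda: dict(DEFAULT_CSP_MAX))
    x_weight: float = 0.2
    # emsa nuisance
    loading_cv: float = 0.10

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if not self.schedule:
            raise ValueError("schedule must be non-empty")
        if float(self.schedule[0]) != 0.0:
            raise ValueError("schedule must start with the free/zero point")
        if self.kd <= 0 or self.receptor_total <= 0:
            raise ValueError("kd and receptor_total must be > 0")

    @classmethod
    def preset(cls, name: str, seed: int = 0, **overrides) -> "GeneratorSpec":
        """Named study conditions; override any field by keyword."""
        presets = {
            "csp_peptide": dict(
                experiment="csp_peptide",
                kd=17e-3,
                receptor_total=0.3e-3,
                schedule=(0.0, 0.5e-3, 1e-3, 2e-3, 4e-3, 8e-3, 16e-3, 30e-3),
                noise=0.004,
            ),
            "csp_dna": dict(
                experiment="csp_dna",
                kd=150e-6,
                receptor_total=0.3e-3,
                schedule=(0.0, 0.05e-3, 0.1e-3, 0.2e-3, 0.4e-3, 0.8e-3, 1.2e-3),
                noise=0.004,
            ),
            "csp_mla": dict(
                experiment="csp_mla",
                kd=11e-3,
                receptor_total=0.3e-3,
                schedule=(0.0, 0.25e-3, 0.5e-3, 1e-3, 2e-3, 4e-3),
                noise=0.003,
            ),
            "lineshape_nucleosome": dict(
                experiment="lineshape_nucleosome",
                kd=1.5e-6,
                receptor_total=116e-6,
                schedule=(0.0, 0.5, 1.0, 1.8, 2.7),
                noise=0.02,
            ),
            "emsa": dict(
                experiment="emsa",
                kd=0.5e-6,
                receptor_total=0.375e-6,
                schedule=(0.0, 0.5, 1.0, 2.0, 3.0),
                noise=0.05,
            ),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; expected one of {sorted(presets)}")
        kw = presets[name]
        kw.update(overrides)
        return cls(seed=seed, **kw)


def _rng(spec: GeneratorSpec) -> np.random.Generator:
    return np.random.default_rng(spec.seed)


def make_csp_dataset(spec: GeneratorSpec):
    """Synthetic CSP titration: peak lists per point plus derived curves.

    Returns ``(peaklists, curves)``.  Noiseless model:
    ``csp = csp_max * [PL]/P0``.  Curve noise is Gaussian on the combined
    CSP, folded at zero (a measured CSP is a magnitude); peak-list noise
    perturbs the raw 1H/X shifts so that the derived combined CSP has
    standard deviation ~``spec.noise``.  The free point is the reference
    and carries no noise.
    """
    if not spec.experiment.startswith("csp"):
        raise ValueError(f"not a CSP experiment: {spec.experiment}")
    rng = _rng(spec)
    schedule = np.asarray(spec.schedule, dtype=float)
    pl = solve_1to1_complex(spec.receptor_total, schedule, spec.kd)
    fb = pl / spec.receptor_total
    phi = math.radians(CSP_SPLIT_ANGLE_DEG)

    curves = []
    deltas = {}  # residue -> noiseless (dH, dX) per point
    for rid, cmax in sorted(spec.csp_max.items()):
        clean = cmax * fb
        noisy = np.abs(clean + rng.normal(0.0, spec.noise, clean.size)) if spec.noise else clean.copy()
        noisy[0] = 0.0
        curves.append(CspCurve(rid, noisy, schedule, spec.receptor_total))
        deltas[rid] = (clean * math.cos(phi), clean * math.sin(phi) / spec.x_weight)

    peaklists = []
    sigma_h = spec.noise / math.sqrt(2.0)
    sigma_x = spec.noise / (math.sqrt(2.0) * spec.x_weight)
    for i in range(schedule.size):
        records = []
        for rid in sorted(spec.csp_max):
            name, h0, x0 = FREE_SHIFTS.get(rid, ("UNK", 8.3, 120.0))
            dh, dx = deltas[rid][0][i], deltas[rid][1][i]
            if spec.noise and i > 0:
                dh += rng.normal(0.0, sigma_h)
                dx += rng.normal(0.0, sigma_x)
            records.append(ShiftRecord(rid, name, h0 + dh, x0 + dx, titration_index=i))
        peaklists.append(records)
    return peaklists, curves


def make_lineshape_dataset(spec: GeneratorSpec):
    """Synthetic exchange line-shape titration.

    Returns ``(traces, manifest)`` where the manifest records the molar
    ratios, receptor concentration and seed.  Noise is additive Gaussian
    with standard deviation ``spec.noise`` times each trace's peak height.
    """
    if spec.experiment != "lineshape_nucleosome":
        raise ValueError(f"not a line-shape experiment: {spec.experiment}")
    rng = _rng(spec)
    states = (
        ExchangeState(0.0, spec.r2_free),
        ExchangeState(spec.delta_omega_ppm, spec.r2_bound),
    )
    traces = titration_lineshapes(
        EquilibriumParams(spec.kd, 2),
        spec.koff,
        states,
        spec.acquisition,
        spec.receptor_total,
        spec.schedule,
    )
    noisy = []
    for tr in traces:
        y = tr.intensity
        if spec.noise:
            y = y + rng.normal(0.0, spec.noise * y.max(), y.size)
        noisy.append(SpectrumTrace(tr.ppm, y, tr.acquisition, tr.ratio))
    manifest = {
        "ratios": [float(r) for r in spec.schedule],
        "receptor_total_M": spec.receptor_total,
        "seed": spec.seed,
    }
    return noisy, manifest


def make_emsa_dataset(spec: GeneratorSpec) -> list[LaneDensities]:
    """Synthetic gel-lane table under the two-equivalent-site model.

    Species fractions at each equivalents step are perturbed by Gaussian
    noise truncated at zero and rescaled by a log-normal per-lane loading
    factor (coefficient of variation ``spec.loading_cv``).
    """
    if spec.experiment != "emsa":
        raise ValueError(f"not an EMSA experiment: {spec.experiment}")
    rng = _rng(spec)
    lanes = []
    for i, eq in enumerate(spec.schedule):
        mix = solve_two_site(spec.receptor_total, eq * spec.receptor_total, spec.kd)
        f = np.asarray(mix.species_fractions)
        if spec.noise:
            f = np.maximum(f + rng.normal(0.0, spec.noise, 3), 0.0)
            if f.sum() == 0:
                f = np.asarray(mix.species_fractions)
        loading = float(rng.lognormal(0.0, spec.loading_cv)) if spec.loading_cv else 1.0
        d = f * loading
        lanes.append(
            LaneDensities(
                equivalents=float(eq),
                density_free=float(d[0]),
                density_b1=float(d[1]),
                density_b2=float(d[2]),
                receptor_total=spec.receptor_total,
                lane_id=f"L{i}",
            )
        )
    return lanes
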