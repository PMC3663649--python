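"""Concentration unit handling.

Everything internal runs in mol/L; these helpers convert at the I/O
boundary.  Units must be named explicitly — there is no inference.
"""

from __future__ import annotations

_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,  # μM
    "nM": 1e-9,
}


def to_molar(value: float, unit: str) -> float:
    """Convert ``value`` in ``unit`` (M, mM, uM/μM, nM) to mol/L."""
    try:
        return value * _FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_FACTORS)}"
        ) from None


def from_molar(value: float, unit: str) -> float:
    """Convert ``value`` in mol/L to ``unit``."""
    try:
        return value / _FACTORS[unit]
    except KeyError:
        raise ValueError(
            f"unknown concentration unit {unit!r}; expected one of {sorted(_FACTORS)}"
        ) from None


def pmol_in_volume_to_molar(pmol: float, volume_ul: float) -> float:
    """Amount (pmol) loaded in ``volume_ul`` microliters → mol/L.

    1.5 pmol in 8 μL is 0.1875 μM; 3 pmol in 8 μL is 0.375 μM — the two
    standard gel-shift loads.
    """
    if pmol < 0:
        raise ValueError("pmol must be >= 0")
    if volume_ul <= 0:
        raise ValueError("volume_ul must be > 0")
    return (pmol * 1e-12) / (volume_ul * 1e-6)
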