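"""Unit registry: molar masses and g/L <-> mmol/L conversions."""

from __future__ import annotations

#: molar masses in g/mol of the measured compounds (free-acid forms)
MOLAR_MASSES = {
    "glucose": 180.16,
    "fructose": 180.16,
    "malate": 134.09,
    "citrate": 192.12,
    "mannitol": 182.17,
    "erythritol": 122.12,
    "L-lactate": 90.08,
    "D-lactate": 90.08,
    "lactate": 90.08,
    "acetate": 60.05,
    "ethanol": 46.07,
    "diacetyl": 86.09,
    "cysteine": 121.16,
    "threonine": 119.12,
    "valine": 117.15,
    "phenylalanine": 165.19,
    "serine": 105.09,
    "arginine": 174.20,
    "glutamate": 147.13,
    "aspartate": 133.10,
    "lysine": 146.19,
    "histidine": 155.15,
    "proline": 115.13,
    "alanine": 89.09,
    "glycine": 75.07,
    "isoleucine": 131.17,
    "leucine": 131.17,
    "methionine": 149.21,
    "tryptophan": 204.23,
    "tyrosine": 181.19,
    "glutamine": 146.14,
    "asparagine": 132.12,
}


def g_per_l_to_mmol_per_l(value: float, compound: str) -> float:
    """Convert a g/L concentration to mmol/L using the packaged molar mass."""
    try:
        mass = MOLAR_MASSES[compound]
    except KeyError as exc:
        raise KeyError(f"no molar mass registered for {compound!r}") from exc
    return value / mass * 1000.0


def mmol_per_l_to_g_per_l(value: float, compound: str) -> float:
    try:
        mass = MOLAR_MASSES[compound]
    except KeyError as exc:
        raise KeyError(f"no molar mass registered for {compound!r}") from exc
    return value * mass / 1000.0
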