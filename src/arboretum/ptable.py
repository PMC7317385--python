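"""Periodic-table constants shared across modules.

Only main-group elements through Kr are tabulated in full; charge schemes
that need element parameters (CM5, EEQ, vdW radii) carry their own tables
and raise on elements they do not cover.
"""

from __future__ import annotations

SYMBOLS = [
    "X", "H", "He",
    "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
    "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu", "Zn",
    "Ga", "Ge", "As", "Se", "Br", "Kr",
]

SYMBOL_TO_Z = {s: z for z, s in enumerate(SYMBOLS) if z > 0}
# accept lowercase / uppercase variants
SYMBOL_TO_Z.update({s.upper(): z for s, z in list(SYMBOL_TO_Z.items())})
SYMBOL_TO_Z.update({s.lower(): z for s, z in list(SYMBOL_TO_Z.items())})

# Standard atomic weights (u), H..Kr.  Used only for moments of inertia in
# duplicate detection; heavier elements fall back to 2*Z.
MASSES = {
    1: 1.008, 2: 4.0026,
    3: 6.94, 4: 9.0122, 5: 10.81, 6: 12.011, 7: 14.007, 8: 15.999,
    9: 18.998, 10: 20.180,
    11: 22.990, 12: 24.305, 13: 26.982, 14: 28.085, 15: 30.974,
    16: 32.06, 17: 35.45, 18: 39.948,
    19: 39.098, 20: 40.078, 21: 44.956, 22: 47.867, 23: 50.942,
    24: 51.996, 25: 54.938, 26: 55.845, 27: 58.933, 28: 58.693,
    29: 63.546, 30: 65.38, 31: 69.723, 32: 72.630, 33: 74.922,
    34: 78.971, 35: 79.904, 36: 83.798,
}


def mass_of(z: int) -> float:
    return MASSES.get(z, 2.0 * z)


def symbol_of(z: int) -> str:
    if 0 < z < len(SYMBOLS):
        return SYMBOLS[z]
    return f"E{z}"


def z_of(symbol: str) -> int:
    try:
        return SYMBOL_TO_Z[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None
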