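"""Van der Waals radii, keyed by element symbol.

Values are the Bondi (1964) set as commonly tabulated for protein work,
in Angstroms. Elements absent from the table fall back to
``DEFAULT_VDW_RADIUS`` with a warning (configurable by the caller).
"""

from __future__ import annotations

import warnings

VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "CA": 2.31,
    "ZN": 1.39,
    "FE": 1.94,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS = 1.70


def vdw_radius(element: str, default: float = DEFAULT_VDW_RADIUS) -> float:
    """Look up the van der Waals radius for an element symbol.

    Unknown elements get ``default`` (1.70 A, a carbon-like sphere) and
    raise a ``UserWarning`` so silent misassignments are visible.
    """
    key = element.strip().upper()
    try:
        return VDW_RADII[key]
    except KeyError:
        warnings.warn(
            f"no van der Waals radius for element {element!r}; "
            f"using default {default} A",
            stacklevel=2,
        )
        return default


_TWO_LETTER = {k for k in VDW_RADII if len(k) == 2}


def element_from_atom_name(name: str) -> str:
    """Infer the element symbol from a PDB atom name.

    PDB atom names right-justify one-letter elements in columns 13-16
    (" CA " is an alpha carbon; "CA  " would be calcium), but files in
    the wild are sloppy, so the heuristic works on the stripped name:
    a leading digit is skipped (e.g. "1HB"), then a two-letter symbol is
    accepted only if the first letter alone is not a standard protein
    element.
    """
    s = name.strip()
    while s and s[0].isdigit():
        s = s[1:]
    if not s:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    first = s[0].upper()
    if first in ("H", "C", "N", "O", "S", "P", "F"):
        return first
    two = s[:2].upper()
    if two in _TWO_LETTER:
        return two
    return first
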