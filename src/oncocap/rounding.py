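"""Exact integer rounding helpers.

All whole-patient and whole-staff conversions in the pipeline round through
exact rational arithmetic so that decimal inputs such as 57% of 28,934 cases
never fall on the wrong side of a half because of binary floating point.
Two conventions are used consistently:

* demand quantities (patients) round **half-up** — whole-patient semantics;
* capacity quantities (staff, wards, machines) round **up** (ceiling) — a
  fractional requirement still needs a whole person or unit.
"""

from __future__ import annotations

import math
from fractions import Fraction


def _as_fraction(x) -> Fraction:
    """Exact rational view of a number; floats go through their decimal repr."""
    if isinstance(x, (int, Fraction)):
        return Fraction(x)
    return Fraction(str(x))


def round_half_up(x) -> int:
    """Round to the nearest integer with halves going up (0.5 -> 1)."""
    return math.floor(_as_fraction(x) + Fraction(1, 2))


def ceil_exact(x) -> int:
    """Ceiling through exact rational arithmetic."""
    return math.ceil(_as_fraction(x))


def scale_half_up(count: int, factor) -> int:
    """count × factor, rounded half-up to whole units."""
    return round_half_up(Fraction(count) * _as_fraction(factor))


def per_1000_ceil(patients: int, per_1000) -> int:
    """Ceiling of patients × rate / 1000 — the staffing-ratio conversion."""
    return ceil_exact(Fraction(patients) * _as_fraction(per_1000) / 1000)
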