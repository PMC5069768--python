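"""Monoisotopic mass arithmetic, mass-defect screening and isotope patterns.

Polyhalogenated natural products (bromophenols, bromopyrroles and their
hybrids) carry strongly anomalous mass defects because Br-79 (78.9183 Da)
and Cl-35 (34.9689 Da) sit far below their nominal masses.  A linear
mass-defect window over the neutral mass is therefore a cheap first-pass
screen for halogenation in an untargeted feature table; the characteristic
M/M+2/M+4 isotope envelopes of Cl/Br confirm the call and constrain the
elemental formula.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ElementalFormula",
    "MassDefectParams",
    "monoisotopic_mass",
    "mass_defect",
    "defect_window_pass",
    "isotope_pattern",
    "pattern_match_score",
    "screen_features",
    "ADDUCT_MASSES",
]

# Most-abundant-isotope masses (Da), CODATA/AME reference values.
MONOISOTOPIC: Dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Br": 78.9183376,
    "Cl": 34.96885271,
    "I": 126.904468,
    "F": 18.99840320,
}

# Per-element isotope distributions as (integer mass offset, abundance).
ISOTOPES: Dict[str, Tuple[Tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
    "P": ((0, 1.0),),
    "Br": ((0, 0.5069), (2, 0.4931)),
    "Cl": ((0, 0.7576), (2, 0.2424)),
    "I": ((0, 1.0),),
    "F": ((0, 1.0),),
}

# Common ESI adduct mass shifts (Da) for dereplication arithmetic.
ADDUCT_MASSES: Dict[str, float] = {
    "[M+H]+": 1.00727646,
    "[M-H]-": -1.00727646,
    "[M+Na]+": 22.98922070,
    "[M+NH4]+": 18.03382555,
    "[M+K]+": 38.96315791,
    "[2M+H]+": 1.00727646,  # apply to 2*M
    "[M+Cl]-": 34.96940126,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Elemental composition over the supported element set."""

    counts: Tuple[Tuple[str, int], ...]

    @classmethod
    def parse(cls, formula: str) -> "ElementalFormula":
        """Parse a Hill-style formula string such as ``"C30H44N2O9S2"``."""
        counts: Dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
            pos = match.end()
            element = match.group(1)
            if element not in MONOISOTOPIC:
                raise ValueError(f"unknown element {element!r} in {formula!r}")
            counts[element] = counts.get(element, 0) + int(match.group(2) or 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not counts or all(v == 0 for v in counts.values()):
            raise ValueError("formula must contain at least one atom")
        if any(v < 0 for v in counts.values()):
            raise ValueError("element counts must be non-negative")
        return cls(tuple(sorted(counts.items())))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = self.as_dict()
        for element, n in other.counts:
            counts[element] = counts.get(element, 0) + n
        return ElementalFormula(tuple(sorted(counts.items())))

    def __str__(self) -> str:
        return "".join(
            f"{el}{n if n != 1 else ''}" for el, n in self.counts if n > 0
        )


def _as_formula(formula: "ElementalFormula | str | Dict[str, int]") -> ElementalFormula:
    if isinstance(formula, ElementalFormula):
        return formula
    if isinstance(formula, str):
        return ElementalFormula.parse(formula)
    items = tuple(sorted((k, int(v)) for k, v in formula.items()))
    for element, n in items:
        if element not in MONOISOTOPIC:
            raise ValueError(f"unknown element {element!r}")
        if n < 0:
            raise ValueError("element counts must be non-negative")
    if not any(n > 0 for _, n in items):
        raise ValueError("formula must contain at least one atom")
    return ElementalFormula(items)


def monoisotopic_mass(formula: "ElementalFormula | str | Dict[str, int]") -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula, in Da."""
    parsed = _as_formula(formula)
    return sum(MONOISOTOPIC[el] * n for el, n in parsed.counts)


def mass_defect(mass: float, definition: str = "nearest_integer") -> float:
    """Mass defect of ``mass`` under the chosen integer-reference convention.

    ``nearest_integer`` returns ``mass - round(mass)`` (in (-0.5, 0.5]);
    ``fractional_part`` returns ``mass - floor(mass)`` (in [0, 1)).
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if definition == "nearest_integer":
        return mass - round(mass)
    if definition == "fractional_part":
        return mass - math.floor(mass)
    raise ValueError(f"unknown defect definition {definition!r}")


@dataclass(frozen=True)
class MassDefectParams:
    """Linear mass-defect screening window.

    The expected defect at neutral mass ``m`` is
    ``intercept + slope * (m / 100)``; a feature passes when its defect lies
    within ``tolerance`` of that line.  Defaults follow the published screen
    for halogenated *Pseudoalteromonas* metabolites (0.0937 Da at the
    intercept, −0.02 Da per 100 Da, ±0.0100 Da).
    """

    intercept: float = 0.0937
    slope: float = -0.02  # Da per 100 Da
    tolerance: float = 0.0100
    defect_definition: str = "nearest_integer"

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def expected_defect(self, mass: float) -> float:
        return self.intercept + self.slope * (mass / 100.0)


def defect_window_pass(mass: float, params: MassDefectParams | None = None) -> bool:
    """True when a neutral mass falls inside the linear mass-defect window."""
    params = params or MassDefectParams()
    defect = mass_defect(mass, params.defect_definition)
    return abs(defect - params.expected_defect(mass)) <= params.tolerance


def isotope_pattern(
    formula: "ElementalFormula | str | Dict[str, int]",
    n_peaks: int | None = None,
    truncate: float = 1e-6,
) -> List[Tuple[int, float]]:
    """Aggregated isotopologue envelope of a formula.

    Per-element isotope distributions are convolved multinomially on the
    integer mass-offset grid (M, M+1, M+2, ...), then normalised so the base
    peak has abundance 1.  Returns ``(offset, relative abundance)`` pairs;
    offsets with abundance below ``truncate`` (relative to the base peak)
    are dropped.
    """
    parsed = _as_formula(formula)
    dist = np.array([1.0])
    for element, count in parsed.counts:
        if count == 0:
            continue
        iso = ISOTOPES[element]
        width = max(offset for offset, _ in iso) + 1
        elem = np.zeros(width)
        for offset, abundance in iso:
            elem[offset] = abundance
        # element^count by binary exponentiation on the offset grid
        power = elem
        n = count
        acc = np.array([1.0])
        while n:
            if n & 1:
                acc = np.convolve(acc, power)
            n >>= 1
            if n:
                power = np.convolve(power, power)
        dist = np.convolve(dist, acc)
    base = dist.max()
    rel = dist / base
    peaks = [(i, float(r)) for i, r in enumerate(rel) if r >= truncate]
    if n_peaks is not None:
        peaks = peaks[:n_peaks]
    return peaks


def pattern_match_score(
    observed: Sequence[Tuple[float, float]],
    theoretical: Sequence[Tuple[float, float]],
    tol: float = 0.3,
) -> float:
    """Cosine similarity between an observed isotope envelope and a theory one.

    Observed peaks are given as (mass-offset-from-monoisotopic, abundance);
    each is assigned to the nearest theoretical isotopologue slot within
    ``tol`` Da.  The score is the cosine of the two abundance vectors over
    the union of slots (unmatched abundance on either side counts against
    the score).  Returns 0.0 when no observed peak lands in any slot.
    """
    if not observed or not theoretical:
        raise ValueError("observed and theoretical patterns must be nonempty")
    slots = [float(off) for off, _ in theoretical]
    theo = np.array([ab for _, ab in theoretical], dtype=float)
    obs = np.zeros_like(theo)
    unmatched = 0.0
    matched_any = False
    for off, ab in observed:
        deltas = [abs(off - s) for s in slots]
        best = int(np.argmin(deltas))
        if deltas[best] <= tol:
            obs[best] += ab
            matched_any = True
        else:
            unmatched += ab * ab
    if not matched_any:
        return 0.0
    denom = math.sqrt(float(obs @ obs) + unmatched) * math.sqrt(float(theo @ theo))
    if denom == 0:
        return 0.0
    return float(obs @ theo) / denom


def screen_features(
    masses: Iterable[float], params: MassDefectParams | None = None
) -> np.ndarray:
    """Vectorised mass-defect screen; returns a boolean pass flag per mass."""
    params = params or MassDefectParams()
    return np.array([defect_window_pass(m, params) for m in masses], dtype=bool)
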