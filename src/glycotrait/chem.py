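"""Glycan compositions, elemental formulas, sodiated masses and isotopic patterns.

Compositions are counted in five residue classes, reflecting linkage-specific
sialic-acid derivatization (ethyl esterification):

* ``H`` hexose, ``N`` N-acetylhexosamine, ``F`` deoxyhexose (fucose),
* ``L`` lactonized N-acetylneuraminic acid (alpha2,3-linked; NeuAc - H2O),
* ``E`` ethyl-esterified N-acetylneuraminic acid (alpha2,6-linked; NeuAc + C2H4).

Masses are reported for the singly charged sodium adduct [M+Na]+ of the free
reducing-end glycan (residue masses + H2O + Na - e-), which is how these
analytes appear in positive-mode MALDI-TOF spectra.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GlycanComposition",
    "ElementalFormula",
    "CompositionError",
    "parse_composition",
    "composition_mass",
    "elemental_formula",
    "isotopic_pattern",
    "enumerate_compositions",
    "ISOTOPOLOGUE_SPACING",
]

# Average spacing between isotopologue peaks used for peak windows (Da).
ISOTOPOLOGUE_SPACING = 1.00235

ELECTRON_MASS = 0.000548579909

# Monoisotopic masses and isotope tables (IUPAC 2021 representative values),
# indexed by extra-neutron count relative to the lightest isotope.
_ELEMENTS = ("C", "H", "N", "O", "Na")
_MONO_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "Na": 22.9897692809,
}
_ISOTOPE_ABUNDANCE = {
    "C": np.array([0.9893, 0.0107]),
    "H": np.array([0.999885, 0.000115]),
    "N": np.array([0.99636, 0.00364]),
    "O": np.array([0.99757, 0.00038, 0.00205]),
    "Na": np.array([1.0]),
}

_RESIDUE_ORDER = "HNFLE"
# Residue formulas as (C, H, N, O) tuples; residues are dehydrated monomers.
_RESIDUE_FORMULA = {
    "H": (6, 10, 0, 5),   # hexose
    "N": (8, 13, 1, 5),   # N-acetylhexosamine
    "F": (6, 10, 0, 4),   # deoxyhexose
    "L": (11, 15, 1, 7),  # NeuAc lactone (alpha2,3), NeuAc - H2O
    "E": (13, 21, 1, 8),  # NeuAc ethyl ester (alpha2,6), NeuAc + C2H4
}


class CompositionError(ValueError):
    """Raised for malformed composition strings or invalid residue counts."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Integer residue counts of an N-glycan composition (H/N/F/L/E)."""

    H: int = 0
    N: int = 0
    F: int = 0
    L: int = 0
    E: int = 0

    def __post_init__(self) -> None:
        for residue in _RESIDUE_ORDER:
            count = getattr(self, residue)
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise CompositionError(
                    f"residue {residue} count must be a non-negative integer, got {count!r}"
                )

    def __str__(self) -> str:
        parts = [
            f"{r}{getattr(self, r)}" for r in _RESIDUE_ORDER if getattr(self, r) > 0
        ]
        return "".join(parts) if parts else "H0N0"

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            *(getattr(self, r) + getattr(other, r) for r in _RESIDUE_ORDER)
        )

    @property
    def sialic(self) -> int:
        """Total sialic acid count (both linkage variants)."""
        return self.L + self.E

    def counts(self) -> dict[str, int]:
        return {r: getattr(self, r) for r in _RESIDUE_ORDER}


@dataclass(frozen=True)
class ElementalFormula:
    """Element counts (C, H, N, O, Na) of a neutral-plus-sodium species."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    Na: int = 0

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        return ElementalFormula(
            *(getattr(self, e) + getattr(other, e) for e in _ELEMENTS)
        )

    def monoisotopic_mass(self, charge_corrected: bool = True) -> float:
        """Monoisotopic mass; subtracts one electron for the +1 cation."""
        mass = sum(getattr(self, e) * _MONO_MASS[e] for e in _ELEMENTS)
        return mass - ELECTRON_MASS if charge_corrected else mass

    def counts(self) -> dict[str, int]:
        return {e: getattr(self, e) for e in _ELEMENTS}


_TOKEN = re.compile(r"([A-Za-z])(-?\d+)?")


def parse_composition(text: str) -> GlycanComposition:
    """Parse a composition string such as ``"H5N4F1L1E1"``.

    Residues may appear in any order; unmentioned residues are zero.  The
    canonical rendered form (``str(c)``) always uses H, N, F, L, E order with
    zero counts omitted.
    """
    if not isinstance(text, str) or not text.strip():
        raise CompositionError(f"empty composition string: {text!r}")
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    for match in _TOKEN.finditer(stripped):
        if match.start() != pos:
            raise CompositionError(
                f"unparseable token {stripped[pos:match.start()]!r} in {text!r}"
            )
        pos = match.end()
        residue, count = match.group(1).upper(), match.group(2)
        if residue not in _RESIDUE_FORMULA:
            raise CompositionError(f"unknown residue letter {residue!r} in {text!r}")
        if count is None:
            raise CompositionError(f"missing count after residue {residue!r} in {text!r}")
        if int(count) < 0:
            raise CompositionError(f"negative count {count!r} for residue {residue!r}")
        if residue in counts:
            raise CompositionError(f"residue {residue!r} given twice in {text!r}")
        counts[residue] = int(count)
    if pos != len(stripped):
        raise CompositionError(f"unparseable trailing text {stripped[pos:]!r} in {text!r}")
    return GlycanComposition(**{r: counts.get(r, 0) for r in _RESIDUE_ORDER})


def _as_composition(c: "GlycanComposition | str") -> GlycanComposition:
    return parse_composition(c) if isinstance(c, str) else c


def elemental_formula(c: "GlycanComposition | str") -> ElementalFormula:
    """Elemental formula of the sodiated species: residues + H2O + Na."""
    c = _as_composition(c)
    totals = {"C": 0, "H": 2, "N": 0, "O": 1, "Na": 1}  # + H2O + Na
    for residue in _RESIDUE_ORDER:
        nC, nH, nN, nO = _RESIDUE_FORMULA[residue]
        n = getattr(c, residue)
        totals["C"] += n * nC
        totals["H"] += n * nH
        totals["N"] += n * nN
        totals["O"] += n * nO
    return ElementalFormula(**totals)


def composition_mass(c: "GlycanComposition | str") -> float:
    """Monoisotopic m/z of the singly charged [M+Na]+ ion of composition *c*."""
    return elemental_formula(c).monoisotopic_mass()


def _binomial_power(base: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """Distribution of the sum of *n* iid isotope draws, truncated to max_len."""
    result = np.array([1.0])
    power = base.copy()
    while n > 0:
        if n & 1:
            result = np.convolve(result, power)[:max_len]
        n >>= 1
        if n:
            power = np.convolve(power, power)[:max_len]
    return result


def isotopic_pattern(
    c: "GlycanComposition | str | ElementalFormula", k: int | None = 3
) -> np.ndarray:
    """First *k* isotopologue fractions of the aggregated isotope distribution.

    Isotopologues are grouped by extra-neutron count (unit-mass aggregation)
    and computed by element-wise convolution of the per-element isotope
    distributions.  ``k=None`` returns the complete pattern (sums to 1).
    """
    if isinstance(c, ElementalFormula):
        formula = c
    else:
        formula = elemental_formula(_as_composition(c))
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    n_extra = sum(
        getattr(formula, e) * (len(_ISOTOPE_ABUNDANCE[e]) - 1) for e in _ELEMENTS
    )
    max_len = n_extra + 1 if k is None else min(k, n_extra + 1)
    # Keep a few guard terms so truncation does not bias the kept fractions.
    work_len = max_len if k is None else n_extra + 1
    pattern = np.array([1.0])
    for element in _ELEMENTS:
        n = getattr(formula, element)
        if n == 0:
            continue
        pattern = np.convolve(
            pattern, _binomial_power(_ISOTOPE_ABUNDANCE[element], n, work_len)
        )[:work_len]
    out = np.zeros(max_len if k is None else k)
    out[: min(len(pattern), len(out))] = pattern[: len(out)]
    return out


def isotopologue_mz(
    c: "GlycanComposition | str", k: int = 3, spacing: float = ISOTOPOLOGUE_SPACING
) -> np.ndarray:
    """m/z positions of the first *k* isotopologue peaks of [M+Na]+."""
    return composition_mass(_as_composition(c)) + spacing * np.arange(k)


DEFAULT_BOUNDS = {"H": 12, "N": 10, "F": 6, "L": 6, "E": 6}


def enumerate_compositions(
    target_mz: float,
    tol_ppm: float = 20.0,
    bounds: dict[str, int] | None = None,
) -> list[GlycanComposition]:
    """All compositions within ``tol_ppm`` of ``target_mz``, sorted by |ppm|.

    Performs an exhaustive search of the bound box; with the default bounds
    this spans ~50k candidate compositions and runs in milliseconds.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    base = composition_mass(GlycanComposition())
    residue_mass = {
        r: composition_mass(GlycanComposition(**{r: 1})) - base for r in _RESIDUE_ORDER
    }
    tol_da = target_mz * tol_ppm * 1e-6
    hits: list[tuple[float, GlycanComposition]] = []
    # Nested search with running-mass pruning (each residue mass is positive).
    ranges = [range(bounds[r] + 1) for r in _RESIDUE_ORDER]
    for counts in itertools.product(*ranges):
        mass = base + sum(n * residue_mass[r] for n, r in zip(counts, _RESIDUE_ORDER))
        if abs(mass - target_mz) <= tol_da:
            ppm = (mass - target_mz) / target_mz * 1e6
            hits.append((abs(ppm), GlycanComposition(*counts)))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [c for _, c in hits]
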