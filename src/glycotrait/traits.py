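"""Glycan classification and derived glycan traits.

A derived trait aggregates the relative abundances of glycans sharing a
structural feature (e.g. multi-fucosylation, galactosylation per antenna)
into a single percentage per sample.  Traits are ratios and therefore
invariant to rescaling of the profile.

Every trait is declared in a single registry (:data:`TRAIT_REGISTRY`) as a
pair of abundance-weight functions (numerator weight, denominator weight)
so alternative formulations can be swapped without touching the pipeline:

    trait(profile) = 100 * sum_c a_c * num(c) / sum_c a_c * den(c)

Composition-level structural quantities used in the formulas:

* class: N=2 and H>=5 -> high-mannose; N=2 and H<=4 -> paucimannose;
  N=3 and H>=5 -> hybrid; otherwise complex (N>=2 required).
* antennae (complex only): N - 2, floored at 1.  Bisecting GlcNAc cannot be
  distinguished from an antenna at the composition level, so a bisected
  species counts one extra antenna (known confound).
* galactoses (complex only): min(H - 3, antennae), floored at 0.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from enum import Enum
from typing import Callable

import numpy as np
import pandas as pd

from .chem import GlycanComposition, parse_composition

__all__ = [
    "GlycanClass",
    "classify_glycan",
    "antennae",
    "galactoses",
    "TraitDef",
    "TRAIT_REGISTRY",
    "TRAIT_NAMES",
    "compute_traits",
    "trait_table",
]


class GlycanClass(str, Enum):
    HIGH_MANNOSE = "high-mannose"
    PAUCIMANNOSE = "paucimannose"
    HYBRID = "hybrid"
    COMPLEX = "complex"


def classify_glycan(c: "GlycanComposition | str") -> GlycanClass:
    """Assign a composition to exactly one structural class.

    Requires at least the two core GlcNAcs (N >= 2); compositions with fewer
    are not valid N-glycans.
    """
    if isinstance(c, str):
        c = parse_composition(c)
    if c.N < 2:
        raise ValueError(f"{c} is not a valid N-glycan composition (needs N >= 2)")
    if c.N == 2:
        return GlycanClass.HIGH_MANNOSE if c.H >= 5 else GlycanClass.PAUCIMANNOSE
    if c.N == 3 and c.H >= 5:
        return GlycanClass.HYBRID
    return GlycanClass.COMPLEX


def antennae(c: GlycanComposition) -> int:
    """Antenna count of a complex composition: N - 2, floored at 1."""
    return max(c.N - 2, 1)


def galactoses(c: GlycanComposition) -> int:
    """Galactose count of a complex composition: min(H - 3, antennae)."""
    return max(min(c.H - 3, antennae(c)), 0)


def _is_complex(c: GlycanComposition) -> bool:
    return classify_glycan(c) is GlycanClass.COMPLEX


WeightFn = Callable[[GlycanComposition], float]


@dataclass(frozen=True)
class TraitDef:
    """One derived trait: numerator and denominator abundance weights."""

    name: str
    description: str
    numerator: WeightFn
    denominator: WeightFn

    def evaluate(self, comps: list[GlycanComposition], ab: np.ndarray) -> float:
        num = sum(a * self.numerator(c) for c, a in zip(comps, ab))
        den = sum(a * self.denominator(c) for c, a in zip(comps, ab))
        if den <= 0:
            return np.nan  # undefined subset: reported missing, never 0
        return 100.0 * num / den


def _all(c: GlycanComposition) -> float:
    return 1.0


TRAIT_REGISTRY: tuple[TraitDef, ...] = (
    TraitDef("MultiFuc", "glycans with >= 2 fucoses, of total",
             lambda c: c.F >= 2, _all),
    TraitDef("MonoFuc", "glycans with exactly 1 fucose, of total",
             lambda c: c.F == 1, _all),
    TraitDef("CFa", "multi-fucosylated complex glycans, of complex (antenna fucosylation)",
             lambda c: _is_complex(c) and c.F >= 2, _is_complex),
    TraitDef("CFc", "mono-fucosylated complex glycans, of complex (core fucosylation)",
             lambda c: _is_complex(c) and c.F == 1, _is_complex),
    TraitDef("SialylTotal", "glycans carrying >= 1 sialic acid, of total",
             lambda c: c.sialic >= 1, _all),
    TraitDef("Sia23", "alpha2,3-sialylation per antenna over complex glycans",
             lambda c: c.L / antennae(c) if _is_complex(c) else 0.0, _is_complex),
    TraitDef("Sia26", "alpha2,6-sialylation per antenna over complex glycans",
             lambda c: c.E / antennae(c) if _is_complex(c) else 0.0, _is_complex),
    TraitDef("Sia23Glycans", "glycans carrying >= 1 alpha2,3-linked sialic acid, of total",
             lambda c: c.L >= 1, _all),
    TraitDef("Sia26Glycans", "glycans carrying >= 1 alpha2,6-linked sialic acid, of total",
             lambda c: c.E >= 1, _all),
    TraitDef("SiaPerGal", "sialic acids per galactose over galactosylated complex glycans",
             lambda c: c.sialic / galactoses(c)
             if _is_complex(c) and galactoses(c) >= 1 else 0.0,
             lambda c: _is_complex(c) and galactoses(c) >= 1),
    TraitDef("GalPerAntenna", "galactoses per antenna over complex glycans",
             lambda c: galactoses(c) / antennae(c) if _is_complex(c) else 0.0,
             _is_complex),
    TraitDef("HexNAcGeHex", "complex glycans with HexNAc >= Hex, of total",
             lambda c: _is_complex(c) and c.N >= c.H, _all),
    TraitDef("HexNAcGe7", "glycans with >= 7 HexNAc, of total",
             lambda c: c.N >= 7, _all),
    TraitDef("CLFa", "multi-fucosylated alpha2,3-sialylated complex glycans, of complex",
             lambda c: _is_complex(c) and c.F >= 2 and c.L >= 1, _is_complex),
    TraitDef("HighMannose", "high-mannose glycans, of total",
             lambda c: classify_glycan(c) is GlycanClass.HIGH_MANNOSE, _all),
)

TRAIT_NAMES: tuple[str, ...] = tuple(t.name for t in TRAIT_REGISTRY)


def compute_traits(profile: Mapping[str, float] | pd.Series) -> pd.Series:
    """Derived traits (%) from one normalized glycan profile.

    ``profile`` maps composition strings to relative abundances.  Traits are
    ratio-based, so any positive total is accepted.  Subsets with zero
    abundance yield NaN for the corresponding trait (missing, not 0).
    """
    if isinstance(profile, pd.Series):
        profile = profile.to_dict()
    if not profile:
        raise ValueError("empty profile")
    comps = [parse_composition(k) for k in profile]
    ab = np.asarray(list(profile.values()), dtype=float)
    if (ab < 0).any():
        raise ValueError("profile abundances must be non-negative")
    if ab.sum() <= 0:
        raise ValueError("profile has zero total abundance")
    return pd.Series(
        {t.name: t.evaluate(comps, ab) for t in TRAIT_REGISTRY}, name="trait"
    )


def trait_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """Trait table (samples x traits) from a profile table (samples x compositions)."""
    return pd.DataFrame(
        {sample: compute_traits(profiles.loc[sample].dropna()) for sample in profiles.index}
    ).T.rename_axis(index="sample")


def describe_registry() -> str:
    """Plain-text dump of the trait formula registry for audit."""
    return "\n".join(f"{t.name}: {t.description}" for t in TRAIT_REGISTRY)
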