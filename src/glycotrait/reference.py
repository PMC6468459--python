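"""Reference inputs: calibrant list, cell-line CDX1 table, glyco-gene panel.

These are the fixed, literature-style inputs the pipeline operates on: the
internal recalibration list of glycan peaks of known composition, the CDX1
mRNA expression levels of the 16 colorectal cancer cell lines that define the
high/low grouping (threshold 60 a.u.), and the default glycosyltransferase /
glyco-gene panel tested for differential expression.
"""

from __future__ import annotations

import pandas as pd

from .chem import parse_composition

__all__ = [
    "CALIBRANTS",
    "calibrant_compositions",
    "CDX1_TABLE",
    "CDX1_THRESHOLD",
    "cdx1_groups",
    "GLYCO_GENE_PANEL",
]

#: Internal recalibration list: composition -> reference m/z of [M+Na]+ as
#: used for spectrum recalibration (known-composition glycan peaks).
CALIBRANTS: dict[str, float] = {
    "H5N2": 1257.423,
    "H6N2": 1419.476,
    "H7N2": 1581.529,
    "H8N2": 1743.581,
    "H5N4F1": 1809.639,
    "H5N4F2": 1955.697,
    "H5N4E1": 1982.709,
    "H10N2": 2067.687,
    "H6N5F1": 2174.7715,
    "H5N4L1E1": 2255.793,
    "H5N4E2": 2301.835,
    "H6N5E1": 2347.8403,
    "H7N6F1": 2539.904,
    "H6N5F4": 2612.945,
    "H6N5L1E1": 2620.925,
    "H7N6E1": 2712.973,
    "H7N6L2": 2940.016,
    "H9N8": 3124.111,
    "H7N6L4F1": 3632.243,
}


def calibrant_compositions():
    """The calibrant list as parsed compositions."""
    return [parse_composition(c) for c in CALIBRANTS]


#: CDX1 mRNA expression (arbitrary units) per colorectal cancer cell line.
CDX1_TABLE: dict[str, float] = {
    "HCA46": 3308.59,
    "HCC56": 4115.35,
    "GP2D": 3058.48,
    "PCJW": 2598.75,
    "LS174T": 1147.36,
    "LIM1863": 2862.38,
    "SW403": 2964.14,
    "RCM1": 1152.22,
    "ISRECO1": 32.10,
    "VACO429": 28.69,
    "HCT116": 59.94,
    "CC20": 59.51,
    "CAR1": 49.35,
    "COLO678": 16.21,
    "HDC8": 29.31,
    "OXCO1": 49.69,
}

#: Cell lines below this CDX1 expression (a.u.) are grouped as CDX1-low.
CDX1_THRESHOLD = 60.0


def cdx1_groups() -> pd.Series:
    """Group label ('high'/'low') per cell line from the CDX1 table."""
    return pd.Series(
        {k: "high" if v >= CDX1_THRESHOLD else "low" for k, v in CDX1_TABLE.items()},
        name="group",
    )


#: Default glyco-gene panel for differential expression testing.  Covers the
#: fucosylation pathway (FUT1-9, GMDS), branching and bisection (MGAT1-5),
#: elongation (B3GNT, B4GALT, B4GALNT), sialylation (ST3GAL, ST6GAL, ST8SIA),
#: the intestinal transcription factors (CDX1/2, HNF1A, HNF4A) and LGALS4.
GLYCO_GENE_PANEL: tuple[str, ...] = (
    "FUT1", "FUT2", "FUT3", "FUT4", "FUT5", "FUT6", "FUT7", "FUT8", "FUT9",
    "GMDS",
    "MGAT1", "MGAT2", "MGAT3", "MGAT4A", "MGAT4B", "MGAT5",
    "B3GNT2", "B3GNT3", "B3GNT8",
    "B4GALT1", "B4GALT2", "B4GALT3", "B4GALT4",
    "B4GALNT1", "B4GALNT2", "B4GALNT3",
    "ST3GAL1", "ST3GAL2", "ST3GAL3", "ST3GAL4", "ST3GAL6",
    "ST6GAL1", "ST6GAL2",
    "ST8SIA1", "ST8SIA2", "ST8SIA4",
    "HNF1A", "HNF4A", "LGALS4", "CDX1", "CDX2",
)
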