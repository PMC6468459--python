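"""Text-based readers and writers for the pipeline's file formats.

Spectra travel as two-column m/z-intensity text files (xy export style,
whitespace or comma separated).  Profiles, trait tables and extraction
tables are CSV; expression matrices are TSV (genes x samples with a header
row of sample identifiers).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .processing import Spectrum

__all__ = [
    "read_xy",
    "write_xy",
    "read_profiles",
    "write_profiles",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_composition_list",
    "write_composition_list",
    "read_design",
]


def read_xy(path, metadata: dict | None = None) -> Spectrum:
    """Read a two-column m/z-intensity text file (whitespace or comma)."""
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    data = np.loadtxt(path, delimiter=delimiter, comments=("#", ";"))
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path} is not a two-column xy file")
    meta = {"source": str(path)}
    meta.update(metadata or {})
    return Spectrum(mz=data[:, 0], intensity=data[:, 1], metadata=meta)


def write_xy(spectrum: Spectrum, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.mz, spectrum.intensity]), fmt="%.6f %.4f")


def read_profiles(path) -> pd.DataFrame:
    """Profile table CSV: rows = samples, columns = composition strings."""
    return pd.read_csv(path, index_col=0)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path)


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression TSV: genes x samples, header row of sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t")


def read_composition_list(path) -> pd.DataFrame:
    """Composition list CSV with at least a 'composition' column."""
    frame = pd.read_csv(path)
    if "composition" not in frame.columns:
        raise ValueError(f"{path} lacks a 'composition' column")
    return frame


def write_composition_list(compositions, path) -> None:
    from .chem import composition_mass, parse_composition

    rows = []
    for c in compositions:
        comp = parse_composition(str(c))
        rows.append(
            {"composition": str(comp), **comp.counts(),
             "theoretical_mz": composition_mass(comp)}
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_design(path) -> dict:
    """Key-value design file: 'key = value' lines, '#' comments.

    Recognised keys: n_high, n_low, replicates, seed, sd and per-group trait
    targets of the form ``high.MultiFuc = 54``.
    """
    out: dict = {"targets": {"high": {}, "low": {}}}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed design line: {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if "." in key:
            group, trait = key.split(".", 1)
            if group not in out["targets"]:
                raise ValueError(f"unknown group {group!r} in design key {key!r}")
            out["targets"][group][trait] = float(value)
        elif key in {"n_high", "n_low", "replicates", "seed"}:
            out[key] = int(value)
        elif key == "sd":
            out[key] = float(value)
        else:
            raise ValueError(f"unknown design key {key!r}")
    if not out["targets"]["high"] and not out["targets"]["low"]:
        out.pop("targets")
    return out
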