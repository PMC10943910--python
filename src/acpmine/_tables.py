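"""Loaders for the bundled plain-text data tables (masses, formulas, pKa, scales)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

_DATA_PKG = "acpmine.data"


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files(_DATA_PKG) / name)


@lru_cache(maxsize=None)
def load_table(name: str) -> pd.DataFrame:
    """Read a bundled tab-separated table ('#' lines are comments)."""
    return pd.read_csv(data_path(name), sep="\t", comment="#")


def residue_formulas() -> dict[str, dict[str, int]]:
    df = load_table("residue_formulas.tsv")
    return {row.residue: {"C": row.C, "H": row.H, "N": row.N, "O": row.O, "S": row.S}
            for row in df.itertuples()}


def residue_masses(kind: str = "average") -> dict[str, float]:
    if kind not in ("average", "monoisotopic"):
        raise ValueError(f"unknown mass kind {kind!r}")
    df = load_table("residue_masses.tsv")
    return dict(zip(df["residue"], df[kind]))


WATER_AVERAGE = 18.01528
WATER_MONO = 18.010565


def load_scale(name_or_path: str) -> dict[str, float]:
    """Load a 20-residue scale either bundled by short name or from a file path.

    Bundled names: ``kyte_doolittle``, ``eisenberg``, ``amp_synthetic``.
    """
    bundled = {
        "kyte_doolittle": "scale_kyte_doolittle.tsv",
        "eisenberg": "scale_eisenberg.tsv",
        "amp_synthetic": "scale_amp_synthetic.tsv",
    }
    if name_or_path in bundled:
        df = load_table(bundled[name_or_path])
    else:
        df = pd.read_csv(name_or_path, sep="\t", comment="#")
    scale = dict(zip(df["residue"], df["value"]))
    if len(scale) != 20:
        raise ValueError(f"scale must cover exactly 20 residues, got {len(scale)}")
    return scale


def load_pka_set(name: str = "emboss") -> dict[str, tuple[float, str]]:
    """Load an ionizable-group pKa set as ``group -> (pKa, 'acidic'|'basic')``."""
    if name == "emboss":
        df = load_table("pka_emboss.tsv")
    else:
        df = pd.read_csv(name, sep="\t", comment="#")
    return {row.group: (float(row.pka), row.kind) for row in df.itertuples()}


def load_profile(name_or_path: str) -> dict[str, float]:
    """Load a residue-frequency class profile (bundled: ``acp``, ``background``)."""
    bundled = {"acp": "profile_acp.tsv", "background": "profile_background.tsv"}
    if name_or_path in bundled:
        df = load_table(bundled[name_or_path])
    else:
        df = pd.read_csv(name_or_path, sep="\t", comment="#")
    return dict(zip(df["residue"], df["freq"]))
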