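"""CSV / YAML readers and writers.

All tabular exchange uses UTF-8 CSV with a decimal point.  Published tables
use typographic minus signs (en dash / Unicode minus); :func:`read_panel_csv`
normalizes those to ASCII on ingest.  Writers prepend ``#``-comment
provenance headers (config hash, seed, package version) which readers skip.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .itc import Isotherm, TitrationProtocol
from .panel_stats import LigandPanel

__all__ = [
    "read_panel_csv",
    "write_panel_csv",
    "read_isotherm_csv",
    "write_isotherm_csv",
    "provenance_header",
]

_DASHES = {
    "‒": "-",  # figure dash
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # minus sign
}


def _normalize_text(text: str) -> str:
    for bad, good in _DASHES.items():
        text = text.replace(bad, good)
    return text


def provenance_header(seed=None, config=None) -> str:
    """``#``-comment header recording version, seed and a config digest."""
    from . import __version__

    lines = [f"# htdkit {__version__}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config sha256:{digest}")
    return "\n".join(lines) + "\n"


def read_panel_csv(path) -> LigandPanel:
    """Read a ligand panel: first column ligand names, rest numeric readouts.

    An optional ``class_label`` column becomes the panel's class labels.
    Typographic minus signs are normalized; empty cells become masked (NaN)
    values; duplicate ligands or non-numeric cells raise with location.
    """
    text = _normalize_text(Path(path).read_text(encoding="utf-8"))
    df = pd.read_csv(_io.StringIO(text), comment="#", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate ligand names in {path}: {dupes}")
    labels = None
    if "class_label" in df.columns:
        labels = df.pop("class_label")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            row = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric cell in {path}, column {col!r}, row {row!r}"
            ) from exc
    return LigandPanel(df, class_labels=labels)


def write_panel_csv(panel: LigandPanel, path, header: str = "") -> None:
    df = panel.data.copy()
    if panel.class_labels is not None:
        df.insert(0, "class_label", panel.class_labels)
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, index_label="ligand")


def write_isotherm_csv(isotherm: Isotherm, path, header: str = "") -> None:
    """Columns ``injection,volume_uL,heat_ucal``."""
    p = isotherm.protocol
    df = pd.DataFrame(
        dict(
            injection=np.arange(1, p.n_injections + 1),
            volume_uL=np.full(p.n_injections, p.injection_volume * 1e6),
            heat_ucal=isotherm.heats,
        )
    )
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        df.to_csv(fh, index=False)


def read_isotherm_csv(path, syringe_conc: float, cell_conc: float = 0.0,
                      cell_volume: float = 2.0e-4,
                      temperature: float = 298.15) -> Isotherm:
    """Read an ``injection,volume_uL,heat_ucal`` table back into an Isotherm.

    Concentrations are not stored in the CSV and must be supplied.
    Injection volumes must be uniform (the protocol model assumes it).
    """
    text = _normalize_text(Path(path).read_text(encoding="utf-8"))
    df = pd.read_csv(_io.StringIO(text), comment="#")
    required = {"injection", "volume_uL", "heat_ucal"}
    if not required.issubset(df.columns):
        raise ValueError(f"isotherm CSV {path} must have columns {sorted(required)}")
    vols = df["volume_uL"].to_numpy(dtype=float)
    if not np.allclose(vols, vols[0]):
        raise ValueError("non-uniform injection volumes are not supported")
    protocol = TitrationProtocol(
        syringe_conc=syringe_conc, cell_conc=cell_conc, cell_volume=cell_volume,
        n_injections=len(df), injection_volume=float(vols[0]) * 1e-6,
        temperature=temperature,
    )
    return Isotherm(df["heat_ucal"].to_numpy(dtype=float), protocol)
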