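"""Monomer-population estimation from two-state NMR peak intensities.

In slow exchange the monomer (free) and heterodimer peaks of the reporter
residue are resolved and their intensities are proportional to the state
populations, so

    p_monomer = I_m / (I_m + I_hd)

The intensity uncertainty is propagated to the population by first-order
Taylor expansion in quadrature,

    E_pop = sqrt[(I_hd E_m)^2 + (I_m E_hd)^2] / (I_m + I_hd)^2,

using the partial derivatives dP/dI_m = I_hd/(I_m+I_hd)^2 and
dP/dI_hd = -I_m/(I_m+I_hd)^2.  Replicate estimates per ligand are
aggregated as mean / sample s.d. (s.d. 0 with a flag for n = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PeakIntensityRecord",
    "monomer_population",
    "monomer_population_error",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class PeakIntensityRecord:
    """One replicate's monomer/heterodimer peak-intensity pair."""

    ligand: str
    replicate: int
    i_monomer: float
    i_heterodimer: float
    e_monomer: float = 0.0
    e_heterodimer: float = 0.0

    def __post_init__(self) -> None:
        if self.i_monomer < 0 or self.i_heterodimer < 0:
            raise ValueError("peak intensities must be non-negative")
        if self.e_monomer < 0 or self.e_heterodimer < 0:
            raise ValueError("intensity uncertainties must be non-negative")
        if self.i_monomer + self.i_heterodimer <= 0:
            raise ValueError("at least one peak intensity must be positive")

    @property
    def population(self) -> float:
        return monomer_population(self.i_monomer, self.i_heterodimer)

    @property
    def population_error(self) -> float:
        return monomer_population_error(
            self.i_monomer, self.i_heterodimer, self.e_monomer, self.e_heterodimer
        )


def monomer_population(i_monomer: float, i_heterodimer: float) -> float:
    """Monomer fraction I_m / (I_m + I_hd); domain error if both are zero."""
    total = i_monomer + i_heterodimer
    if total <= 0:
        raise ValueError("monomer_population undefined: both intensities are zero")
    if i_monomer < 0 or i_heterodimer < 0:
        raise ValueError("intensities must be non-negative")
    return i_monomer / total


def monomer_population_error(
    i_monomer: float, i_heterodimer: float, e_monomer: float, e_heterodimer: float
) -> float:
    """First-order quadrature propagation of intensity errors to the population."""
    total = i_monomer + i_heterodimer
    if total <= 0:
        raise ValueError("error propagation undefined: both intensities are zero")
    return (
        math.hypot(i_heterodimer * e_monomer, i_monomer * e_heterodimer) / total**2
    )


def aggregate_replicates(records) -> pd.DataFrame:
    """Per-ligand mean/sd of replicate populations with propagated error.

    Parameters
    ----------
    records : iterable of PeakIntensityRecord or DataFrame
        A DataFrame must carry columns ``ligand, replicate, i_monomer,
        i_heterodimer`` and optionally ``e_monomer, e_heterodimer``.

    Returns
    -------
    DataFrame
        Index ``ligand``; columns ``pop_mean``, ``pop_sd`` (sample s.d.,
        0.0 for n = 1), ``pop_err`` (mean propagated error), ``n`` and a
        ``single_replicate`` flag.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        for col in ("e_monomer", "e_heterodimer"):
            if col not in df.columns:
                df[col] = 0.0
    else:
        records = list(records)
        if not records:
            raise ValueError("aggregate_replicates requires at least one record")
        df = pd.DataFrame(
            dict(
                ligand=[r.ligand for r in records],
                replicate=[r.replicate for r in records],
                i_monomer=[r.i_monomer for r in records],
                i_heterodimer=[r.i_heterodimer for r in records],
                e_monomer=[r.e_monomer for r in records],
                e_heterodimer=[r.e_heterodimer for r in records],
            )
        )
    if df.empty:
        raise ValueError("aggregate_replicates requires at least one record")

    df["pop"] = [
        monomer_population(im, ih) for im, ih in zip(df.i_monomer, df.i_heterodimer)
    ]
    df["err"] = [
        monomer_population_error(im, ih, em, eh)
        for im, ih, em, eh in zip(df.i_monomer, df.i_heterodimer, df.e_monomer, df.e_heterodimer)
    ]
    out = df.groupby("ligand", sort=False).agg(
        pop_mean=("pop", "mean"),
        pop_sd=("pop", lambda s: s.std(ddof=1) if len(s) > 1 else 0.0),
        pop_err=("err", "mean"),
        n=("pop", "size"),
    )
    out["single_replicate"] = out["n"] == 1
    return out
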