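"""Simulation and fitting of dilution and competition ITC experiments.

Two experiment types are modelled:

* **Dissociation-by-dilution** — concentrated self-associated protein (the
  RXRα LBD homodimer) is injected into buffer; each injection's heat comes
  from dimer dissociation on dilution.  Fitting recovers the homodimer
  ``K_D`` and association enthalpy.
* **Competition titration** — Nurr1 LBD (B, non-self-associating) is titrated
  into an RXRα LBD cell (A, homodimerizing); each injection's heat mixes
  heterodimer formation and homodimer perturbation.  Fitting with the
  homodimer parameters held fixed recovers the heterodimer ``log K_D`` and
  ``ΔH``.

Both simulators use the standard discrete displacement model for the
perfusion cell: injecting ``dV`` into working volume ``V0`` scales the
pre-existing cell contents by ``(1 - dV/V0)`` and adds syringe material at
``c_syr * dV / V0``; the displaced volume leaves at pre-injection
composition.  The measured heat of injection *i* is the enthalpy change of
re-equilibrating the post-mixing cell contents:

    q_i = 1e9 * sum_species dH_s * (n_s,after - n_s,mixed)   [µcal]

where ``n_s,mixed`` counts complex moles carried over from the (displaced)
cell plus those delivered by the syringe.

The fitting layer follows the model/results idiom: build ``DilutionITC`` or
``CompetitionITC`` from an :class:`Isotherm`, call ``fit()``, inspect the
returned results object (estimates, standard errors, residuals,
``summary()``).  The functional wrappers ``fit_dilution_heats`` /
``fit_competition_heats`` are retained for pipeline use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import lmfit
import numpy as np

from .equilibria import DEFAULT_DH_HOMO, DEFAULT_KD_HOMO, BindingParameters, solve_competition, solve_homodimer

__all__ = [
    "TitrationProtocol",
    "Isotherm",
    "simulate_dilution_heats",
    "simulate_competition_heats",
    "DilutionITC",
    "DilutionITCResults",
    "CompetitionITC",
    "CompetitionITCResults",
    "fit_dilution_heats",
    "fit_competition_heats",
    "delta_g_from_log_kd",
    "t_delta_s",
    "replicate_stats",
    "thermo_table",
]

UCAL_PER_KCAL = 1e9
R_KCAL = 1.9872e-3  # gas constant, kcal / (mol K)
LN10 = math.log(10.0)


@dataclass(frozen=True)
class TitrationProtocol:
    """Geometry and schedule of one ITC run.

    Defaults follow the published protocol: 20 × 2 µL injections into a
    200 µL working cell at 25 °C, syringe:cell concentration ratio 10:1 for
    the competition experiment (cell_conc = 0 for dilution runs).
    Concentrations are total monomer-equivalent, M.
    """

    syringe_conc: float
    cell_conc: float = 0.0
    cell_volume: float = 2.0e-4
    n_injections: int = 20
    injection_volume: float = 2.0e-6
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if self.cell_volume <= 0 or self.injection_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.n_injections < 1:
            raise ValueError("n_injections must be >= 1")
        if self.syringe_conc < 0 or self.cell_conc < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def injection_moles(self) -> np.ndarray:
        """Moles of injectant delivered per injection."""
        return np.full(self.n_injections, self.syringe_conc * self.injection_volume)


@dataclass(frozen=True)
class Isotherm:
    """Integrated per-injection heats with protocol metadata.

    ``heats`` are in µcal (instrument frame: positive = endothermic);
    ``normalized_heats`` are kcal per mole of injectant;
    ``molar_ratio`` is the cumulative injectant / cell-analyte mole ratio
    (cumulative injectant concentration in the cell for dilution runs).
    """

    heats: np.ndarray
    protocol: TitrationProtocol
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        heats = np.asarray(self.heats, dtype=float)
        if heats.shape != (self.protocol.n_injections,):
            raise ValueError(
                f"expected {self.protocol.n_injections} heats, got shape {heats.shape}"
            )
        object.__setattr__(self, "heats", heats)

    @property
    def normalized_heats(self) -> np.ndarray:
        """Heats per mole of injectant, kcal/mol."""
        return self.heats / (UCAL_PER_KCAL * self.protocol.injection_moles)

    @property
    def molar_ratio(self) -> np.ndarray:
        p = self.protocol
        f = p.injection_volume / p.cell_volume
        i = np.arange(1, p.n_injections + 1)
        keep = (1.0 - f) ** i
        # cumulative in-cell totals under the displacement model
        syr = p.syringe_conc * (1.0 - keep)
        if p.cell_conc > 0:
            return syr / (p.cell_conc * keep)
        return syr

    def with_noise(self, sd: float, rng: np.random.Generator) -> "Isotherm":
        """Return a copy with i.i.d. Gaussian noise (µcal) added to the heats."""
        noisy = self.heats + rng.normal(0.0, sd, size=self.heats.shape)
        return Isotherm(noisy, self.protocol, noise_sd=sd)


# ---------------------------------------------------------------------------
# forward simulation


def _dilution_complex_trace(protocol: TitrationProtocol, kd_homo: float):
    """Per-injection (A2_mixed, A2_after) concentrations for a dilution run."""
    p = protocol
    f = p.injection_volume / p.cell_volume
    syringe = solve_homodimer(p.syringe_conc, kd_homo)
    total = 0.0
    a2 = 0.0
    mixed = np.empty(p.n_injections)
    after = np.empty(p.n_injections)
    for i in range(p.n_injections):
        total = total * (1.0 - f) + p.syringe_conc * f
        mixed[i] = a2 * (1.0 - f) + syringe.conc_A2 * f
        a2 = solve_homodimer(total, kd_homo).conc_A2
        after[i] = a2
    return mixed, after


def simulate_dilution_heats(
    protocol: TitrationProtocol, kd_homo: float, dh_homo: float
) -> Isotherm:
    """Simulate a dissociation-by-dilution isotherm (noiseless).

    Heat of injection *i* is ``1e9 * dh_homo * V0 * (A2_after - A2_mixed)``
    µcal: with an exothermic association enthalpy, net dimer dissociation in
    the cell gives positive (endothermic) heats that decay as the cell
    concentration builds up.
    """
    if protocol.cell_conc != 0.0:
        raise ValueError("dilution protocol requires an empty cell (cell_conc = 0)")
    if protocol.syringe_conc <= 0:
        raise ValueError("dilution protocol requires syringe_conc > 0")
    mixed, after = _dilution_complex_trace(protocol, kd_homo)
    q = UCAL_PER_KCAL * dh_homo * protocol.cell_volume * (after - mixed)
    return Isotherm(q, protocol)


def _competition_complex_trace(protocol: TitrationProtocol, kd_homo: float, kd_het: float):
    """Per-injection mixed/after (A2, AB) concentrations for a competition run."""
    p = protocol
    f = p.injection_volume / p.cell_volume
    total_A = p.cell_conc
    total_B = 0.0
    state = solve_homodimer(total_A, kd_homo)
    a2, ab = state.conc_A2, 0.0
    mixed = np.empty((p.n_injections, 2))
    after = np.empty((p.n_injections, 2))
    for i in range(p.n_injections):
        total_A *= 1.0 - f
        total_B = total_B * (1.0 - f) + p.syringe_conc * f
        mixed[i] = (a2 * (1.0 - f), ab * (1.0 - f))  # syringe carries no complexes
        st = solve_competition(total_A, total_B, kd_homo, kd_het)
        a2, ab = st.conc_A2, st.conc_AB
        after[i] = (a2, ab)
    return mixed, after


def simulate_competition_heats(
    protocol: TitrationProtocol, params: BindingParameters
) -> Isotherm:
    """Simulate a Nurr1-into-RXRα competition isotherm (noiseless).

    Per injection, ``q_i = 1e9 * V0 * (dh_het * ΔAB + dh_homo * ΔA2)`` with
    displacement-then-re-equilibration bookkeeping.  For the published
    parameter regime (endothermic heterodimerization, exothermic
    homodimerization that is net dissociated by the titration) early heats
    are positive and decay toward the dilution baseline at saturation.
    """
    if protocol.cell_conc <= 0:
        raise ValueError("competition protocol requires analyte in the cell")
    mixed, after = _competition_complex_trace(protocol, params.kd_homo, params.kd_het)
    delta = after - mixed
    q = (
        UCAL_PER_KCAL
        * protocol.cell_volume
        * (params.dh_homo * delta[:, 0] + params.dh_het * delta[:, 1])
    )
    return Isotherm(q, protocol)


# ---------------------------------------------------------------------------
# thermodynamics helpers


def delta_g_from_log_kd(log_kd: float, temperature: float = 298.15) -> float:
    """Binding free energy ΔG = RT ln(10) log10(K_D), kcal/mol."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return R_KCAL * temperature * LN10 * log_kd


def t_delta_s(dh: float, log_kd: float, temperature: float = 298.15) -> float:
    """Entropic component TΔS = ΔH − ΔG, kcal/mol."""
    return dh - delta_g_from_log_kd(log_kd, temperature)


def replicate_stats(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample s.d. (n−1 denominator; 0.0 for n=1) and n of replicates."""
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("replicate_stats requires at least one value")
    n = int(vals.size)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def thermo_table(fits: dict[str, Sequence[tuple[float, float]]],
                 temperature: float = 298.15):
    """Build a per-ligand thermodynamic table from replicate (log_kd, dh) fits.

    Returns a DataFrame with mean/sd/n for log K_D, ΔH and the derived TΔS,
    mirroring the layout of a published ITC summary table.
    """
    import pandas as pd

    rows = []
    for ligand, reps in fits.items():
        log_kds = [r[0] for r in reps]
        dhs = [r[1] for r in reps]
        tdss = [t_delta_s(dh, lk, temperature) for lk, dh in zip(log_kds, dhs)]
        lk_m, lk_sd, n = replicate_stats(log_kds)
        dh_m, dh_sd, _ = replicate_stats(dhs)
        td_m, td_sd, _ = replicate_stats(tdss)
        rows.append(
            dict(ligand=ligand, log_kd_avg=lk_m, log_kd_sd=lk_sd, n=n,
                 dh_avg=dh_m, dh_sd=dh_sd, tds_avg=td_m, tds_sd=td_sd)
        )
    return pd.DataFrame(rows).set_index("ligand")


# ---------------------------------------------------------------------------
# fitting layer (model / results objects)

#: heats below this ceiling (µcal) are treated as a flat, unidentifiable isotherm
_FLAT_HEAT_UCAL = 1e-3


@dataclass
class _FitResultsBase:
    params: dict
    stderr: dict
    residuals: np.ndarray
    rss: float
    success: bool
    identifiable: bool
    message: str
    isotherm: Isotherm

    @property
    def nobs(self) -> int:
        return self.isotherm.heats.size

    def _summary_lines(self, title: str) -> list[str]:
        lines = [title, "=" * len(title)]
        lines.append(f"n injections      {self.nobs}")
        lines.append(f"identifiable      {self.identifiable}")
        lines.append(f"converged         {self.success}")
        lines.append(f"residual SS       {self.rss:.6g} µcal²")
        for name, val in self.params.items():
            se = self.stderr.get(name)
            se_txt = f" ± {se:.4g}" if se is not None and np.isfinite(se) else ""
            lines.append(f"{name:<17} {val:.6g}{se_txt}")
        return lines

    def summary(self) -> str:
        return "\n".join(self._summary_lines(type(self).__name__))


@dataclass
class DilutionITCResults(_FitResultsBase):
    """Estimates from a dissociation-by-dilution fit."""

    @property
    def kd_homo(self) -> float:
        return self.params["kd_homo"]

    @property
    def dh_homo(self) -> float:
        return self.params["dh_homo"]


@dataclass
class CompetitionITCResults(_FitResultsBase):
    """Estimates from a homodimer-competition fit (homodimer params fixed)."""

    @property
    def log_kd_het(self) -> float:
        return self.params["log_kd_het"]

    @property
    def dh_het(self) -> float:
        return self.params["dh_het"]

    @property
    def tds_het(self) -> float:
        return t_delta_s(self.dh_het, self.log_kd_het, self.isotherm.protocol.temperature)


class DilutionITC:
    """Dissociation-by-dilution model for one isotherm.

    Least-squares over (log10 K_D, ΔH) with Levenberg–Marquardt;
    K_D is log-parameterized for positivity.  Multi-start over a decade grid
    of K_D guesses; the linear role of ΔH in the heats gives its conditional
    optimum in closed form at each start.
    """

    _LOG_KD_STARTS = (-4.0, -5.0, -6.0)

    def __init__(self, isotherm: Isotherm):
        if isotherm.protocol.cell_conc != 0.0:
            raise ValueError("DilutionITC requires a dilution isotherm (empty cell)")
        self.isotherm = isotherm

    def _model_heats(self, log10_kd: float, dh: float) -> np.ndarray:
        return simulate_dilution_heats(self.isotherm.protocol, 10.0 ** log10_kd, dh).heats

    def fit(self, ftol: float = 1e-12) -> DilutionITCResults:
        q_obs = self.isotherm.heats
        if np.max(np.abs(q_obs)) < max(_FLAT_HEAT_UCAL, 3.0 * self.isotherm.noise_sd / 4.0):
            return DilutionITCResults(
                params={"kd_homo": math.nan, "dh_homo": math.nan},
                stderr={}, residuals=q_obs.copy(), rss=float(q_obs @ q_obs),
                success=False, identifiable=False,
                message="flat isotherm: homodimer parameters unidentifiable",
                isotherm=self.isotherm,
            )

        best = None
        for lk0 in self._LOG_KD_STARTS:
            basis = self._model_heats(lk0, 1.0)
            denom = float(basis @ basis)
            dh0 = float(basis @ q_obs) / denom if denom > 0 else -1.0
            pars = lmfit.Parameters()
            pars.add("log10_kd", value=lk0, min=-12.0, max=0.0)
            pars.add("dh", value=dh0 if dh0 != 0 else -1.0)

            def resid(p):
                return self._model_heats(p["log10_kd"].value, p["dh"].value) - q_obs

            out = lmfit.minimize(resid, pars, method="leastsq", ftol=ftol, xtol=ftol)
            rss = float(np.sum(out.residual**2))
            if best is None or rss < best[0]:
                best = (rss, out)
        rss, out = best
        lk = out.params["log10_kd"]
        dh = out.params["dh"]
        stderr = {}
        if lk.stderr is not None:
            stderr["kd_homo"] = 10.0 ** lk.value * LN10 * lk.stderr
        if dh.stderr is not None:
            stderr["dh_homo"] = dh.stderr
        return DilutionITCResults(
            params={"kd_homo": 10.0 ** lk.value, "dh_homo": dh.value},
            stderr=stderr, residuals=np.asarray(out.residual), rss=rss,
            success=bool(out.success), identifiable=True,
            message=out.message, isotherm=self.isotherm,
        )


class CompetitionITC:
    """Homodimer-competition model for one Nurr1-into-RXRα isotherm.

    The homodimer dissociation constant and enthalpy are supplied and held
    fixed (the same approximation used when fitting the published data); the
    free parameters are the heterodimer ``log10 K_D`` and ``ΔH``.  Because
    both enthalpies enter the heats linearly at fixed ``K_D``, each start's
    ``ΔH_het`` guess is the conditional linear least-squares optimum.
    """

    _LOG_KD_STARTS = (-4.0, -5.0, -6.0)

    def __init__(
        self,
        isotherm: Isotherm,
        kd_homo: float = DEFAULT_KD_HOMO,
        dh_homo: float = DEFAULT_DH_HOMO,
    ):
        if isotherm.protocol.cell_conc <= 0:
            raise ValueError("CompetitionITC requires analyte in the cell")
        self.isotherm = isotherm
        self.kd_homo = kd_homo
        self.dh_homo = dh_homo

    def _traces(self, log_kd_het: float):
        return _competition_complex_trace(
            self.isotherm.protocol, self.kd_homo, 10.0 ** log_kd_het
        )

    def _model_heats(self, log_kd_het: float, dh_het: float) -> np.ndarray:
        p = self.isotherm.protocol
        mixed, after = self._traces(log_kd_het)
        delta = after - mixed
        return UCAL_PER_KCAL * p.cell_volume * (
            self.dh_homo * delta[:, 0] + dh_het * delta[:, 1]
        )

    def fit(self, ftol: float = 1e-12) -> CompetitionITCResults:
        q_obs = self.isotherm.heats
        p = self.isotherm.protocol
        if np.max(np.abs(q_obs)) < _FLAT_HEAT_UCAL:
            return CompetitionITCResults(
                params={"log_kd_het": math.nan, "dh_het": math.nan},
                stderr={}, residuals=q_obs.copy(), rss=float(q_obs @ q_obs),
                success=False, identifiable=False,
                message="flat isotherm: heterodimer parameters unidentifiable",
                isotherm=self.isotherm,
            )

        best = None
        for lk0 in self._LOG_KD_STARTS:
            mixed, after = self._traces(lk0)
            delta = after - mixed
            homo_part = UCAL_PER_KCAL * p.cell_volume * self.dh_homo * delta[:, 0]
            het_basis = UCAL_PER_KCAL * p.cell_volume * delta[:, 1]
            denom = float(het_basis @ het_basis)
            dh0 = float(het_basis @ (q_obs - homo_part)) / denom if denom > 0 else 1.0
            pars = lmfit.Parameters()
            pars.add("log_kd_het", value=lk0, min=-12.0, max=0.0)
            pars.add("dh_het", value=dh0 if dh0 != 0 else 1.0)

            def resid(pr):
                return self._model_heats(pr["log_kd_het"].value, pr["dh_het"].value) - q_obs

            out = lmfit.minimize(resid, pars, method="leastsq", ftol=ftol, xtol=ftol)
            rss = float(np.sum(out.residual**2))
            if best is None or rss < best[0]:
                best = (rss, out)
            if rss < max(1e-12, 1e-10 * float(q_obs @ q_obs)):
                break  # essentially exact fit; further starts cannot improve
        rss, out = best
        lk = out.params["log_kd_het"]
        dh = out.params["dh_het"]
        stderr = {}
        if lk.stderr is not None:
            stderr["log_kd_het"] = lk.stderr
        if dh.stderr is not None:
            stderr["dh_het"] = dh.stderr
        return CompetitionITCResults(
            params={"log_kd_het": lk.value, "dh_het": dh.value},
            stderr=stderr, residuals=np.asarray(out.residual), rss=rss,
            success=bool(out.success), identifiable=True,
            message=out.message, isotherm=self.isotherm,
        )


def fit_dilution_heats(isotherm: Isotherm) -> DilutionITCResults:
    """Fit the dissociation-by-dilution model; see :class:`DilutionITC`."""
    return DilutionITC(isotherm).fit()


def fit_competition_heats(
    isotherm: Isotherm,
    kd_homo: float = DEFAULT_KD_HOMO,
    dh_homo: float = DEFAULT_DH_HOMO,
) -> CompetitionITCResults:
    """Fit the homodimer-competition model; see :class:`CompetitionITC`."""
    return CompetitionITC(isotherm, kd_homo=kd_homo, dh_homo=dh_homo).fit()
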