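"""ITC simulation, fitting and thermodynamic-decomposition correctness."""

import numpy as np
import pytest

from htdkit.equilibria import BindingParameters
from htdkit.itc import (
    CompetitionITC,
    DilutionITC,
    Isotherm,
    TitrationProtocol,
    delta_g_from_log_kd,
    fit_competition_heats,
    fit_dilution_heats,
    replicate_stats,
    simulate_competition_heats,
    simulate_dilution_heats,
    t_delta_s,
    thermo_table,
)
from htdkit.reference import HOMODIMER_DH, HOMODIMER_KD, reference_panel

DILUTION = TitrationProtocol(syringe_conc=1.0e-3)
COMPETITION = TitrationProtocol(syringe_conc=1.0e-3, cell_conc=1.0e-4)


def bookkeeping_dilution_oracle(protocol, kd, dh, oracle):
    """Independent per-injection mole bookkeeping using the bisection oracle."""
    f = protocol.injection_volume / protocol.cell_volume
    _, d_syr = oracle(protocol.syringe_conc, kd)
    total, d = 0.0, 0.0
    heats = []
    for _ in range(protocol.n_injections):
        total = total * (1 - f) + protocol.syringe_conc * f
        mixed = d * (1 - f) + d_syr * f
        _, d = oracle(total, kd)
        heats.append(1e9 * dh * protocol.cell_volume * (d - mixed))
    return np.array(heats)


class TestDilutionSimulation:
    def test_zero_enthalpy_gives_zero_heats(self):
        iso = simulate_dilution_heats(DILUTION, 1.63e-5, 0.0)
        assert np.all(iso.heats == 0.0)

    def test_monomeric_syringe_gives_tiny_heats(self):
        ref = simulate_dilution_heats(DILUTION, 1.63e-5, -13.10)
        weak = simulate_dilution_heats(DILUTION, 1.0, -13.10)
        assert np.all(np.abs(weak.heats) < 0.05 * np.abs(ref.heats))

    def test_matches_mole_bookkeeping_oracle(self, homodimer_oracle):
        iso = simulate_dilution_heats(DILUTION, 1.63e-5, -13.10)
        expected = bookkeeping_dilution_oracle(DILUTION, 1.63e-5, -13.10, homodimer_oracle)
        np.testing.assert_allclose(iso.heats, expected, rtol=1e-8)
        # endothermic dissociation signal, ~6.5 µcal first injection, decaying
        assert iso.heats[0] == pytest.approx(6.5, abs=0.2)
        assert np.all(iso.heats > 0)
        assert np.all(np.diff(iso.heats) < 0)

    def test_heat_telescoping(self):
        """Cumulative heat equals dh * (dimer delivered - dimer surviving)."""
        from htdkit.equilibria import solve_homodimer
        from htdkit.itc import _dilution_complex_trace

        kd, dh = 1.63e-5, -13.10
        iso = simulate_dilution_heats(DILUTION, kd, dh)
        f = DILUTION.injection_volume / DILUTION.cell_volume
        d_syr = solve_homodimer(DILUTION.syringe_conc, kd).conc_A2
        _, after = _dilution_complex_trace(DILUTION, kd)
        n = DILUTION.n_injections
        delivered = n * f * d_syr
        # dimer surviving: in the cell at the end plus in displaced aliquots
        surviving = after[-1] + f * after[:-1].sum()
        total_heat = 1e9 * dh * DILUTION.cell_volume * (surviving - delivered)
        assert iso.heats.sum() == pytest.approx(total_heat, rel=1e-6)

    def test_cell_analyte_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_heats(COMPETITION, 1e-5, -13.0)


class TestDilutionFit:
    def test_noiseless_round_trip_recovers_published_homodimer(self):
        iso = simulate_dilution_heats(DILUTION, HOMODIMER_KD, HOMODIMER_DH)
        res = fit_dilution_heats(iso)
        assert res.identifiable
        assert abs(np.log10(res.kd_homo) - np.log10(HOMODIMER_KD)) < 0.01
        assert abs(res.dh_homo - HOMODIMER_DH) < 0.005 * abs(HOMODIMER_DH)

    def test_noisy_round_trip_within_repeat_tolerance(self, rng):
        iso = simulate_dilution_heats(DILUTION, HOMODIMER_KD, HOMODIMER_DH)
        noisy = iso.with_noise(0.2, rng)
        res = DilutionITC(noisy).fit()
        assert abs(np.log10(res.kd_homo) - np.log10(HOMODIMER_KD)) < 0.1

    def test_flat_isotherm_flagged_unidentifiable(self):
        iso = Isotherm(np.zeros(20), DILUTION)
        res = fit_dilution_heats(iso)
        assert not res.identifiable
        assert np.isnan(res.params["kd_homo"])

    def test_summary_mentions_estimates(self):
        res = fit_dilution_heats(simulate_dilution_heats(DILUTION, 1.63e-5, -13.10))
        text = res.summary()
        assert "kd_homo" in text and "dh_homo" in text


class TestCompetitionSimulation:
    def test_zero_enthalpies_give_zero_heats(self):
        params = BindingParameters(dh_homo=0.0, log_kd_het=-5.335, dh_het=0.0)
        iso = simulate_competition_heats(COMPETITION, params)
        np.testing.assert_allclose(iso.heats, 0.0, atol=1e-12)

    def test_no_binding_limit_is_nearly_flat(self):
        params = BindingParameters(log_kd_het=0.0, dh_het=2.9)
        iso = simulate_competition_heats(COMPETITION, params)
        assert np.max(np.abs(iso.heats)) < 0.2  # residual cell-dilution signal only

    def test_published_vehicle_regime_endothermic_with_oracle_bookkeeping(
        self, equilibrium_oracle
    ):
        params = BindingParameters(log_kd_het=-5.335, dh_het=2.900)
        iso = simulate_competition_heats(COMPETITION, params)
        assert np.all(iso.heats[:5] > 0)
        assert iso.heats[0] > iso.heats[-1]
        # independent per-injection bookkeeping via the nested-bisection oracle
        f = COMPETITION.injection_volume / COMPETITION.cell_volume
        ta, tb = COMPETITION.cell_conc, 0.0
        _, a2, _, ab = equilibrium_oracle(ta, 0.0, params.kd_homo, params.kd_het)
        expected = []
        for _ in range(COMPETITION.n_injections):
            ta *= 1 - f
            tb = tb * (1 - f) + COMPETITION.syringe_conc * f
            a2_mix, ab_mix = a2 * (1 - f), ab * (1 - f)
            _, a2, _, ab = equilibrium_oracle(ta, tb, params.kd_homo, params.kd_het)
            expected.append(
                1e9
                * COMPETITION.cell_volume
                * (params.dh_homo * (a2 - a2_mix) + params.dh_het * (ab - ab_mix))
            )
        np.testing.assert_allclose(iso.heats, expected, rtol=1e-6)

    def test_normalized_heats_use_injectant_moles(self):
        params = BindingParameters(log_kd_het=-5.335, dh_het=2.900)
        iso = simulate_competition_heats(COMPETITION, params)
        moles = COMPETITION.syringe_conc * COMPETITION.injection_volume
        np.testing.assert_allclose(
            iso.normalized_heats, iso.heats / (1e9 * moles), rtol=1e-9
        )


class TestCompetitionFit:
    @pytest.mark.parametrize(
        "ligand, log_kd, dh",
        [("DMSO", -5.335, 2.900), ("BRF110", -4.376, 5.365)],
    )
    def test_round_trip_recovers_published_fits(self, ligand, log_kd, dh):
        params = BindingParameters(log_kd_het=log_kd, dh_het=dh)
        iso = simulate_competition_heats(COMPETITION, params)
        res = fit_competition_heats(iso)
        assert res.log_kd_het == pytest.approx(log_kd, abs=1e-3)
        assert res.dh_het == pytest.approx(dh, abs=1e-3)

    def test_round_trip_every_reference_ligand(self):
        """Noiseless round trips recover every reference parameter set within 0.01."""
        ref = reference_panel()
        for ligand, row in ref.iterrows():
            params = BindingParameters(log_kd_het=row.log_kd_avg, dh_het=row.dh_avg)
            res = fit_competition_heats(simulate_competition_heats(COMPETITION, params))
            assert abs(res.log_kd_het - row.log_kd_avg) < 0.01, ligand

    def test_fisher_consistency_under_noise(self, rng):
        """Median fitted logK_D over noisy replicates sits within 0.05 of truth."""
        params = BindingParameters(log_kd_het=-5.335, dh_het=2.900)
        clean = simulate_competition_heats(COMPETITION, params)
        fits = [
            fit_competition_heats(clean.with_noise(0.2, rng)).log_kd_het
            for _ in range(100)
        ]
        assert abs(np.median(fits) - (-5.335)) < 0.05

    def test_wrong_fixed_homodimer_biases_heterodimer_affinity(self):
        """Sensitivity to the fixed-homodimer approximation: a 10x wrong K_D shifts the fit."""
        params = BindingParameters(log_kd_het=-5.335, dh_het=2.900)
        iso = simulate_competition_heats(COMPETITION, params)
        biased = fit_competition_heats(iso, kd_homo=1.63e-4, dh_homo=-13.10)
        assert abs(biased.log_kd_het - (-5.335)) > 0.05

    def test_flat_isotherm_flagged(self):
        res = fit_competition_heats(Isotherm(np.zeros(20), COMPETITION))
        assert not res.identifiable


class TestThermodynamics:
    def test_delta_g_reference_state_is_zero(self):
        assert delta_g_from_log_kd(0.0, 298.15) == 0.0

    @pytest.mark.parametrize(
        "log_kd, expected", [(-5.335, -7.279), (-6.132, -8.366)]
    )
    def test_delta_g_closed_form(self, log_kd, expected):
        # expected values carry the rounding of the 3-decimal source table
        assert delta_g_from_log_kd(log_kd, 298.15) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "dh, log_kd, expected",
        [(2.900, -5.335, 10.179), (5.365, -4.376, 11.335)],
    )
    def test_entropy_decomposition_matches_published_rows(self, dh, log_kd, expected):
        assert t_delta_s(dh, log_kd, 298.15) == pytest.approx(expected, abs=1e-3)

    def test_isoenthalpic_isoergonic_case(self):
        dg = delta_g_from_log_kd(-5.0, 298.15)
        assert t_delta_s(dg, -5.0, 298.15) == 0.0

    def test_reference_table_internal_consistency(self):
        """TΔS = ΔH − ΔG reproduces every printed average except the flagged row."""
        ref = reference_panel()
        for ligand, row in ref.iterrows():
            recomputed = t_delta_s(row.dh_avg, row.log_kd_avg, 298.15)
            if row.tds_inconsistent:
                assert abs(recomputed - row.tds_avg) > 1.0  # documented discrepancy
            else:
                assert recomputed == pytest.approx(row.tds_avg, abs=0.01), ligand


class TestReplicateStats:
    def test_published_vehicle_pair(self):
        mean, sd, n = replicate_stats([-5.418, -5.252])
        assert mean == pytest.approx(-5.335, abs=5e-4)
        assert sd == pytest.approx(0.118, abs=1e-3)
        assert n == 2

    def test_single_replicate_convention(self):
        mean, sd, n = replicate_stats([-4.673])
        assert (mean, sd, n) == (-4.673, 0.0, 1)

    def test_identical_replicates_zero_sd(self):
        assert replicate_stats([1.5, 1.5])[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_stats([])

    def test_thermo_table_aggregates_replicates(self):
        table = thermo_table({"X": [(-5.4, 2.9), (-5.3, 3.1)]})
        assert table.loc["X", "n"] == 2
        assert table.loc["X", "log_kd_avg"] == pytest.approx(-5.35)
        assert table.loc["X", "tds_avg"] == pytest.approx(
            np.mean([t_delta_s(2.9, -5.4), t_delta_s(3.1, -5.3)])
        )
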