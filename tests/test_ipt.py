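"""Isotope-pairing partition, r-IPT validity checks and anammox estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nitracer import (
    Analyte,
    IncubationSeries,
    IsotopologueRate,
    IsotopologueRates,
    PanelFlag,
    RunConfig,
    TrueParameters,
    ValidationError,
    anammox_rate,
    independence_check,
    ipt_partition,
    isotopologue_slopes,
    pair_production_rates,
    pairing_consistency,
    pairing_excess,
    simulate_n2_series,
)

NAN = float("nan")


def rates(p29, p30, p28=None, se=0.0, p=NAN):
    mk = lambda r: IsotopologueRate(rate=r, se=se, p_value=p)  # noqa: E731
    return IsotopologueRates(
        p29=mk(p29), p30=mk(p30), p28=None if p28 is None else mk(p28)
    )


def rates_from_simulation(params, treatment="no3", geom=None):
    ser = simulate_n2_series(params, treatment=treatment)
    return isotopologue_slopes(
        ser[Analyte.N2_29], ser[Analyte.N2_30], geom, series28=ser[Analyte.N2_28]
    )


class TestIptPartition:
    def test_binomial_pairing_panel(self):
        # binomial split of D_a = 100 N atoms at ε = 0.6: p29 = 24, p30 = 18
        panel = ipt_partition(rates(24.0, 18.0), epsilon_w=0.6)
        assert panel.d15 == pytest.approx(60.0)
        assert panel.d14 == pytest.approx(40.0)
        assert panel.d_tot == pytest.approx(100.0)

    def test_all_water_fuelled_when_epsilon_matches(self):
        panel = ipt_partition(rates(24.0, 18.0), epsilon_w=0.6)
        assert panel.d_w == pytest.approx(100.0)
        assert panel.d_n == pytest.approx(0.0)

    def test_pure_label_boundary(self):
        # ε = 1: no ¹⁴N to pair with, so p29 = 0 and D_tot = D15
        panel = ipt_partition(rates(0.0, 50.0), epsilon_w=1.0)
        assert panel.d14 == pytest.approx(0.0)
        assert panel.d_tot == pytest.approx(panel.d15) == pytest.approx(100.0)

    def test_zero_p30_gives_undefined_d14_flag(self):
        panel = ipt_partition(rates(24.0, 0.0), epsilon_w=0.6)
        assert PanelFlag.UNDEFINED_D14 in panel.flags
        assert panel.d15 == pytest.approx(24.0)
        assert math.isnan(panel.d14)

    def test_nonsignificant_panel_zeroed_with_flag(self):
        panel = ipt_partition(rates(24.0, 18.0, p=0.5), epsilon_w=0.6)
        assert not panel.significant
        assert PanelFlag.NOT_SIGNIFICANT in panel.flags
        assert panel.d_tot == 0.0

    def test_zero_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            ipt_partition(rates(24.0, 18.0), epsilon_w=0.0)

    @given(
        d_a=st.floats(1.0, 500.0),
        eps=st.floats(0.05, 0.95),
        eps_w=st.floats(0.05, 1.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_identities(self, d_a, eps, eps_w):
        """D_tot = D14 + D15 and D_w + D_n = D_tot hold bit-wise sans flooring."""
        p29 = d_a * eps * (1 - eps)
        p30 = d_a / 2 * eps**2
        panel = ipt_partition(rates(p29, p30), epsilon_w=eps_w)
        assert panel.d_tot == panel.d14 + panel.d15
        if PanelFlag.DN_FLOORED not in panel.flags:
            assert panel.d_w + panel.d_n == panel.d_tot


class TestIsotopologueSlopes:
    def test_noiseless_slope_scaled_by_geometry(self, core):
        t = (0.0, 1.5, 3.0)
        s29 = IncubationSeries("C1", Analyte.N2_29, t, tuple(1.0 + 0.2 * x for x in t))
        s30 = IncubationSeries("C1", Analyte.N2_30, t, tuple(0.5 + 0.1 * x for x in t))
        r = isotopologue_slopes(s29, s30, core)
        scale = core.water_volume_l / core.sediment_area_m2
        assert r.p29.rate == pytest.approx(0.2 * scale, rel=1e-9)
        assert r.p30.rate == pytest.approx(0.1 * scale, rel=1e-9)
        assert r.normalizer == "areal"

    def test_flat_series_zero_rates_p_one(self):
        t = (0.0, 3.0, 6.0, 8.0)
        s29 = IncubationSeries("V1", Analyte.N2_29, t, (1.0,) * 4)
        s30 = IncubationSeries("V1", Analyte.N2_30, t, (0.5,) * 4)
        r = isotopologue_slopes(s29, s30)
        assert r.p29.rate == 0.0
        assert r.p30.rate == 0.0
        assert r.p29.p_value == pytest.approx(1.0)

    def test_simulator_forward_oracle(self, noiseless_params):
        """Noiseless binomial pairing at D_a = 100, ε = 0.6 → 8:24:18 split."""
        import dataclasses

        p = dataclasses.replace(noiseless_params, d_a=100.0, epsilon=0.6)
        ser = simulate_n2_series(p)
        v = p.vessel.water_volume_l
        slopes = {}
        for a, s in ser.items():
            slopes[a] = np.polyfit(s.times, s.concentrations, 1)[0] * 1000 * v
        assert slopes[Analyte.N2_28] == pytest.approx(8.0, rel=1e-6)
        assert slopes[Analyte.N2_29] == pytest.approx(24.0, rel=1e-6)
        assert slopes[Analyte.N2_30] == pytest.approx(18.0, rel=1e-6)


class TestPairingConsistency:
    def test_binomial_input_gives_unity(self):
        r = rates(24.0, 18.0, p28=8.0)
        assert pairing_consistency(r) == pytest.approx(1.0)

    def test_anammox_drives_ratio_above_one(self, noiseless_params):
        import dataclasses

        p = dataclasses.replace(noiseless_params, d_a=100.0, amx_a=20.0)
        r = rates_from_simulation(p)
        assert pairing_consistency(r) > 1.0
        excess, se = pairing_excess(r)
        assert excess > 0
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_excess_is_zero_under_pure_denitrification(self, noiseless_params):
        r = rates_from_simulation(noiseless_params)
        excess, _ = pairing_excess(r)
        assert excess == pytest.approx(0.0, abs=1e-9)


class TestIndependenceCheck:
    def _panel(self, eps, params):
        import dataclasses

        p = dataclasses.replace(params, epsilon=eps)
        r = rates_from_simulation(p)
        return ipt_partition(r, eps), r

    def test_identical_panels_pass(self):
        panel = ipt_partition(rates(24.0, 18.0), 0.6)
        rep = independence_check(panel, panel, tol=0.25)
        assert rep.passed
        assert rep.dtot_rel_diff == pytest.approx(0.0)

    def test_relative_difference_beyond_tolerance_fails(self):
        low = ipt_partition(rates(24.0, 18.0), 0.6)  # D_tot = 100
        high = ipt_partition(rates(33.6, 25.2), 0.6)  # D_tot = 140
        rep = independence_check(low, high, tol=0.25)
        assert not rep.passed
        assert rep.dtot_rel_diff == pytest.approx(40.0 / 120.0)

    def test_nonsignificant_panel_skips_check(self):
        sig = ipt_partition(rates(24.0, 18.0), 0.6)
        nonsig = ipt_partition(rates(24.0, 18.0, p=0.9), 0.6)
        rep = independence_check(sig, nonsig)
        assert PanelFlag.CHECK_SKIPPED in rep.flags
        assert not rep.passed

    def test_pure_denitrification_passes_across_epsilon_grid(self, noiseless_params):
        panels = {eps: self._panel(eps, noiseless_params) for eps in (0.3, 0.6, 0.9)}
        (pl, rl), (ph, rh) = panels[0.3], panels[0.9]
        rep = independence_check(pl, ph, rates_low=rl, rates_high=rh)
        assert rep.passed
        # D_tot itself is ε-invariant
        d_tots = [p.d_tot for p, _ in panels.values()]
        assert max(d_tots) == pytest.approx(min(d_tots), rel=1e-9)

    def test_injected_anammox_fails_validity_check(self, noiseless_params):
        import dataclasses

        p = dataclasses.replace(noiseless_params, d_a=100.0, amx_a=20.0)
        panels = {}
        for eps in (0.3, 0.9):
            q = dataclasses.replace(p, epsilon=eps)
            r = rates_from_simulation(q)
            panels[eps] = (ipt_partition(r, eps), r)
        (pl, rl), (ph, rh) = panels[0.3], panels[0.9]
        rep = independence_check(pl, ph, rates_low=rl, rates_high=rh)
        assert not rep.passed
        assert rep.pairing_ratio_low > 1.0


class TestAnammoxRate:
    def test_zero_p29_means_no_detection(self):
        res = anammox_rate(rates(0.0, 0.0), f_a=0.5)
        assert not res.detected
        assert res.rate_n2 == 0.0

    def test_labeled_fraction_scaling(self):
        res = anammox_rate(rates(1.0, 0.0), f_a=0.5)
        assert res.rate_n2 == pytest.approx(2.0)
        assert res.rate_n == pytest.approx(4.0)

    def test_nonsignificant_slope_reports_zero(self):
        res = anammox_rate(rates(1.0, 0.0, p=0.8), f_a=0.5)
        assert not res.detected
        assert res.rate_n2 == 0.0

    def test_zero_fa_rejected(self):
        with pytest.raises(ValidationError):
            anammox_rate(rates(1.0, 0.0), f_a=0.0)

    def test_simulated_anammox_recovered_from_nh4_treatment(self, noiseless_params):
        import dataclasses

        p = dataclasses.replace(noiseless_params, d_a=50.0, amx_a=10.0, f_a=0.86)
        geom = p.vessel
        r = rates_from_simulation(p, treatment="nh4", geom=geom)
        res = anammox_rate(r, p.f_a)
        # truth on the biomass basis: amx_a nmol N/h over the animal biomass
        assert res.rate_n == pytest.approx(p.amx_a / geom.biomass_sfdw_g, rel=1e-6)

    def test_noisy_anammox_recovery_within_monte_carlo_error(self):
        import dataclasses

        base = TrueParameters(d_a=50.0, amx_a=10.0, noise_cv=0.05)
        estimates = []
        for i in range(200):
            p = dataclasses.replace(base, seed=10_000 + i)
            r = rates_from_simulation(p, treatment="nh4", geom=p.vessel)
            estimates.append(anammox_rate(r, p.f_a).rate_n)
        est = np.asarray(estimates)
        truth = base.amx_a / base.vessel.biomass_sfdw_g
        se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - truth) < 3 * se + 1e-9
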