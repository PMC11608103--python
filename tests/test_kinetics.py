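"""Rate laws (temperature / moisture / water-table factors, TST, Monod) and
the Crank-Nicolson reaction integrator."""

import numpy as np
import pytest

from bucketrt.chem import EnvParams, ReactionDef, build_network, parse_database
from bucketrt.kinetics import (
    RateContext,
    SEC_PER_DAY,
    env_factor_Sw,
    env_factor_T,
    env_factor_Zw,
    integrate_zone_reactions,
    kinetic_rate,
    rate_breakdown,
)
from bucketrt.speciation import EquilibriumSystem, speciate


class TestEnvFactors:
    @pytest.mark.parametrize("temp", [5.0, 15.0, 25.0])
    def test_q10_of_one_disables_temperature_dependence(self, temp):
        assert env_factor_T(temp, q10=1.0) == 1.0

    def test_reference_temperature_gives_unity(self):
        for q10 in (0.5, 1.0, 2.3, 5.0):
            assert env_factor_T(20.0, q10) == 1.0

    def test_exponent_exactly_one(self):
        assert env_factor_T(30.0, 2.3) == pytest.approx(2.3)
        # printed absolute-value form: same factor 10 degC below reference
        assert env_factor_T(10.0, 2.3) == pytest.approx(2.3)
        # signed alternative decreases below the reference instead
        assert env_factor_T(10.0, 2.3, signed=True) == pytest.approx(1 / 2.3)

    def test_moisture_peak_at_critical_saturation(self):
        for swc in (0.3, 0.7, 1.0):
            assert env_factor_Sw(swc, swc, n=1.4) == 1.0

    def test_moisture_exponent_zero_disables_dependence(self):
        for sw in (0.0, 0.31, 0.99):
            assert env_factor_Sw(sw, swc=0.7, n=0.0) == 1.0

    def test_moisture_power_law_value(self):
        # sw/swc = 0.5 below the optimum, exponent 0.8
        assert env_factor_Sw(0.35, 0.7, 0.8) == pytest.approx(0.5 ** 0.8)

    def test_water_table_factor_unity_cases(self):
        assert env_factor_Zw(3.2, alpha_beta=0.0) == 1.0
        assert env_factor_Zw(0.0, alpha_beta=1.7) == 1.0

    def test_water_table_factor_strictly_decreasing_for_positive_product(self):
        zws = np.linspace(0.0, 5.0, 11)
        vals = [env_factor_Zw(z, 0.8) for z in zws]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[3] == pytest.approx(np.exp(-0.8 * zws[3]))


def _toy_system(extra_rxn=None, keq_text=""):
    db = parse_database("S(s) = A : logK=0.0\n" + keq_text)
    cfg = {
        "species": {"primary": ["A", "B"], "solid": ["S(s)"]},
        "kinetics": {"SZ": [dict(
            name="consume", signature="S(s) + A = 0.7 B", rate="monod",
            log10_k=-9.0, ssa=1.0, substrate_density=1.0,
            monod={"A": 1e-4},
        )] + ([extra_rxn] if extra_rxn else [])},
    }
    net = build_network(cfg, db)
    sys = EquilibriumSystem.from_network(net, "SZ")
    return net, sys


def _ctx(**kw):
    base = dict(temp=20.0, sw=0.7, zw=0.5, dt=1.0, water_volume=300.0)
    base.update(kw)
    return RateContext(**base)


class TestRateLaws:
    def test_tst_rate_vanishes_at_equilibrium_and_reverses_beyond(
            self, carbon_network, carbon_sz_system):
        rxn = next(r for r in carbon_network.kinetic_by_zone["SZ"]
                   if r.id == "Carbonate_SZ")
        ctx = _ctx()
        # find totals that straddle equilibrium: IAP = a(Ca)^1.1 a(HCO3)^0.5
        base = {"DOC": 1e-5, "HCO3-": 2e-4, "H+": 1e-5, ">X": 0.0}
        lo = speciate(dict(base, **{"Ca++": 1e-7}), carbon_sz_system)
        hi = speciate(dict(base, **{"Ca++": 5e-3}), carbon_sz_system)
        assert kinetic_rate(rxn, lo, ctx, area=1.0) > 0      # dissolution
        assert kinetic_rate(rxn, hi, ctx, area=1.0) < 0      # precipitation
        # at IAP exactly Keq the saturation term is zero
        ca_eq = 10.0 ** ((rxn.log10_keq
                          - 0.5 * np.log10(lo.conc["HCO3-"])) / 1.1)
        eq = speciate(dict(base, **{"Ca++": ca_eq}), carbon_sz_system,
                      guess=lo.conc)
        bd = rate_breakdown(rxn, eq, ctx, area=1.0)
        assert bd.saturation_term == pytest.approx(0.0, abs=1e-6)

    def test_monod_half_saturation_gives_half_maximal_rate(self):
        net, sys = _toy_system()
        rxn = net.kinetic_by_zone["SZ"][0]
        st_ = speciate({"A": 1e-4, "B": 0.0}, sys)  # A at its KM
        r = kinetic_rate(rxn, st_, _ctx(), area=1.0)
        k_day = 10.0 ** -9.0 * SEC_PER_DAY
        # the availability guard contributes at most 1e-5 relative here
        assert r == pytest.approx(k_day / 2.0, rel=1e-4)

    def test_rates_scale_linearly_in_area_and_rate_constant(self):
        net, sys = _toy_system()
        rxn = net.kinetic_by_zone["SZ"][0]
        st_ = speciate({"A": 5e-4, "B": 0.0}, sys)
        r1 = kinetic_rate(rxn, st_, _ctx(), area=2.0)
        r2 = kinetic_rate(rxn, st_, _ctx(), area=4.0)
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)
        bumped = ReactionDef(
            id=rxn.id, kind=rxn.kind, stoichiometry=rxn.stoichiometry,
            log10_k=rxn.log10_k + 1.0, ssa=rxn.ssa, monod_terms=rxn.monod_terms,
            env=rxn.env,
        )
        assert kinetic_rate(bumped, st_, _ctx(), area=2.0) == pytest.approx(
            10.0 * r1, rel=1e-12)

    def test_inhibition_term_suppresses_rate(self):
        net, sys = _toy_system()
        rxn = net.kinetic_by_zone["SZ"][0]
        inhibited = ReactionDef(
            id="inh", kind=rxn.kind, stoichiometry=rxn.stoichiometry,
            log10_k=rxn.log10_k, monod_terms=rxn.monod_terms,
            inhibition_terms={"B": 1e-5}, env=rxn.env,
        )
        st_ = speciate({"A": 5e-4, "B": 9e-5}, sys)
        bd = rate_breakdown(inhibited, st_, _ctx(), area=1.0)
        assert bd.inhibition_term == pytest.approx(1e-5 / (9e-5 + 1e-5))

    def test_tst_without_keq_is_rejected_at_definition(self):
        with pytest.raises(Exception, match="[Kk]eq"):
            ReactionDef(id="bad", kind="kinetic-tst",
                        stoichiometry={"A": 1.0}, log10_k=-9.0)


class TestIntegrator:
    def test_zero_rate_constant_leaves_state_unchanged(self):
        net, sys = _toy_system()
        rxn = net.kinetic_by_zone["SZ"][0]
        dead = ReactionDef(
            id=rxn.id, kind=rxn.kind, stoichiometry=rxn.stoichiometry,
            log10_k=-300.0, monod_terms=rxn.monod_terms, env=rxn.env,
        )
        totals = {"A": 3e-4, "B": 1e-5}
        st_, rates = integrate_zone_reactions(totals, [dead], _ctx(), sys,
                                              {"consume": 1.0})
        assert rates["consume"] == pytest.approx(0.0, abs=1e-200)
        assert st_.totals["A"] == pytest.approx(3e-4, rel=1e-12)
        assert st_.totals["B"] == pytest.approx(1e-5, rel=1e-12)

    def test_stoichiometric_coupling_is_exact(self):
        """For S(s) + A -> 0.7 B the product gain is exactly 0.7x the
        reactant loss, whatever the rate history."""
        net, sys = _toy_system()
        totals = {"A": 3e-4, "B": 1e-5}
        st_, rates = integrate_zone_reactions(
            totals, net.kinetic_by_zone["SZ"], _ctx(dt=2.0), sys,
            {"consume": 50.0})
        d_a = st_.totals["A"] - totals["A"]
        d_b = st_.totals["B"] - totals["B"]
        assert d_a < 0
        assert d_b == pytest.approx(-0.7 * d_a, rel=1e-12)
        # and the reported mean rate reproduces the increments exactly
        vw = 300.0
        assert d_a == pytest.approx(-rates["consume"] * 2.0 / vw, rel=1e-12)

    def test_matches_fine_step_explicit_reference_on_stiff_toy(self):
        """Fast Monod consumption integrated with 10,000 explicit sub-steps
        serves as the reference for one daily Crank-Nicolson step."""
        net, sys = _toy_system()
        rxn = net.kinetic_by_zone["SZ"][0]
        area = 2000.0  # fast: consumes a large share of A within a day
        totals = {"A": 3e-4, "B": 0.0}
        ctx = _ctx()

        k_day = 10.0 ** rxn.log10_k * SEC_PER_DAY * area
        km = 1e-4
        a = totals["A"]
        bb = totals["B"]
        n = 10_000
        h = ctx.dt / n
        for _ in range(n):
            guard = a / (a + 1e-9)
            r = k_day * (a / (a + km)) * guard
            a -= r * h / ctx.water_volume
            bb += 0.7 * r * h / ctx.water_volume
        st_, _ = integrate_zone_reactions(totals, [rxn], ctx, sys,
                                          {"consume": area})
        assert st_.totals["A"] == pytest.approx(a, rel=1e-3)
        assert st_.totals["B"] == pytest.approx(bb, rel=1e-3)

    def test_crank_nicolson_is_second_order_on_smooth_toy(self):
        """Halving dt must shrink the end-state error ~4x (O(dt^2))."""
        net, sys = _toy_system()
        base = net.kinetic_by_zone["SZ"][0]
        # a half-saturation above the pool makes the decay visibly curved,
        # so truncation error dominates solver noise; the turnover stays
        # below the integrator's accuracy-halving threshold
        rxn = ReactionDef(
            id=base.id, kind=base.kind, stoichiometry=base.stoichiometry,
            log10_k=base.log10_k, monod_terms={"A": 5e-4}, env=base.env,
        )
        area = 500.0
        totals = {"A": 3e-4, "B": 0.0}

        def end_state(dt_total, n_steps):
            t = dict(totals)
            st_ = None
            for _ in range(n_steps):
                st_, _ = integrate_zone_reactions(
                    t, [rxn], _ctx(dt=dt_total / n_steps), sys,
                    {"consume": area})
                t = dict(st_.totals)
            return st_.totals["A"]

        ref = end_state(1.0, 256)
        ns = np.array([1, 2, 4, 8])
        errs = np.array([abs(end_state(1.0, int(n)) - ref) for n in ns])
        assert np.all(errs > 0)
        slope = np.polyfit(np.log(1.0 / ns), np.log(errs), 1)[0]
        # second-order convergence (allowing higher-order contamination at
        # the coarsest steps, which pushes the apparent slope slightly up)
        assert 1.7 < slope < 3.2

    def test_solid_monod_term_uses_prescribed_substrate_availability(self):
        db = parse_database("S(s) = A : logK=0.0\n")
        net = build_network({
            "species": {"primary": ["A"], "solid": ["S(s)"]},
            "kinetics": {"SZ": [dict(
                name="produce", signature="S(s) = A", rate="monod",
                log10_k=-9.0, monod={"S(s)": 6e-6},
            )]},
        }, db)
        sys = EquilibriumSystem.from_network(net, "SZ")
        st_ = speciate({"A": 1e-6}, sys)
        r_rich = kinetic_rate(net.kinetic_by_zone["SZ"][0], st_,
                              _ctx(substrate_conc={"S(s)": 1e-2}), 1.0)
        r_poor = kinetic_rate(net.kinetic_by_zone["SZ"][0], st_,
                              _ctx(substrate_conc={"S(s)": 6e-6}), 1.0)
        assert r_rich == pytest.approx(2 * r_poor * (1e-2 / (1e-2 + 6e-6)),
                                       rel=1e-9)
        with pytest.raises(KeyError, match="availability"):
            kinetic_rate(net.kinetic_by_zone["SZ"][0], st_, _ctx(), 1.0)

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            _ctx(sw=1.2)
        with pytest.raises(ValueError):
            _ctx(zw=-0.1)
        with pytest.raises(ValueError):
            _ctx(dt=0.0)
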