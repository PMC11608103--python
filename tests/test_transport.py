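"""Snow chemistry, infiltration mixing, zone advection, and stream mixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bucketrt as b
from bucketrt.transport import (
    SnowChemState,
    ZoneMixState,
    infiltration_concentration,
    step_snow_chemistry,
    step_zone_advection,
    stream_concentration,
)


class TestInfiltrationMixing:
    @pytest.mark.parametrize("p_rain, c_rain, q_melt, c_melt, expected", [
        (5.0, 3.3e-4, 0.0, 9.9, 3.3e-4),        # single source
        (2.0, 2e-4, 2.0, 0.0, 1e-4),            # equal mixing halves it
        (3.0, 1.0, 1.0, 5.0, 2.0),              # (3*1 + 1*5)/4
        (0.0, 1.0, 0.0, 1.0, 0.0),              # no water: defined as 0
    ])
    def test_flux_weighted_mean(self, p_rain, c_rain, q_melt, c_melt, expected):
        assert infiltration_concentration(p_rain, c_rain, q_melt, c_melt) \
            == pytest.approx(expected)

    def test_negative_flux_rejected(self):
        with pytest.raises(ValueError):
            infiltration_concentration(-1.0, 0.0, 2.0, 0.0)


class TestSnowChemistry:
    def test_complete_melt_exports_entire_pack_and_snowfall_mass(self):
        s = SnowChemState(swe=30.0, conc={"Tracer": 2e-4})
        new, c_melt = step_snow_chemistry(s, p_snow=10.0,
                                          c_ppt={"Tracer": 5e-5},
                                          q_melt=40.0, dt=1.0)
        exported = 40.0 * c_melt["Tracer"]
        assert exported == pytest.approx(30.0 * 2e-4 + 10.0 * 5e-5)
        assert new.swe == 0.0
        assert new.mass("Tracer") == 0.0

    def test_snowfall_mixes_mass_weighted_into_pack(self):
        s = SnowChemState(swe=20.0, conc={"Tracer": 1e-4})
        new, _ = step_snow_chemistry(s, p_snow=10.0, c_ppt={"Tracer": 4e-4},
                                     q_melt=0.0, dt=1.0)
        # hand-computed: (20*1e-4 + 10*4e-4) / 30
        assert new.conc["Tracer"] == pytest.approx(2e-4)
        assert new.swe == 30.0

    def test_partial_melt_leaves_concentration_unchanged(self):
        s = SnowChemState(swe=50.0, conc={"Tracer": 3e-4})
        new, c_melt = step_snow_chemistry(s, 0.0, {}, q_melt=20.0, dt=1.0)
        assert new.conc["Tracer"] == pytest.approx(3e-4)
        assert c_melt["Tracer"] == pytest.approx(3e-4)
        assert new.swe == pytest.approx(30.0)

    def test_overmelt_rejected(self):
        s = SnowChemState(swe=5.0, conc={})
        with pytest.raises(ValueError):
            step_snow_chemistry(s, 0.0, {}, q_melt=6.0, dt=1.0)

    @given(
        swe=st.floats(0.0, 100.0), c0=st.floats(0.0, 1e-3),
        p_snow=st.floats(0.0, 30.0), c_ppt=st.floats(0.0, 1e-3),
        melt_frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_mass_is_never_created_or_destroyed(self, swe, c0, p_snow, c_ppt,
                                                melt_frac):
        s = SnowChemState(swe=swe, conc={"X": c0})
        q_melt = melt_frac * (swe + p_snow)
        new, c_melt = step_snow_chemistry(s, p_snow, {"X": c_ppt}, q_melt, 1.0)
        mass_in = swe * c0 + p_snow * c_ppt
        mass_out = q_melt * c_melt["X"] + new.mass("X")
        assert mass_out == pytest.approx(mass_in, rel=1e-9, abs=1e-15)


def _day(rain=4.0, snowfall=0.0, melt=0.0, q_sf=0.5, q_sz=1.5, q_dz=1.0,
         q_perc=2.0, v_sf=2.0, v_sz=350.0, v_dz=1100.0):
    return dict(rain=rain, snowfall=snowfall, snowmelt=melt, q_sf=q_sf,
                q_sz=q_sz, q_dz=q_dz, q_perc=q_perc, v_sf=v_sf, v_sz=v_sz,
                v_dz=v_dz)


def _states(c=1e-4, v_sf=2.0, v_sz=350.0, v_dz=1100.0):
    return {
        "SF": ZoneMixState(v_w=v_sf, mobile={"X": c}),
        "SZ": ZoneMixState(v_w=v_sz, mobile={"X": c}),
        "DZ": ZoneMixState(v_w=v_dz, mobile={"X": c}),
    }


class TestZoneAdvection:
    def test_single_step_matches_backward_euler_algebra(self):
        """One shallow-zone update equals the closed-form implicit formula."""
        states = _states(c=2e-4)
        day = _day()
        c_rain = {"X": 5e-5}
        new, _, _ = step_zone_advection(states, SnowChemState(), day, c_rain,
                                        ["X"], 1.0)
        q_in = day["rain"]
        c_infil = c_rain["X"]
        expected = (2e-4 * 350.0 + (q_in - day["q_sf"]) * c_infil) \
            / (350.0 + day["q_sz"] + day["q_perc"])
        assert new["SZ"].mobile["X"] == pytest.approx(expected, rel=1e-12)

    def test_constant_input_converges_to_input_concentration(self):
        """The well-mixed-reactor limit: with steady inflow chemistry and no
        volume change, every zone approaches the inflow concentration."""
        states = _states(c=0.0)
        snow = SnowChemState()
        # each zone's in/outflows balance, so storages are truly steady
        day = _day(q_dz=2.0)
        for _ in range(20000):
            states, snow, _ = step_zone_advection(states, snow, day,
                                                  {"X": 1e-4}, ["X"], 1.0)
        for z in ("SF", "SZ", "DZ"):
            assert states[z].mobile["X"] == pytest.approx(1e-4, rel=1e-6)

    def test_immobile_mass_conserved_under_volume_change(self):
        states = _states()
        states["SZ"].immobile = {"X": 5e-5}
        day = _day(v_sz=300.0)  # zone dries
        new, _, _ = step_zone_advection(states, SnowChemState(), day,
                                        {"X": 0.0}, ["X"], 1.0)
        assert new["SZ"].immobile["X"] * 300.0 == pytest.approx(5e-5 * 350.0)

    def test_negative_infiltration_routes_return_flux_without_mass_loss(self):
        """On recession days quick flow can exceed rain+melt; the excess is
        drawn from the shallow zone and the global balance still closes."""
        states = _states(c=1e-4)
        day = _day(rain=0.2, q_sf=1.0)
        new, _, _ = step_zone_advection(states, SnowChemState(), day,
                                        {"X": 1e-4}, ["X"], 1.0)
        mass_before = sum(states[z].mobile["X"] * states[z].v_w
                          for z in states)
        mass_after = sum(new[z].mobile["X"] * new[z].v_w for z in new)
        inflow = day["rain"] * 1e-4
        outflow = (day["q_sf"] * new["SF"].mobile["X"]
                   + day["q_sz"] * new["SZ"].mobile["X"]
                   + day["q_dz"] * new["DZ"].mobile["X"])
        assert mass_after - mass_before == pytest.approx(inflow - outflow,
                                                         rel=1e-10)

    def test_percolation_carries_end_of_step_shallow_concentration(self):
        states = _states(c=0.0)
        states["SZ"] = ZoneMixState(v_w=350.0, mobile={"X": 1e-3})
        day = _day(rain=0.0, q_sf=0.0)
        new, _, _ = step_zone_advection(states, SnowChemState(), day,
                                        {"X": 0.0}, ["X"], 1.0)
        c_sz_end = new["SZ"].mobile["X"]
        expected_dz = (0.0 * 1100.0 + day["q_perc"] * c_sz_end) \
            / (1100.0 + day["q_dz"])
        assert new["DZ"].mobile["X"] == pytest.approx(expected_dz, rel=1e-12)


class TestStreamMixing:
    def test_equal_concentrations_pass_through(self):
        assert stream_concentration(0.5, 1.5, 1.0, 2.0, 2.0, 2.0) \
            == pytest.approx(2.0)

    def test_single_pathway_dominates(self):
        assert stream_concentration(0.0, 0.0, 3.0, 9.0, 9.0, 1.7) \
            == pytest.approx(1.7)

    def test_weighted_mean_with_typical_flow_partition(self):
        # fractions 0.01/0.35/0.64 of unit flow with c = 1, 4, 2
        assert stream_concentration(0.01, 0.35, 0.64, 1.0, 4.0, 2.0) \
            == pytest.approx(2.69)

    def test_zero_flow_reports_missing(self):
        assert np.isnan(stream_concentration(0.0, 0.0, 0.0, 1.0, 1.0, 1.0))

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            stream_concentration(-0.1, 0.3, 0.2, 1.0, 1.0, 1.0)


class TestMixingCellOracle:
    def test_two_year_tracer_matches_explicit_substepped_oracle(self):
        """An independently coded explicit mixing-cell integration at 100
        sub-steps/day reproduces the implicit transport everywhere within
        0.5%."""
        from dataclasses import replace

        spec = replace(b.W9_PRESET, seed=99, precip_chem={"X": 1e-4})
        forcing = b.generate_forcing(730, spec)
        params = b.synthetic.W9_HBV_PARAMS
        hydro = b.run_hbv(forcing, params)
        zones = {
            "SZ": b.ZoneConfig(depth=2.0, porosity=0.45, passive_storage=200.0,
                               fc=250.0),
            "DZ": b.ZoneConfig(depth=6.0, porosity=0.25,
                               passive_storage=1000.0),
        }
        from bucketrt.hydrology import derive_zone_hydrology

        zh = derive_zone_hydrology(hydro, zones, sf_storage=2.0)

        c0 = 1e-4
        # --- implementation: daily backward-Euler steps
        states = _states(c=c0, v_sf=zh.v_w["SF"][0], v_sz=zh.v_w["SZ"][0],
                         v_dz=zh.v_w["DZ"][0])
        snow = SnowChemState()
        impl = {z: [] for z in ("SF", "SZ", "DZ")}
        v_prev = {z: zh.v_w[z][0] for z in ("SF", "SZ", "DZ")}
        for i in range(730):
            day = dict(rain=hydro.rain[i], snowfall=hydro.snowfall[i],
                       snowmelt=hydro.snowmelt[i], q_sf=hydro.q_sf[i],
                       q_sz=hydro.q_sz[i], q_dz=hydro.q_dz[i],
                       q_perc=hydro.q_perc[i], v_sf=zh.v_w["SF"][i],
                       v_sz=zh.v_w["SZ"][i], v_dz=zh.v_w["DZ"][i])
            states, snow, _ = step_zone_advection(states, snow, day,
                                                  {"X": c0}, ["X"], 1.0)
            for z in impl:
                impl[z].append(states[z].mobile["X"])

        # --- oracle: explicit mass bookkeeping, 100 sub-steps per day
        n_sub = 100
        h = 1.0 / n_sub
        m = {z: c0 * zh.v_w[z][0] for z in ("SF", "SZ", "DZ")}
        m_snow = 0.0
        swe = 0.0
        orc = {z: [] for z in ("SF", "SZ", "DZ")}
        v = dict(v_prev)
        for i in range(730):
            v_start = dict(v)
            v_end = {z: zh.v_w[z][i] for z in ("SF", "SZ", "DZ")}
            rain, snowfall = hydro.rain[i], hydro.snowfall[i]
            melt = hydro.snowmelt[i]
            q_sf, q_sz, q_dz = hydro.q_sf[i], hydro.q_sz[i], hydro.q_dz[i]
            q_perc = hydro.q_perc[i]
            q_infil = rain + melt - q_sf
            for k in range(n_sub):
                swe_mid = swe + snowfall * h
                m_snow_mid = m_snow + snowfall * h * c0
                c_melt = m_snow_mid / swe_mid if swe_mid > 0 else 0.0
                swe = swe_mid - melt * h
                m_snow = m_snow_mid - melt * h * c_melt
                c_infil = ((rain * c0 + melt * c_melt) / (rain + melt)
                           if rain + melt > 0 else 0.0)
                frac = (k + 1) / n_sub
                v_new = {z: v_start[z] + (v_end[z] - v_start[z]) * frac
                         for z in v}
                c = {z: m[z] / v[z] for z in v}
                if q_infil >= 0:
                    m["SF"] += h * (q_sf * c_infil - q_sf * c["SF"])
                    m["SZ"] += h * (q_infil * c_infil
                                    - (q_sz + q_perc) * c["SZ"])
                else:
                    m["SZ"] += h * (-(q_sz + q_perc - q_infil) * c["SZ"])
                    # return flux |q_infil| carries shallow-zone water upward
                    m["SF"] += h * ((rain + melt) * c_infil
                                    - q_infil * c["SZ"]
                                    - q_sf * c["SF"])
                m["DZ"] += h * (q_perc * c["SZ"] - q_dz * c["DZ"])
                v = v_new
            for z in orc:
                orc[z].append(m[z] / v[z])

        for z in ("SZ", "DZ", "SF"):
            a = np.array(impl[z])
            o = np.array(orc[z])
            assert np.max(np.abs(a - o) / o) < 0.005, z
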