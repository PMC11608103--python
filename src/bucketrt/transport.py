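"""Advective solute transport between snowpack, surface, shallow and deep
zones, and flux-weighted stream mixing.

Each zone is a well-mixed reactor. Transport is solved with a backward-Euler
step that is fully implicit in both concentration and end-of-step storage;
the deep zone receives the shallow zone's end-of-step concentration within
the same step. Reactions are handled separately (operator splitting); the
transport step carries no reaction source terms. Evapotranspiration removes
pure water, concentrating the remaining solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "SnowChemState",
    "ZoneMixState",
    "infiltration_concentration",
    "step_snow_chemistry",
    "step_zone_advection",
    "stream_concentration",
    "CONC_FLOOR",
]

log = logging.getLogger(__name__)

CONC_FLOOR = 1e-20  # mol/L floor applied if a step yields a negative value


@dataclass
class SnowChemState:
    """Snowpack water equivalent (mm) and solute concentrations (mol/L).

    No reactions occur in the pack; melt leaves at the pack concentration.
    """

    swe: float = 0.0
    conc: dict[str, float] = field(default_factory=dict)

    def mass(self, species: str) -> float:
        """Solute mass per unit area, mol/m^2 (mm x mol/L = mol/m^2)."""
        return self.swe * self.conc.get(species, 0.0)


@dataclass
class ZoneMixState:
    """Mobile and immobile component concentrations of one zone (mol/L),
    relative to the zone's water volume v_w (mm)."""

    v_w: float
    mobile: dict[str, float]
    immobile: dict[str, float] = field(default_factory=dict)

    def total(self, species: str) -> float:
        return self.mobile.get(species, 0.0) + self.immobile.get(species, 0.0)

    def totals(self) -> dict[str, float]:
        keys = set(self.mobile) | set(self.immobile)
        return {s: self.total(s) for s in keys}


def infiltration_concentration(
    p_rain: float, c_rain: float, q_melt: float, c_melt: float
) -> float:
    """Flux-weighted mix of rain and snowmelt chemistry entering the soil;
    defined as 0 when there is no incoming water."""
    if p_rain < 0 or q_melt < 0:
        raise ValueError("water fluxes must be non-negative")
    total = p_rain + q_melt
    if total <= 0:
        return 0.0
    return (p_rain * c_rain + q_melt * c_melt) / total


def step_snow_chemistry(
    s: SnowChemState,
    p_snow: float,
    c_ppt: Mapping[str, float],
    q_melt: float,
    dt: float,
) -> tuple[SnowChemState, dict[str, float]]:
    """Advance the snowpack solute balance over one step.

    Snowfall adds mass at precipitation chemistry; the pack is then fully
    mixed and melt leaves at the mixed pack concentration. Returns the new
    state and the melt concentrations. Melting more than the available pack
    is an error.
    """
    if p_snow < 0 or q_melt < 0:
        raise ValueError("snowfall and melt must be non-negative")
    swe_mid = s.swe + p_snow * dt
    if q_melt * dt > swe_mid + 1e-9:
        raise ValueError("snowmelt exceeds available snow water equivalent")
    species = set(s.conc) | set(c_ppt)
    mass_mid = {
        sp: s.mass(sp) + p_snow * dt * c_ppt.get(sp, 0.0) for sp in species
    }
    if swe_mid > 0:
        c_pack = {sp: m / swe_mid for sp, m in mass_mid.items()}
    else:
        c_pack = {sp: 0.0 for sp in species}
    swe_new = swe_mid - q_melt * dt
    if swe_new <= 1e-12:
        swe_new = 0.0
        conc_new = {sp: 0.0 for sp in species}
    else:
        conc_new = dict(c_pack)  # melt removes mass proportionally: conc unchanged
    return SnowChemState(swe=swe_new, conc=conc_new), c_pack


def _implicit_update(
    c_old: float, v_old: float, v_new: float,
    inflow_mass: float, q_out: float, dt: float,
) -> float:
    """Backward-Euler well-mixed update, implicit in C and end-of-step V:

        C_new = (C_old V_old + dt * inflow_mass) / (V_new + dt * q_out)
    """
    denom = v_new + dt * q_out
    if denom <= 0:
        return 0.0
    return (c_old * v_old + dt * inflow_mass) / denom


def step_zone_advection(
    states: Mapping[str, ZoneMixState],
    snow: SnowChemState,
    hydro: Mapping[str, float],
    c_rain: Mapping[str, float],
    species: list[str],
    dt: float,
    signed_species: frozenset[str] = frozenset(),
) -> tuple[dict[str, ZoneMixState], SnowChemState, dict[str, dict[str, float]]]:
    """One coupled transport step for snowpack + SF + SZ + DZ.

    ``hydro`` carries the day's water fluxes and end-of-step storages:
    ``rain, snowfall, snowmelt, q_sf, q_sz, q_dz, q_perc, v_sf, v_sz, v_dz``
    (mm and mm/day). ``signed_species`` lists components whose totals may
    legitimately be negative (e.g. total H+ under the alkalinity convention);
    these are never clipped. Returns updated states, the new snow state, and the
    end-of-step mobile concentrations per zone (used for stream mixing and
    export bookkeeping). Negative infiltration (quick flow exceeding incoming
    water on recession days) is routed as an SZ -> SF return flux at the
    shallow zone's end-of-step concentration, keeping every balance closed.
    """
    rain = hydro["rain"]
    melt = hydro["snowmelt"]
    q_sf, q_sz, q_dz = hydro["q_sf"], hydro["q_sz"], hydro["q_dz"]
    q_perc = hydro["q_perc"]
    if min(rain, melt, q_sf, q_sz, q_dz, q_perc) < -1e-12:
        raise ValueError("negative water flux in transport step")

    snow_new, c_melt = step_snow_chemistry(
        snow, hydro["snowfall"], c_rain, melt, dt
    )

    q_in = rain + melt
    q_infil = q_in - q_sf
    sf, sz, dz = states["SF"], states["SZ"], states["DZ"]
    v_sf_new, v_sz_new, v_dz_new = hydro["v_sf"], hydro["v_sz"], hydro["v_dz"]

    c_infil = {
        sp: infiltration_concentration(rain, c_rain.get(sp, 0.0),
                                       melt, c_melt.get(sp, 0.0))
        for sp in species
    }

    new_mobile: dict[str, dict[str, float]] = {}

    def advect_zone(state: ZoneMixState, v_new: float,
                    inflow_mass: Mapping[str, float], q_out: float):
        mob = {}
        for sp in species:
            c = _implicit_update(state.mobile.get(sp, 0.0), state.v_w, v_new,
                                 inflow_mass.get(sp, 0.0), q_out, dt)
            if c < 0 and sp not in signed_species:
                log.warning("clipping negative concentration of %s to floor", sp)
                c = CONC_FLOOR
            mob[sp] = c
        # immobile mass is conserved; its concentration rescales with volume
        imm = {sp: (c * state.v_w / v_new if v_new > 0 else 0.0)
               for sp, c in state.immobile.items()}
        return ZoneMixState(v_w=v_new, mobile=mob, immobile=imm)

    if q_infil >= 0:
        # SF receives rain+melt, exports q_sf at its own mixed concentration
        # and passes q_infil straight through at infiltration chemistry.
        sf_in = {sp: q_in * c_infil[sp] - q_infil * c_infil[sp] for sp in species}
        sf_new = advect_zone(sf, v_sf_new, sf_in, q_sf)
        sz_in = {sp: q_infil * c_infil[sp] for sp in species}
        sz_new = advect_zone(sz, v_sz_new, sz_in, q_sz + q_perc)
        dz_in = {sp: q_perc * sz_new.mobile[sp] for sp in species}
        dz_new = advect_zone(dz, v_dz_new, dz_in, q_dz)
    else:
        q_ret = -q_infil  # SZ -> SF return flux; nothing infiltrates today
        sz_in = {sp: 0.0 for sp in species}
        sz_new = advect_zone(sz, v_sz_new, sz_in, q_sz + q_perc + q_ret)
        sf_in = {sp: q_in * c_infil[sp] + q_ret * sz_new.mobile[sp]
                 for sp in species}
        sf_new = advect_zone(sf, v_sf_new, sf_in, q_sf)
        dz_in = {sp: q_perc * sz_new.mobile[sp] for sp in species}
        dz_new = advect_zone(dz, v_dz_new, dz_in, q_dz)

    new_states = {"SF": sf_new, "SZ": sz_new, "DZ": dz_new}
    new_mobile = {z: dict(new_states[z].mobile) for z in new_states}
    return new_states, snow_new, new_mobile


def stream_concentration(
    q_sf: float, q_sz: float, q_dz: float,
    c_sf: float, c_sz: float, c_dz: float,
) -> float:
    """Instantaneous flux-weighted mixing of the three flow paths; NaN on
    zero-total-flow steps (no stream water to speak of)."""
    if min(q_sf, q_sz, q_dz) < 0:
        raise ValueError("flows must be non-negative")
    q = q_sf + q_sz + q_dz
    if q <= 0:
        return float("nan")
    return (q_sf * c_sf + q_sz * c_sz + q_dz * c_dz) / q
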