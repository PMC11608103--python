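"""Simulation orchestration: hydrology first, then chemistry, step by step.

The time loop follows a sequential non-iterative (operator-splitting) scheme:
each step advances snow chemistry and advective transport (backward Euler),
then integrates the kinetic reactions zone by zone (Crank-Nicolson with
Newton-Raphson and adaptive step halving), then re-speciates. Stream
chemistry is the instantaneous flux-weighted mix of the three flow paths.

Also provides delimited-text output tables, concentration-discharge (C-Q)
summaries, and the TOML configuration loader behind the CLI.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .chem import ReactionNetwork
from .hydrology import (
    ForcingSeries,
    HBVParams,
    HydroSeries,
    ZoneConfig,
    derive_zone_hydrology,
    read_forcing,
    read_hbv_light,
    run_hbv,
)
from .kinetics import RateContext, integrate_zone_reactions
from .speciation import EquilibriumSystem, speciate
from .transport import SnowChemState, ZoneMixState, step_zone_advection, stream_concentration

__all__ = [
    "SimConfig",
    "SimOutput",
    "run_simulation",
    "export_tables",
    "read_tables",
    "cq_summary",
    "drop_kinetic_reactions",
]

REACTIVE_ZONES = ("SZ", "DZ")
MMOL = 1000.0  # mol -> mmol


@dataclass
class SimConfig:
    """Everything needed for one run; see the README for the TOML schema."""

    network: ReactionNetwork
    zones: dict[str, ZoneConfig]
    initial_totals: dict[str, dict[str, float]]
    forcing: ForcingSeries | None = None
    forcing_spec: object | None = None        # ClimateSpec when synthetic
    years: int = 2
    hbv_params: HBVParams = field(default_factory=HBVParams)
    hydro: HydroSeries | None = None          # pre-computed hydrology, if any
    substrate_conc: dict[str, dict[str, float]] = field(default_factory=dict)
    pco2_log10: dict[str, float] = field(default_factory=dict)
    aggregates: dict[str, list[str]] = field(default_factory=dict)
    dt: float = 1.0
    spinup_years: int = 1
    surface_reactions: bool = False
    signed_q10: bool = False
    sf_storage: float = 2.0
    reactions_enabled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.forcing is None and self.forcing_spec is None:
            raise ValueError("either forcing or forcing_spec must be given")

    @classmethod
    def from_toml(cls, path: str | Path) -> "SimConfig":
        """Load a run configuration from a TOML file; relative paths resolve
        against the file's directory."""
        path = Path(path)
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
        base = path.parent

        from .chem import build_network, parse_database
        from .synthetic import W9_HBV_PARAMS, W9_PRESET, generate_forcing

        net_cfg = cfg["network"]
        db = parse_database((base / net_cfg["database"]).read_text()) \
            if "database" in net_cfg else None
        network = build_network((base / net_cfg["config"]).read_text(), db)

        f_cfg = cfg.get("forcing", {})
        forcing = forcing_spec = None
        years = int(f_cfg.get("years", 2))
        if "file" in f_cfg:
            forcing = read_forcing(str(base / f_cfg["file"]))
        else:
            spec = W9_PRESET
            overrides = {k: v for k, v in f_cfg.items()
                         if k not in ("years", "preset", "chemistry")}
            chem = f_cfg.get("chemistry", {})
            forcing_spec = replace(spec, precip_chem=dict(chem), **overrides)

        h_cfg = cfg.get("hbv", {})
        hydro = None
        if "results" in h_cfg:
            hydro, hbv_params = read_hbv_light(
                (base / h_cfg["results"]).read_text(),
                (base / h_cfg["params"]).read_text(),
            )
        elif h_cfg:
            hbv_params = HBVParams(**h_cfg)
        else:
            hbv_params = W9_HBV_PARAMS

        zones = {}
        initial = {}
        substrate = {}
        pco2 = {}
        for zone, zc in cfg.get("zones", {}).items():
            initial[zone] = dict(zc.pop("initial", {}))
            substrate[zone] = dict(zc.pop("substrate", {}))
            if "pco2_log10" in zc:
                pco2[zone] = float(zc.pop("pco2_log10"))
            if zone in ("SZ", "DZ"):
                zones[zone] = ZoneConfig(**zc)
        if "SF" not in initial:
            initial["SF"] = {}

        opts = cfg.get("options", {})
        aggregates = {k: list(v) for k, v in cfg.get("aggregates", {}).items()}
        return cls(
            network=network, zones=zones, initial_totals=initial,
            forcing=forcing, forcing_spec=forcing_spec, years=years,
            hbv_params=hbv_params, hydro=hydro,
            substrate_conc=substrate, pco2_log10=pco2, aggregates=aggregates,
            dt=float(opts.get("dt", 1.0)),
            spinup_years=int(opts.get("spinup_years", 1)),
            surface_reactions=bool(opts.get("surface_reactions", False)),
            signed_q10=bool(opts.get("signed_q10", False)),
            sf_storage=float(opts.get("sf_storage", 2.0)),
            reactions_enabled=bool(opts.get("reactions_enabled", True)),
            seed=int(opts.get("seed", 0)),
        )


def drop_kinetic_reactions(network: ReactionNetwork, names: list[str]) -> ReactionNetwork:
    """Overlay helper: a copy of the network without the named kinetic
    reactions (reaction toggling experiments are config edits, not code
    edits)."""
    known = {r.id for rxns in network.kinetic_by_zone.values() for r in rxns}
    missing = set(names) - known
    if missing:
        raise ValueError(f"unknown kinetic reactions: {sorted(missing)}")
    return ReactionNetwork(
        species=list(network.species),
        equilibrium=list(network.equilibrium),
        equilibrium_zones=dict(network.equilibrium_zones),
        kinetic_by_zone={
            z: [r for r in rxns if r.id not in names]
            for z, rxns in network.kinetic_by_zone.items()
        },
        surface_area={k: v for k, v in network.surface_area.items()
                      if k[1] not in names},
        secondary_of=dict(network.secondary_of),
    )


@dataclass
class SimOutput:
    """Time series produced by one run (spin-up already dropped).

    ``conc`` columns are ``<zone>.<species>`` (mol/L, component totals in the
    zone's water) plus ``stream.<species>``; aggregates (e.g. DIC) appear as
    additional species. ``rates`` and ``exports`` are mmol/m^2/day.
    """

    conc: pd.DataFrame
    rates: pd.DataFrame
    exports: pd.DataFrame
    hydro: pd.DataFrame
    species: list[str]
    dt: float


def _concat_spinup(forcing: ForcingSeries, spinup_years: int) -> tuple[ForcingSeries, int]:
    if spinup_years <= 0:
        return forcing, 0
    n = min(365 * spinup_years, len(forcing))
    chem = {sp: np.concatenate([c[:n], c]) for sp, c in forcing.precip_chem.items()}
    ext = ForcingSeries(
        precip=np.concatenate([forcing.precip[:n], forcing.precip]),
        temp=np.concatenate([forcing.temp[:n], forcing.temp]),
        pet=np.concatenate([forcing.pet[:n], forcing.pet]),
        precip_chem=chem,
    )
    return ext, n


def run_simulation(cfg: SimConfig) -> SimOutput:
    """Run hydrology then chemistry over the configured period.

    Deterministic given the config and seed. The first simulated year is
    repeated ``spinup_years`` times before the reported period to damp
    initial-condition transients.
    """
    if cfg.forcing is not None:
        forcing = cfg.forcing
    else:
        from .synthetic import generate_forcing

        spec = cfg.forcing_spec
        if getattr(spec, "seed", None) != cfg.seed:
            spec = replace(spec, seed=cfg.seed)
        forcing = generate_forcing(cfg.years * 365, spec)

    forcing, n_spin = _concat_spinup(forcing, cfg.spinup_years)
    if cfg.hydro is not None:
        if len(cfg.hydro) != len(forcing):
            raise ValueError(
                f"hydrology series length {len(cfg.hydro)} does not match "
                f"forcing length {len(forcing)}"
            )
        hydro = cfg.hydro
    else:
        hydro = run_hbv(forcing, cfg.hbv_params)
    zone_h = derive_zone_hydrology(hydro, cfg.zones, sf_storage=cfg.sf_storage)

    network = cfg.network
    mobile = network.mobile_primaries
    primaries = network.primaries
    has_eq = bool(network.secondary_of)

    systems = {
        z: EquilibriumSystem.from_network(
            network, z,
            fixed_activities={
                sp.name: 10.0 ** cfg.pco2_log10.get(z, -3.5)
                for sp in network.species if sp.phase == "pseudo-gas"
            },
        )
        for z in ("SF", "SZ", "DZ")
    }

    # components with a negative tableau coefficient anywhere can carry
    # legitimately negative totals (alkalinity convention for H+)
    signed = set()
    for sys_z in systems.values():
        for j, p in enumerate(sys_z.primaries):
            if sys_z.tableau.shape[0] and (sys_z.tableau[:, j] < 0).any():
                signed.add(p)
    signed = frozenset(signed)

    # initial states: speciate once to split mobile / immobile
    states: dict[str, ZoneMixState] = {}
    spec_states = {}
    v0 = {z: zone_h.v_w[z][0] for z in ("SF", "SZ", "DZ")}
    for z in ("SF", "SZ", "DZ"):
        totals = {p: float(cfg.initial_totals.get(z, {}).get(p, 0.0))
                  for p in primaries}
        st = speciate(totals, systems[z])
        spec_states[z] = st
        mob = {p: st.mobile_total(p) for p in mobile}
        imm = {p: totals[p] - mob.get(p, 0.0) for p in primaries}
        states[z] = ZoneMixState(v_w=v0[z], mobile=mob, immobile=imm)
    snow = SnowChemState()

    reactive = {z: (cfg.reactions_enabled and bool(network.kinetic_by_zone.get(z)))
                for z in ("SF", "SZ", "DZ")}
    if not cfg.surface_reactions:
        reactive["SF"] = False
    rxn_ids = [(z, r.id) for z in ("SF", "SZ", "DZ")
               for r in network.kinetic_by_zone.get(z, []) if reactive[z]]

    n_days = len(forcing)
    substeps = max(1, round(1.0 / cfg.dt))
    dt = 1.0 / substeps
    n_steps = n_days * substeps

    out_species = mobile + list(cfg.aggregates)
    conc_cols = {f"{z}.{sp}": np.zeros(n_steps)
                 for z in ("SF", "SZ", "DZ", "stream") for sp in out_species}
    rate_cols = {f"{z}.{rid}": np.zeros(n_steps) for z, rid in rxn_ids}
    exp_cols = {f"{z}.{sp}": np.zeros(n_steps)
                for z in ("SF", "SZ", "DZ") for sp in out_species}
    hyd_cols = {k: np.zeros(n_steps) for k in
                ("q_sf", "q_sz", "q_dz", "q_total", "temp", "precip")}

    v_prev = dict(v0)
    step = 0
    for day in range(n_days):
        day_h = {k: float(getattr(hydro, k)[day])
                 for k in ("rain", "snowfall", "snowmelt",
                           "q_sf", "q_sz", "q_dz", "q_perc")}
        v_day = {z: float(zone_h.v_w[z][day]) for z in ("SF", "SZ", "DZ")}
        c_rain = {sp: (float(forcing.precip_chem[sp][day])
                       if sp in forcing.precip_chem else 0.0)
                  for sp in mobile}
        for sub in range(substeps):
            frac = (sub + 1) / substeps
            v_end = {z: v_prev[z] + (v_day[z] - v_prev[z]) * frac
                     for z in ("SF", "SZ", "DZ")}
            hydro_step = dict(day_h)
            hydro_step.update(v_sf=v_end["SF"], v_sz=v_end["SZ"], v_dz=v_end["DZ"])

            states, snow, _ = step_zone_advection(
                states, snow, hydro_step, c_rain, mobile, dt,
                signed_species=signed,
            )

            for z in ("SF", "SZ", "DZ"):
                st_z = states[z]
                if reactive[z]:
                    totals = st_z.totals()
                    totals = {p: totals.get(p, 0.0) for p in primaries}
                    ctx = RateContext(
                        temp=float(forcing.temp[day]),
                        sw=float(zone_h.sw[z][day]),
                        zw=float(zone_h.zw[z][day]),
                        dt=dt,
                        water_volume=st_z.v_w,
                        substrate_conc=cfg.substrate_conc.get(z, {}),
                        signed_q10=cfg.signed_q10,
                    )
                    areas = {rid: network.surface_area.get((z, rid), 0.0)
                             for _, rid in rxn_ids}
                    st, rates = integrate_zone_reactions(
                        totals, network.kinetic_by_zone[z], ctx, systems[z],
                        areas, guess=spec_states[z].conc,
                    )
                    spec_states[z] = st
                    mob = {p: st.mobile_total(p) for p in mobile}
                    imm = {p: st.totals[p] - mob.get(p, 0.0) for p in primaries}
                    states[z] = ZoneMixState(v_w=st_z.v_w, mobile=mob, immobile=imm)
                    for rid, r in rates.items():
                        rate_cols[f"{z}.{rid}"][step] = r * MMOL
                elif has_eq or cfg.aggregates:
                    totals = st_z.totals()
                    totals = {p: totals.get(p, 0.0) for p in primaries}
                    spec_states[z] = speciate(totals, systems[z],
                                              guess=spec_states[z].conc)

            # record concentrations, stream mixing, and export fluxes
            q = {"SF": day_h["q_sf"], "SZ": day_h["q_sz"], "DZ": day_h["q_dz"]}
            zone_conc: dict[str, dict[str, float]] = {}
            for z in ("SF", "SZ", "DZ"):
                vals = {}
                for sp in mobile:
                    vals[sp] = states[z].mobile.get(sp, 0.0)
                for agg, members in cfg.aggregates.items():
                    vals[agg] = sum(spec_states[z].conc.get(m, 0.0)
                                    for m in members)
                zone_conc[z] = vals
                for sp, v in vals.items():
                    conc_cols[f"{z}.{sp}"][step] = v
                    exp_cols[f"{z}.{sp}"][step] = q[z] * v * MMOL
            for sp in out_species:
                conc_cols[f"stream.{sp}"][step] = stream_concentration(
                    q["SF"], q["SZ"], q["DZ"],
                    zone_conc["SF"][sp], zone_conc["SZ"][sp], zone_conc["DZ"][sp],
                )
            hyd_cols["q_sf"][step] = q["SF"]
            hyd_cols["q_sz"][step] = q["SZ"]
            hyd_cols["q_dz"][step] = q["DZ"]
            hyd_cols["q_total"][step] = q["SF"] + q["SZ"] + q["DZ"]
            hyd_cols["temp"][step] = forcing.temp[day]
            hyd_cols["precip"][step] = forcing.precip[day]
            step += 1
        v_prev = v_day

    skip = n_spin * substeps
    def trim(cols):
        return pd.DataFrame({k: v[skip:] for k, v in cols.items()})

    return SimOutput(
        conc=trim(conc_cols), rates=trim(rate_cols), exports=trim(exp_cols),
        hydro=trim(hyd_cols), species=out_species, dt=dt,
    )


# ---------------------------------------------------------------------------
# Output tables and C-Q summaries
# ---------------------------------------------------------------------------

_TABLES = ("concentrations", "rates", "exports", "hydro")


def export_tables(out: SimOutput, directory: str | Path) -> dict[str, Path]:
    """Write the four delimited-text output tables; rereadable losslessly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frames = dict(zip(_TABLES, (out.conc, out.rates, out.exports, out.hydro)))
    paths = {}
    for name, df in frames.items():
        p = directory / f"{name}.csv"
        # default float formatting is the shortest exact round-trip repr
        df.to_csv(p, index_label="step")
        paths[name] = p
    return paths


def read_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    return {
        name: pd.read_csv(directory / f"{name}.csv", index_col="step",
                          float_precision="round_trip")
        for name in _TABLES
    }


def cq_summary(out: SimOutput, solute: str,
               min_steps: int = 30) -> dict[str, float]:
    """Concentration-discharge summary for a stream solute.

    Returns the least-squares slope of log10 C against log10 Q and the
    Spearman rank correlation, excluding zero-flow and missing steps. A
    positive relationship is a flushing pattern (shallow-enriched solutes), a
    negative one dilution (deep-enriched solutes). Constant series report
    slope 0 and rho 0 with ``constant=1``.
    """
    col = f"stream.{solute}"
    if col not in out.conc.columns:
        raise KeyError(f"no stream series for solute {solute!r}")
    c = out.conc[col].to_numpy()
    q = out.hydro["q_total"].to_numpy()
    ok = np.isfinite(c) & (q > 0) & (c > 0)
    c, q = c[ok], q[ok]
    if len(c) < min_steps:
        raise ValueError(f"need at least {min_steps} positive-flow steps, got {len(c)}")
    if np.ptp(c) == 0.0:
        return {"slope": 0.0, "rho": 0.0, "constant": 1.0}
    slope = float(np.polyfit(np.log10(q), np.log10(c), 1)[0])
    rho = stats.spearmanr(q, c).statistic
    return {"slope": slope, "rho": float(rho), "constant": 0.0}
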