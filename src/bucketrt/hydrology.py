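"""Bucket hydrology: an internal standard HBV implementation, readers and
writers for an HBV-light-style results/parameter text dialect, and derivation
of the per-zone quantities the chemistry needs (passive-augmented storages,
saturation, water-table depth).

The model has a degree-day snow routine, a soil-moisture store with a
``(SM/FC)^BETA`` recharge split and evapotranspiration scaled by ``SM/(FC*LP)``,
and two linear-reservoir subsurface stores: the upper zone yields quick flow
``Q0 = k0 * max(UZ - UZL, 0)`` and interflow ``Q1 = k1 * UZ``, recharge to the
lower zone is capped at PERC, and baseflow is ``Q2 = k2 * LZ``. Flows are
renamed for the chemistry: Q0 -> QSF (surface), Q1 -> QSZ (shallow),
Q2 -> QDZ (deep). All storages and fluxes are drainage-area-normalized
(mm, mm/day).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, TextIO

import numpy as np
import pandas as pd

__all__ = [
    "ForcingSeries",
    "HBVParams",
    "HydroSeries",
    "ZoneConfig",
    "ZoneHydroSeries",
    "run_hbv",
    "read_forcing",
    "write_forcing",
    "read_hbv_light",
    "write_hbv_light",
    "derive_zone_hydrology",
]


@dataclass
class ForcingSeries:
    """Daily climate forcing plus precipitation chemistry (mol/L per species).

    Chemistry columns give the component totals of primaries in precipitation;
    species absent from ``precip_chem`` rain in at zero concentration.
    """

    precip: np.ndarray          # mm/day
    temp: np.ndarray            # deg C
    pet: np.ndarray             # mm/day
    precip_chem: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.precip = np.asarray(self.precip, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.pet = np.asarray(self.pet, dtype=float)
        n = len(self.precip)
        if len(self.temp) != n or len(self.pet) != n:
            raise ValueError("forcing series must all have the same length")
        if np.any(~np.isfinite(self.precip)) or np.any(~np.isfinite(self.temp)) \
                or np.any(~np.isfinite(self.pet)):
            raise ValueError("forcing series contain non-finite values (missing days?)")
        if np.any(self.precip < 0) or np.any(self.pet < 0):
            raise ValueError("precipitation and PET must be non-negative")
        for sp, c in self.precip_chem.items():
            c = np.asarray(c, dtype=float)
            if len(c) != n:
                raise ValueError(f"chemistry series for {sp!r} has wrong length")
            self.precip_chem[sp] = c

    def __len__(self):
        return len(self.precip)

    def chem_at(self, i: int) -> dict[str, float]:
        return {sp: float(c[i]) for sp, c in self.precip_chem.items()}


@dataclass(frozen=True)
class HBVParams:
    tt: float = 0.0        # deg C, rain/snow threshold
    cfmax: float = 3.0     # mm/degC/day degree-day melt factor
    fc: float = 250.0      # mm field capacity
    lp: float = 0.7        # fraction of FC where AET reaches PET
    beta: float = 2.0      # recharge-split exponent
    k0: float = 0.3        # 1/day quick-flow recession
    k1: float = 0.1        # 1/day shallow recession
    k2: float = 0.02       # 1/day deep recession
    uzl: float = 30.0      # mm quick-flow threshold
    perc: float = 2.0      # mm/day max recharge to the lower zone

    def __post_init__(self):
        for name in ("cfmax", "fc", "lp", "beta", "k0", "k1", "k2", "uzl", "perc"):
            if getattr(self, name) < 0:
                raise ValueError(f"HBV parameter {name} must be non-negative")
        if not (self.k0 >= self.k1 >= self.k2):
            raise ValueError("recession coefficients must satisfy k0 >= k1 >= k2")
        if self.k0 + self.k1 > 1.0:
            raise ValueError("k0 + k1 > 1/day would overdrain the upper zone")


_HYDRO_COLUMNS = [
    "precip", "temp", "rain", "snowfall", "swe", "snowmelt", "sm", "uz", "lz",
    "q_sf", "q_sz", "q_dz", "q_infil", "q_perc", "aet", "pet",
]


@dataclass
class HydroSeries:
    """Daily water storages and fluxes (mm, mm/day); column names above."""

    data: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _HYDRO_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"HydroSeries missing columns: {missing}")

    def __len__(self):
        return len(self.data)

    def __getattr__(self, name):
        if name in _HYDRO_COLUMNS:
            return self.data[name].to_numpy()
        raise AttributeError(name)

    @property
    def q_total(self) -> np.ndarray:
        return self.q_sf + self.q_sz + self.q_dz


def run_hbv(forcing: ForcingSeries, params: HBVParams,
            init: Mapping[str, float] | None = None) -> HydroSeries:
    """Run the internal standard HBV model day by day.

    ``init`` may set starting storages (``sm``, ``uz``, ``lz``, ``swe`` in mm;
    defaults: SM at half field capacity, empty elsewhere). The per-day water
    balance closes to floating-point precision by construction.
    """
    p = params
    init = dict(init or {})
    sm = float(init.get("sm", p.fc / 2.0))
    uz = float(init.get("uz", 0.0))
    lz = float(init.get("lz", 0.0))
    swe = float(init.get("swe", 0.0))

    n = len(forcing)
    out = {c: np.zeros(n) for c in _HYDRO_COLUMNS}
    for i in range(n):
        pr, t, pet = forcing.precip[i], forcing.temp[i], forcing.pet[i]
        # snow routine
        snowfall = pr if t < p.tt else 0.0
        rain = pr - snowfall
        swe += snowfall
        melt = min(p.cfmax * max(t - p.tt, 0.0), swe)
        swe -= melt

        # soil moisture routine
        inflow = rain + melt
        recharge = inflow * min(sm / p.fc, 1.0) ** p.beta
        sm += inflow - recharge
        aet = pet * min(sm / (p.fc * p.lp), 1.0) if p.fc * p.lp > 0 else pet
        aet = min(aet, sm)
        sm -= aet

        # upper / lower response reservoirs
        uz += recharge
        q_perc = min(p.perc, uz)
        uz -= q_perc
        lz += q_perc
        q_sf = p.k0 * max(uz - p.uzl, 0.0)
        q_sz = p.k1 * uz
        uz -= q_sf + q_sz
        q_dz = p.k2 * lz
        lz -= q_dz

        q_infil = rain + melt - q_sf  # may be negative on recession days

        for name, val in (
            ("precip", pr), ("temp", t), ("rain", rain), ("snowfall", snowfall),
            ("swe", swe), ("snowmelt", melt), ("sm", sm), ("uz", uz), ("lz", lz),
            ("q_sf", q_sf), ("q_sz", q_sz), ("q_dz", q_dz),
            ("q_infil", q_infil), ("q_perc", q_perc), ("aet", aet), ("pet", pet),
        ):
            out[name][i] = val
    return HydroSeries(pd.DataFrame(out))


# ---------------------------------------------------------------------------
# Zone hydrology for the chemistry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneConfig:
    """Static description of one subsurface zone's column."""

    depth: float              # m
    porosity: float           # fraction in (0, 1]
    passive_storage: float    # mm, non-drainable but mixing/reacting water
    fc: float | None = None   # mm, field capacity of the soil store (SZ only)

    def __post_init__(self):
        if not (0.0 < self.porosity <= 1.0):
            raise ValueError("porosity must lie in (0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.passive_storage < 0:
            raise ValueError("passive storage must be >= 0")


@dataclass
class ZoneHydroSeries:
    """Per-zone daily storages (incl. passive), saturation, and water-table
    depth for SF, SZ and DZ."""

    v_w: dict[str, np.ndarray]   # mm
    sw: dict[str, np.ndarray]    # fraction
    zw: dict[str, np.ndarray]    # m
    capped: dict[str, int]       # days where storage exceeded pore capacity


def derive_zone_hydrology(
    h: HydroSeries,
    zones: Mapping[str, ZoneConfig],
    sf_storage: float = 2.0,
) -> ZoneHydroSeries:
    """Map HBV storages onto the chemistry zones.

    * SZ storage = UZ + SM + passive; DZ storage = LZ + passive; SF is a small
      constant transient store (``sf_storage`` mm).
    * SZ saturation = min(1, SM / FC) (soil store only); DZ saturation uses
      the storage-to-pore-capacity ratio.
    * Water table depth Zw = max(0, depth - (v_w/1000)/porosity) m, measured
      from the top of the zone's column; a fully saturated column gives 0.
    """
    szc, dzc = zones["SZ"], zones["DZ"]
    fc = szc.fc if szc.fc is not None else np.inf

    v_sz = h.uz + h.sm + szc.passive_storage
    v_dz = h.lz + dzc.passive_storage
    n = len(h)
    v_sf = np.full(n, float(sf_storage))

    def saturation(v_mm, cfg: ZoneConfig):
        cap = cfg.porosity * cfg.depth * 1000.0
        return np.minimum(v_mm / cap, 1.0), int(np.sum(v_mm > cap))

    sw_sz = np.minimum(h.sm / fc, 1.0)
    _, capped_sz = saturation(v_sz, szc)
    sw_dz, capped_dz = saturation(v_dz, dzc)

    def table_depth(v_mm, cfg: ZoneConfig):
        return np.maximum(cfg.depth - (v_mm / 1000.0) / cfg.porosity, 0.0)

    return ZoneHydroSeries(
        v_w={"SF": v_sf, "SZ": v_sz, "DZ": v_dz},
        sw={"SF": np.ones(n), "SZ": sw_sz, "DZ": sw_dz},
        zw={"SF": np.zeros(n), "SZ": table_depth(v_sz, szc),
            "DZ": table_depth(v_dz, dzc)},
        capped={"SZ": capped_sz, "DZ": capped_dz},
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def read_forcing(source: str | TextIO) -> ForcingSeries:
    """Read forcing from delimited text with columns ``date, precip, temp,
    pet`` plus one ``c_<species>`` column per precipitation-chemistry
    species."""
    df = pd.read_csv(source, float_precision="round_trip")
    required = {"precip", "temp", "pet"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"forcing file missing columns: {sorted(missing)}")
    chem = {
        col[2:]: df[col].to_numpy(dtype=float)
        for col in df.columns if col.startswith("c_")
    }
    return ForcingSeries(
        precip=df["precip"].to_numpy(dtype=float),
        temp=df["temp"].to_numpy(dtype=float),
        pet=df["pet"].to_numpy(dtype=float),
        precip_chem=chem,
    )


def write_forcing(forcing: ForcingSeries, dest: str | TextIO) -> None:
    df = pd.DataFrame({
        "date": np.arange(len(forcing)),
        "precip": forcing.precip,
        "temp": forcing.temp,
        "pet": forcing.pet,
    })
    for sp, c in forcing.precip_chem.items():
        df[f"c_{sp}"] = c
    df.to_csv(dest, index=False, float_format="%.10g")


_HBV_LIGHT_COLUMNS = {
    "Date": None, "Precipitation": "precip", "Temperature": "temp",
    "AET": "aet", "PET": "pet", "Snow": "swe", "SM": "sm", "UZ": "uz",
    "LZ": "lz", "Q0": "q_sf", "Q1": "q_sz", "Q2": "q_dz",
}

_PARAM_NAMES = {"TT": "tt", "CFMAX": "cfmax", "FC": "fc", "LP": "lp",
                "BETA": "beta", "K0": "k0", "K1": "k1", "K2": "k2",
                "UZL": "uzl", "PERC": "perc"}


def read_hbv_light(results_text: str, params_text: str) -> tuple[HydroSeries, HBVParams]:
    """Read an HBV-light-style tab-delimited results file plus parameter file.

    The results file must carry the named columns Date, Precipitation,
    Temperature, AET, PET, Snow, SM, UZ, LZ, Q0, Q1, Q2 (storages are
    end-of-day values). The fluxes the chemistry needs but the file lacks are
    back-calculated so each zone balance closes exactly: recharge to the lower
    zone from ``LZ_t - LZ_{t-1} + Q2_t``, snowmelt from the snow-storage
    balance, and infiltration as ``rain + melt - Q0``.
    """
    params_kw = {}
    for lineno, raw in enumerate(params_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"parameter file line {lineno}: expected 'NAME<tab>value'")
        name = parts[0].strip().upper()
        if name not in _PARAM_NAMES:
            raise ValueError(
                f"parameter file line {lineno}: unknown parameter {name!r}; "
                f"expected one of {sorted(_PARAM_NAMES)}"
            )
        params_kw[_PARAM_NAMES[name]] = float(parts[1])
    params = HBVParams(**params_kw)

    df = pd.read_csv(io.StringIO(results_text), sep="\t",
                 float_precision="round_trip")
    missing = [c for c in _HBV_LIGHT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"HBV-light results file missing columns {missing}; expected "
            f"{list(_HBV_LIGHT_COLUMNS)}"
        )

    out = {}
    for src, dst in _HBV_LIGHT_COLUMNS.items():
        if dst is not None:
            out[dst] = df[src].to_numpy(dtype=float)
    n = len(df)
    if n == 0:
        raise ValueError("HBV-light results file has no data rows")

    precip, temp, swe = out["precip"], out["temp"], out["swe"]
    snowfall = np.where(temp < params.tt, precip, 0.0)
    rain = precip - snowfall
    swe_prev = np.concatenate([[swe[0] - snowfall[0]], swe[:-1]])
    melt = swe_prev + snowfall - swe
    if np.any(melt < -1e-9):
        raise ValueError("snow storage increases faster than snowfall allows")
    melt = np.maximum(melt, 0.0)

    lz = out["lz"]
    lz_prev = np.concatenate([[lz[0] + out["q_dz"][0]], lz[:-1]])
    q_perc = lz - lz_prev + out["q_dz"]
    # first-day storage change is unknowable from the file; assume steady
    q_perc = np.maximum(q_perc, 0.0)
    out.update(
        rain=rain, snowfall=snowfall, snowmelt=melt,
        q_perc=q_perc, q_infil=rain + melt - out["q_sf"],
    )
    return HydroSeries(pd.DataFrame(out)[_HYDRO_COLUMNS]), params


def write_hbv_light(h: HydroSeries, params: HBVParams) -> tuple[str, str]:
    """Serialize to the documented dialect; inverse of :func:`read_hbv_light`
    up to the back-calculated columns."""
    df = pd.DataFrame({"Date": np.arange(len(h))})
    for src, dst in _HBV_LIGHT_COLUMNS.items():
        if dst is not None:
            df[src] = h.data[dst].to_numpy()
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=False, float_format="%.17g")
    params_text = "\n".join(
        f"{name}\t{getattr(params, attr):.10g}" for name, attr in _PARAM_NAMES.items()
    ) + "\n"
    return buf.getvalue(), params_text
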