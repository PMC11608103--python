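"""Species, reactions, geochemical database, and reaction-network assembly.

A reaction network couples three ingredients:

* a species list split by phase (aqueous primaries, aqueous secondaries,
  solids, surface sorption sites/sorbed complexes, and immobile pseudo-gases),
* equilibrium reactions, each defining exactly one secondary species in terms
  of primaries via a mass-action law, and
* per-zone kinetic reactions (TST mineral dissolution, Monod/inhibition
  microbial kinetics) carrying their rate parameters.

Thermodynamic constants live in a small line-oriented database file (the
grammar is documented in the README); the network configuration is TOML.
"""

from __future__ import annotations

import math
import re
import tomllib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "Phase",
    "SpeciesDef",
    "EnvParams",
    "ReactionDef",
    "GeochemDatabase",
    "ReactionNetwork",
    "NetworkError",
    "DatabaseParseError",
    "parse_signature",
    "format_signature",
    "canonical_signature",
    "parse_database",
    "serialize_database",
    "build_network",
    "stoichiometric_increment",
    "resolve_tableau",
    "WATER",
]

ZONES = ("SF", "SZ", "DZ")

#: Water is assigned unit activity and excluded from mole balances.
WATER = "H2O"

AQUEOUS_PRIMARY = "aqueous-primary"
AQUEOUS_SECONDARY = "aqueous-secondary"
SOLID = "solid"
SORPTION_SITE = "sorption-site"
SORBED = "sorbed"
PSEUDO_GAS = "pseudo-gas"

Phase = str
_PHASES = {AQUEOUS_PRIMARY, AQUEOUS_SECONDARY, SOLID, SORPTION_SITE, SORBED, PSEUDO_GAS}

#: Phases whose members are carried by flowing water.
MOBILE_PHASES = {AQUEOUS_PRIMARY, AQUEOUS_SECONDARY}
#: Phases with prescribed activity (1 for solids, pCO2-like for pseudo-gases);
#: these never enter mole balances. Sorption sites are balanced, not fixed.
FIXED_ACTIVITY_PHASES = {SOLID, PSEUDO_GAS}


class NetworkError(ValueError):
    """Raised when a network configuration fails validation."""


class DatabaseParseError(ValueError):
    """Raised on a malformed database file; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None):
        if lineno is not None:
            message = f"line {lineno}: {message}"
        super().__init__(message)
        self.lineno = lineno


@dataclass(frozen=True)
class SpeciesDef:
    name: str
    phase: Phase

    def __post_init__(self):
        if self.phase not in _PHASES:
            raise NetworkError(f"unknown phase {self.phase!r} for species {self.name!r}")

    @property
    def mobile(self) -> bool:
        return self.phase in MOBILE_PHASES

    @property
    def fixed_activity(self) -> bool:
        return self.phase in FIXED_ACTIVITY_PHASES


@dataclass(frozen=True)
class EnvParams:
    """Environmental-dependence parameters of a kinetic rate law.

    q10 scales the temperature response (1 disables it); n and swc shape the
    soil-moisture response, peaking at saturation swc (n = 0 disables it);
    alpha_beta is the exponential water-table-depth coefficient (1/m,
    0 disables it).
    """

    q10: float = 1.0
    n: float = 0.0
    swc: float = 1.0
    alpha_beta: float = 0.0

    def __post_init__(self):
        if self.q10 <= 0:
            raise NetworkError("q10 must be > 0")
        if not (0.0 < self.swc <= 1.0):
            raise NetworkError("swc must lie in (0, 1]")


EQUILIBRIUM = "equilibrium"
KINETIC_TST = "kinetic-tst"
KINETIC_MONOD = "kinetic-monod"


@dataclass(frozen=True)
class ReactionDef:
    """A reaction with signed stoichiometry (reactants < 0, products > 0)."""

    id: str
    kind: str
    stoichiometry: Mapping[str, float]
    log10_keq: float | None = None
    log10_k: float | None = None       # log10 mol/m^2/s
    ssa: float | None = None           # m^2/g
    substrate: str | None = None       # solid / pseudo-gas the area term refers to
    monod_terms: Mapping[str, float] = field(default_factory=dict)       # KM, mol/L
    inhibition_terms: Mapping[str, float] = field(default_factory=dict)  # KI, mol/L
    catalyst_terms: Mapping[str, float] = field(default_factory=dict)    # exponent m
    env: EnvParams = field(default_factory=EnvParams)

    def __post_init__(self):
        if self.kind not in (EQUILIBRIUM, KINETIC_TST, KINETIC_MONOD):
            raise NetworkError(f"unknown reaction kind {self.kind!r}")
        if self.kind == EQUILIBRIUM:
            if self.log10_keq is None:
                raise NetworkError(f"equilibrium reaction {self.id!r} needs log10_keq")
            if self.log10_k is not None or self.monod_terms or self.inhibition_terms:
                raise NetworkError(
                    f"equilibrium reaction {self.id!r} must not carry kinetic parameters"
                )
        else:
            if self.log10_k is None:
                raise NetworkError(f"kinetic reaction {self.id!r} needs log10_k")
            if self.kind == KINETIC_TST and self.log10_keq is None:
                raise NetworkError(f"TST reaction {self.id!r} needs log10_keq")
        for name, km in {**self.monod_terms, **self.inhibition_terms}.items():
            if km <= 0:
                raise NetworkError(f"KM/KI for {name!r} in {self.id!r} must be > 0")

    @property
    def reactants(self) -> dict[str, float]:
        return {s: -c for s, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {s: c for s, c in self.stoichiometry.items() if c > 0}


# ---------------------------------------------------------------------------
# Reaction signatures
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)\s+)?(\S+)$")


def parse_signature(text: str) -> dict[str, float]:
    """Parse ``'A + 2 B = 1.1 C + D'`` into signed stoichiometry.

    Species left of ``=`` are reactants (negative coefficients), right are
    products (positive). Coefficients default to 1. Species names are
    whitespace-free tokens; ``+`` separates terms.
    """
    if text.count("=") != 1:
        raise DatabaseParseError(f"signature needs exactly one '=': {text!r}")
    lhs, rhs = text.split("=")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float):
        if side.strip() == "0":  # empty-side placeholder
            return
        terms = [t.strip() for t in side.split(" + ")]
        for term in terms:
            if not term:
                raise DatabaseParseError(f"empty term in signature {text!r}")
            m = _TERM_RE.match(term)
            if m is None:
                raise DatabaseParseError(f"bad term {term!r} in signature {text!r}")
            coef = float(m.group(1)) if m.group(1) else 1.0
            name = m.group(2)
            stoich[name] = stoich.get(name, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    return {s: c for s, c in stoich.items() if c != 0.0}


def _fmt_coef(c: float) -> str:
    return repr(c)  # shortest exact round-trip


def format_signature(stoich: Mapping[str, float]) -> str:
    """Render signed stoichiometry back into canonical signature text."""
    lhs = [(s, -c) for s, c in sorted(stoich.items()) if c < 0]
    rhs = [(s, c) for s, c in sorted(stoich.items()) if c > 0]

    def side(terms):
        if not terms:
            return "0"
        return " + ".join(
            name if coef == 1.0 else f"{_fmt_coef(coef)} {name}" for name, coef in terms
        )

    return f"{side(lhs)} = {side(rhs)}"


def canonical_signature(stoich_or_text: Mapping[str, float] | str) -> str:
    if isinstance(stoich_or_text, str):
        stoich_or_text = parse_signature(stoich_or_text)
    return format_signature(stoich_or_text)


# ---------------------------------------------------------------------------
# Geochemical database
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatabaseEntry:
    stoichiometry: Mapping[str, float]
    log10_keq: float
    log10_k: float | None = None
    ssa: float | None = None


@dataclass
class GeochemDatabase:
    """Thermodynamic (and optional default kinetic) constants keyed by the
    canonical reaction signature."""

    entries: dict[str, DatabaseEntry]

    def lookup(self, signature: str) -> DatabaseEntry:
        key = canonical_signature(signature)
        if key not in self.entries:
            raise NetworkError(f"reaction {key!r} not found in database")
        return self.entries[key]

    def __eq__(self, other):
        return isinstance(other, GeochemDatabase) and self.entries == other.entries


_KEYVAL_RE = re.compile(r"^\s*(logK|logk|ssa)\s*=\s*([-+0-9.eE]+)\s*$")
_DB_KEYS = {"logK", "logk", "ssa"}


def parse_database(text: str) -> GeochemDatabase:
    """Parse the line-oriented constants file.

    Each non-comment line reads ``<signature> : logK=<val>[, logk=<val>]
    [, ssa=<val>]``. ``#`` starts a comment; blank lines are skipped. Unknown
    keys, duplicate signatures, and malformed lines raise
    :class:`DatabaseParseError` with the line number.
    """
    entries: dict[str, DatabaseEntry] = {}
    saw_line = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        saw_line = True
        if ":" not in line:
            raise DatabaseParseError("expected '<signature> : key=value[, ...]'", lineno)
        sig_text, rest = line.split(":", 1)
        try:
            stoich = parse_signature(sig_text.strip())
        except DatabaseParseError as exc:
            raise DatabaseParseError(str(exc), lineno) from None
        values: dict[str, float] = {}
        for part in rest.split(","):
            m = _KEYVAL_RE.match(part)
            if m is None:
                raise DatabaseParseError(f"bad key=value field {part.strip()!r} "
                                         f"(known keys: {sorted(_DB_KEYS)})", lineno)
            key = m.group(1)
            if key in values:
                raise DatabaseParseError(f"duplicate key {key!r}", lineno)
            values[key] = float(m.group(2))
        if "logK" not in values:
            raise DatabaseParseError("every entry must carry logK", lineno)
        key = format_signature(stoich)
        if key in entries:
            raise DatabaseParseError(f"duplicate reaction signature {key!r}", lineno)
        entries[key] = DatabaseEntry(
            stoichiometry=stoich,
            log10_keq=values["logK"],
            log10_k=values.get("logk"),
            ssa=values.get("ssa"),
        )
    if not saw_line:
        raise DatabaseParseError("database text is empty")
    return GeochemDatabase(entries)


def serialize_database(db: GeochemDatabase) -> str:
    lines = []
    for sig in sorted(db.entries):
        e = db.entries[sig]
        fields = [f"logK={e.log10_keq:g}"]
        if e.log10_k is not None:
            fields.append(f"logk={e.log10_k:g}")
        if e.ssa is not None:
            fields.append(f"ssa={e.ssa:g}")
        lines.append(f"{sig} : " + ", ".join(fields))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Reaction network
# ---------------------------------------------------------------------------

@dataclass
class ReactionNetwork:
    species: list[SpeciesDef]
    equilibrium: list[ReactionDef]                      # all zones unless scoped
    equilibrium_zones: dict[str, tuple[str, ...]]       # reaction id -> zones
    kinetic_by_zone: dict[str, list[ReactionDef]]
    #: constant surface-area term per (zone, reaction id), m^2 substrate per
    #: m^2 catchment (SSA x areal substrate density); fixed in time.
    surface_area: dict[tuple[str, str], float]
    secondary_of: dict[str, ReactionDef]                # secondary name -> defining rxn

    def species_def(self, name: str) -> SpeciesDef:
        for sp in self.species:
            if sp.name == name:
                return sp
        raise NetworkError(f"species {name!r} not declared in network")

    @property
    def primaries(self) -> list[str]:
        """Species whose totals are time-stepped (aqueous primaries + sorption
        sites)."""
        return [s.name for s in self.species
                if s.phase in (AQUEOUS_PRIMARY, SORPTION_SITE)]

    @property
    def mobile_primaries(self) -> list[str]:
        return [s.name for s in self.species if s.phase == AQUEOUS_PRIMARY]

    def equilibrium_for_zone(self, zone: str) -> list[ReactionDef]:
        return [r for r in self.equilibrium
                if zone in self.equilibrium_zones.get(r.id, ZONES)]


def stoichiometric_increment(reaction: ReactionDef, extent: float) -> dict[str, float]:
    """Species increments (mol/m^2) for a given reaction extent.

    Reactant entries come out negative and product entries positive; the map
    scales linearly with extent so opposite extents cancel exactly.
    """
    if not math.isfinite(extent):
        raise ValueError("extent must be finite")
    return {s: c * extent for s, c in reaction.stoichiometry.items()}


def resolve_tableau(
    primaries: Iterable[str],
    secondaries: dict[str, ReactionDef],
    fixed_activity: Iterable[str] = (),
) -> dict[str, tuple[dict[str, float], float, dict[str, float]]]:
    """Express every secondary species in terms of primaries.

    For each secondary ``s`` with defining reaction ``R`` (mass action
    ``Keq = prod a^nu``), returns ``(coeffs, log10_kf, gas_coeffs)`` such that

        log10 a_s = log10_kf + sum_p coeffs[p] * log10 a_p
                             + sum_g gas_coeffs[g] * log10 a_g

    where ``p`` ranges over primaries and ``g`` over fixed-activity species
    (solids, pseudo-gases; water is dropped at unit activity). Secondaries may
    be defined via other secondaries as long as the dependency graph is
    acyclic; unresolvable configurations raise :class:`NetworkError`.
    """
    primaries = list(primaries)
    fixed = set(fixed_activity)
    resolved: dict[str, tuple[dict[str, float], float, dict[str, float]]] = {}
    pending = dict(secondaries)
    while pending:
        progressed = False
        for name, rxn in list(pending.items()):
            nu_s = rxn.stoichiometry.get(name)
            if nu_s is None or nu_s == 0:
                raise NetworkError(
                    f"secondary {name!r} does not appear in its defining reaction {rxn.id!r}"
                )
            others = {s: c for s, c in rxn.stoichiometry.items() if s != name}
            if any(s in pending for s in others):
                continue  # wait for the inner secondary to resolve first
            # log Keq = nu_s log a_s + sum_others nu_i log a_i
            coeffs: dict[str, float] = {}
            gas_coeffs: dict[str, float] = {}
            log_kf = rxn.log10_keq / nu_s
            for s, c in others.items():
                w = -c / nu_s
                if s == WATER:
                    continue
                if s in fixed:
                    gas_coeffs[s] = gas_coeffs.get(s, 0.0) + w
                elif s in primaries:
                    coeffs[s] = coeffs.get(s, 0.0) + w
                elif s in resolved:
                    inner_c, inner_kf, inner_g = resolved[s]
                    log_kf += w * inner_kf
                    for p, wc in inner_c.items():
                        coeffs[p] = coeffs.get(p, 0.0) + w * wc
                    for g, wc in inner_g.items():
                        gas_coeffs[g] = gas_coeffs.get(g, 0.0) + w * wc
                else:
                    raise NetworkError(
                        f"secondary {name!r} references {s!r}, which is neither a "
                        f"primary, a fixed-activity species, nor a resolvable secondary"
                    )
            resolved[name] = (coeffs, log_kf, gas_coeffs)
            del pending[name]
            progressed = True
        if not progressed:
            raise NetworkError(
                "secondary species cannot be expressed via primaries (cyclic or "
                f"missing definitions): {sorted(pending)}"
            )
    return resolved


# ---------------------------------------------------------------------------
# Network configuration (TOML)
# ---------------------------------------------------------------------------

_PHASE_KEYS = {
    "primary": AQUEOUS_PRIMARY,
    "secondary": AQUEOUS_SECONDARY,
    "solid": SOLID,
    "sorption_site": SORPTION_SITE,
    "sorbed": SORBED,
    "gas": PSEUDO_GAS,
}


def build_network(config: str | Mapping,
                  db: GeochemDatabase | None = None) -> ReactionNetwork:
    """Assemble and validate a :class:`ReactionNetwork` from TOML text (or an
    already-parsed mapping) plus a constants database.

    Validation: unique species names, every secondary/sorbed species has
    exactly one defining equilibrium reaction resolvable down to primaries
    (tableau construction), kinetic reactions reference only declared species,
    and the per-(zone, reaction) surface-area term is precomputed as
    SSA (m^2/g) x areal substrate density (g/m^2).
    """
    if isinstance(config, str):
        cfg = tomllib.loads(config)
    else:
        cfg = dict(config)

    sp_cfg = cfg.get("species", {})
    species: list[SpeciesDef] = []
    seen: set[str] = set()
    for key, phase in _PHASE_KEYS.items():
        for name in sp_cfg.get(key, []):
            if name in seen:
                raise NetworkError(f"species {name!r} declared more than once")
            seen.add(name)
            species.append(SpeciesDef(name, phase))
    if WATER not in seen:
        species.append(SpeciesDef(WATER, SOLID))  # unit activity, never balanced
        seen.add(WATER)
    declared = seen

    def check_declared(stoich: Mapping[str, float], where: str):
        for s in stoich:
            if s not in declared:
                raise NetworkError(f"undeclared species {s!r} referenced by {where}")

    # --- equilibrium reactions: one per secondary/sorbed species
    secondary_names = [s.name for s in species
                       if s.phase in (AQUEOUS_SECONDARY, SORBED)]
    sec_cfg = cfg.get("secondary_reactions", {})
    equilibrium: list[ReactionDef] = []
    equilibrium_zones: dict[str, tuple[str, ...]] = {}
    secondary_of: dict[str, ReactionDef] = {}
    for name in secondary_names:
        if name not in sec_cfg:
            raise NetworkError(f"secondary species {name!r} has no defining "
                               "equilibrium reaction")
        spec = sec_cfg[name]
        if isinstance(spec, str):
            sig, zones = spec, ZONES
        else:
            sig = spec["signature"]
            zones = tuple(spec.get("zones", ZONES))
        if db is None:
            raise NetworkError("a database is required for equilibrium reactions")
        entry = db.lookup(sig)
        stoich = parse_signature(sig)
        check_declared(stoich, f"equilibrium reaction for {name!r}")
        if name not in stoich:
            raise NetworkError(f"defining reaction for {name!r} does not contain it")
        rxn = ReactionDef(
            id=f"eq_{name}", kind=EQUILIBRIUM, stoichiometry=stoich,
            log10_keq=entry.log10_keq,
        )
        equilibrium.append(rxn)
        equilibrium_zones[rxn.id] = zones
        secondary_of[name] = rxn
    extra = set(sec_cfg) - set(secondary_names)
    if extra:
        raise NetworkError(f"secondary_reactions given for undeclared secondaries: {sorted(extra)}")

    # --- tableau validation (per zone scope; full set must resolve)
    primaries = [s.name for s in species if s.phase in (AQUEOUS_PRIMARY, SORPTION_SITE)]
    fixed = [s.name for s in species if s.phase in (SOLID, PSEUDO_GAS)]
    resolve_tableau(primaries, secondary_of, fixed)

    # --- kinetic reactions
    kin_cfg = cfg.get("kinetics", {})
    kinetic_by_zone: dict[str, list[ReactionDef]] = {z: [] for z in ZONES}
    surface_area: dict[tuple[str, str], float] = {}
    for zone, rxn_list in kin_cfg.items():
        if zone not in ZONES:
            raise NetworkError(f"unknown zone {zone!r} in kinetics section")
        for item in rxn_list:
            name = item["name"]
            sig = item["signature"]
            stoich = parse_signature(sig)
            check_declared(stoich, f"kinetic reaction {name!r}")
            kind = {"tst": KINETIC_TST, "monod": KINETIC_MONOD}.get(item.get("rate", "monod"))
            if kind is None:
                raise NetworkError(f"kinetic reaction {name!r}: rate must be 'tst' or 'monod'")
            log10_keq = item.get("log10_keq")
            if kind == KINETIC_TST and log10_keq is None:
                if db is None:
                    raise NetworkError(f"TST reaction {name!r} needs a database Keq")
                log10_keq = db.lookup(sig).log10_keq
            monod = dict(item.get("monod", {}))
            inhibition = dict(item.get("inhibition", {}))
            catalyst = dict(item.get("catalyst", {}))
            for s in list(monod) + list(inhibition) + list(catalyst):
                if s not in declared:
                    raise NetworkError(f"undeclared species {s!r} in rate terms of {name!r}")
            env = EnvParams(
                q10=float(item.get("q10", 1.0)),
                n=float(item.get("n", 0.0)),
                swc=float(item.get("swc", 1.0)),
                alpha_beta=float(item.get("alpha_beta", 0.0)),
            )
            rxn = ReactionDef(
                id=name, kind=kind, stoichiometry=stoich,
                log10_keq=log10_keq,
                log10_k=float(item["log10_k"]),
                ssa=float(item.get("ssa", 1.0)),
                substrate=item.get("substrate"),
                monod_terms=monod, inhibition_terms=inhibition,
                catalyst_terms=catalyst, env=env,
            )
            kinetic_by_zone[zone].append(rxn)
            density = float(item.get("substrate_density", 1.0))  # g/m^2
            surface_area[(zone, name)] = (rxn.ssa or 1.0) * density

    return ReactionNetwork(
        species=species,
        equilibrium=equilibrium,
        equilibrium_zones=equilibrium_zones,
        kinetic_by_zone=kinetic_by_zone,
        surface_area=surface_area,
        secondary_of=secondary_of,
    )
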