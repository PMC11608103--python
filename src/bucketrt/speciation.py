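"""Equilibrium speciation by Newton-Raphson on log-concentrations.

Given total (component) concentrations of the primary species, solve the
coupled mass-action + mole-balance system for all species. Activities are
taken equal to concentrations (dilute-solution convention, no ionic-strength
correction); solids have unit activity and pseudo-gases a prescribed one, so
neither enters the balances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .chem import (
    AQUEOUS_PRIMARY,
    SORPTION_SITE,
    WATER,
    ReactionDef,
    ReactionNetwork,
    resolve_tableau,
)

__all__ = ["EquilibriumSystem", "SpeciationState", "SpeciationError",
           "speciate", "log_ion_activity_product"]

MAX_ITER = 100
REL_TOL = 1e-10
ABS_TOL = 1e-18   # mol/L; lets zero-total components settle at the floor
MAX_DLOG10 = 1.0  # damping: largest per-iteration move in log10 units

CONC_FLOOR = 1e-20  # mol/L


class SpeciationError(RuntimeError):
    """Non-convergence; carries the residual vector for diagnostics."""

    def __init__(self, message: str, residuals: Mapping[str, float] | None = None):
        super().__init__(message)
        self.residuals = dict(residuals or {})


@dataclass
class EquilibriumSystem:
    """Precompiled tableau for one zone.

    ``tableau[s, p]`` is the coefficient of primary ``p`` in the formation
    expression of secondary ``s``:

        log10 c_s = log_kf[s] + sum_p tableau[s, p] * log10 c_p

    with fixed-activity contributions already folded into ``log_kf``.
    """

    primaries: list[str]
    secondaries: list[str]
    tableau: np.ndarray          # (n_sec, n_prim)
    log_kf: np.ndarray           # (n_sec,)
    reactions: dict[str, ReactionDef]   # defining reaction per secondary
    fixed_activities: dict[str, float] = field(default_factory=dict)
    unit_activity: frozenset[str] = frozenset()   # solids etc. at activity 1
    immobile_primaries: frozenset[str] = frozenset()
    immobile_secondaries: frozenset[str] = frozenset()

    @classmethod
    def from_network(
        cls,
        network: ReactionNetwork,
        zone: str = "SZ",
        fixed_activities: Mapping[str, float] | None = None,
        fixed_primaries: Mapping[str, float] | None = None,
    ) -> "EquilibriumSystem":
        """Build the zone's system from a validated network.

        ``fixed_activities`` prescribes pseudo-gas activities (e.g. soil pCO2).
        ``fixed_primaries`` pins chosen primaries at a known activity (useful
        for fixed-pH calculations); they leave the unknown set and their
        contribution is folded into the formation constants.
        """
        fixed_act = dict(fixed_activities or {})
        fixed_prim = dict(fixed_primaries or {})
        prim_defs = [s for s in network.species
                     if s.phase in (AQUEOUS_PRIMARY, SORPTION_SITE)]
        primaries = [s.name for s in prim_defs if s.name not in fixed_prim]
        immobile_prim = frozenset(s.name for s in prim_defs if s.phase == SORPTION_SITE)

        zone_rxns = {}
        for name, rxn in network.secondary_of.items():
            if zone in network.equilibrium_zones.get(rxn.id, ("SF", "SZ", "DZ")):
                zone_rxns[name] = rxn
        fixed_names = [s.name for s in network.species if s.fixed_activity]
        fixed_names += list(fixed_prim)
        resolved = resolve_tableau(primaries, zone_rxns, fixed_names)

        secondaries = sorted(resolved)
        tab = np.zeros((len(secondaries), len(primaries)))
        log_kf = np.zeros(len(secondaries))
        p_index = {p: i for i, p in enumerate(primaries)}
        for i, s in enumerate(secondaries):
            coeffs, kf, gas = resolved[s]
            log_kf[i] = kf
            for p, c in coeffs.items():
                tab[i, p_index[p]] = c
            for g, c in gas.items():
                act = fixed_act.get(g, fixed_prim.get(g, 1.0))
                log_kf[i] += c * np.log10(act)
        immobile_sec = frozenset(
            s for s in secondaries if not network.species_def(s).mobile
        )
        unit_act = frozenset(
            s.name for s in network.species
            if s.fixed_activity and s.name not in fixed_act
        )
        fixed_act.update({p: float(v) for p, v in fixed_prim.items()})
        return cls(
            primaries=primaries, secondaries=secondaries, tableau=tab,
            log_kf=log_kf, reactions=zone_rxns, fixed_activities=fixed_act,
            unit_activity=unit_act,
            immobile_primaries=immobile_prim, immobile_secondaries=immobile_sec,
        )


@dataclass
class SpeciationState:
    """Converged concentrations (mol/L), the totals they satisfy, and log10
    ion-activity products of the zone's equilibrium reactions."""

    conc: dict[str, float]
    totals: dict[str, float]
    log_iap: dict[str, float]
    system: EquilibriumSystem

    def activity(self, species: str) -> float:
        if species == WATER:
            return 1.0
        if species in self.conc:
            return self.conc[species]
        if species in self.system.fixed_activities:
            return self.system.fixed_activities[species]
        if species in self.system.unit_activity:
            return 1.0
        raise KeyError(f"species {species!r} not present in speciation state")

    def mobile_total(self, primary: str) -> float:
        """Component total carried by flowing water (excludes the sorbed /
        site-bound share)."""
        sys = self.system
        if primary in sys.immobile_primaries:
            return 0.0
        j = sys.primaries.index(primary)
        tot = self.conc[primary]
        for i, s in enumerate(sys.secondaries):
            if s in sys.immobile_secondaries:
                continue
            tot += sys.tableau[i, j] * self.conc[s]
        return tot


def _secondary_conc(sys: EquilibriumSystem, logc_p: np.ndarray) -> np.ndarray:
    return 10.0 ** (sys.log_kf + sys.tableau @ logc_p)


def speciate(
    totals: Mapping[str, float],
    sys: EquilibriumSystem,
    guess: Mapping[str, float] | None = None,
) -> SpeciationState:
    """Solve mole balance + mass action for all species.

    ``totals`` maps each primary to its component total (mol/L); totals of a
    primary like H+ may be negative (alkalinity convention). Unknowns are
    log10 concentrations of primaries, so positivity is structural. Newton
    steps are damped to one log10 unit; convergence requires every balance
    residual below ``REL_TOL`` relative to the component's gross size.
    """
    n = len(sys.primaries)
    tot = np.array([float(totals[p]) for p in sys.primaries])
    if not np.all(np.isfinite(tot)):
        raise ValueError("component totals must be finite")

    # primaries no secondary is built from decouple: their free concentration
    # equals their total (floored at a trace value if the total is zero)
    n_sec = len(sys.secondaries)
    coupled = (np.abs(sys.tableau) > 0).any(axis=0) if n_sec else np.zeros(n, bool)
    logc = np.empty(n)
    logc[~coupled] = np.log10(np.maximum(tot[~coupled], CONC_FLOOR))

    idx = np.flatnonzero(coupled)
    if idx.size:
        tab = sys.tableau[:, idx]
        abs_tab = np.abs(tab)
        if guess is not None:
            c0 = np.array([max(float(guess.get(sys.primaries[j], 1e-7)), CONC_FLOOR)
                           for j in idx])
        else:
            c0 = np.where(tot[idx] > 0, np.maximum(tot[idx], CONC_FLOOR), 1e-7)
        x = np.log10(c0)
        ln10 = np.log(10.0)
        kf_other = sys.log_kf + sys.tableau[:, ~coupled] @ logc[~coupled]
        for _ in range(MAX_ITER):
            c_p = 10.0 ** x
            c_s = 10.0 ** (kf_other + tab @ x)
            resid = c_p + tab.T @ c_s - tot[idx]
            scale = np.maximum(np.abs(tot[idx]), c_p + abs_tab.T @ c_s)
            scale = np.maximum(scale, CONC_FLOOR)
            if np.all(np.abs(resid) <= REL_TOL * scale + ABS_TOL):
                break
            # d resid_q / d log10 c_p = ln10 * (diag(c_p) + T^T diag(c_s) T)
            jac = ln10 * (np.diag(c_p) + tab.T @ (c_s[:, None] * tab))
            try:
                step = np.linalg.solve(jac, -resid)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(jac, -resid, rcond=None)[0]
            big = np.max(np.abs(step))
            if big > MAX_DLOG10:
                step *= MAX_DLOG10 / big
            x = x + step
        else:
            raise SpeciationError(
                "speciation did not converge in "
                f"{MAX_ITER} iterations (max residual {np.max(np.abs(resid)):.3e})",
                residuals={sys.primaries[j]: float(r) for j, r in zip(idx, resid)},
            )
        logc[idx] = x

    conc = {p: float(10.0 ** logc[i]) for i, p in enumerate(sys.primaries)}
    c_s = _secondary_conc(sys, logc)
    conc.update({s: float(c_s[i]) for i, s in enumerate(sys.secondaries)})

    state = SpeciationState(conc=conc, totals={p: float(t) for p, t in
                                               zip(sys.primaries, tot)},
                            log_iap={}, system=sys)
    for s, rxn in sys.reactions.items():
        state.log_iap[rxn.id] = log_ion_activity_product(state, rxn)
    return state


def log_ion_activity_product(state: SpeciationState, rxn: ReactionDef) -> float:
    """log10 IAP = sum over species of nu * log10 activity (products positive),
    with unit activity for water and solids and prescribed activity for
    pseudo-gases."""
    total = 0.0
    for s, nu in rxn.stoichiometry.items():
        a = state.activity(s)
        total += nu * np.log10(a)
    return float(total)
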