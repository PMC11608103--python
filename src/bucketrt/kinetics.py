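"""Kinetic rate laws and the within-zone reaction integrator.

Every kinetic rate takes the factored form

    r = k * A * f(T) * f(Sw) * f(Zw) * <chemical term>

with k the rate constant (mol/m^2 substrate/s, stored as log10), A the
constant substrate surface area per unit catchment area (m^2/m^2), and the
chemical term either the TST departure-from-equilibrium factor
``a^m (1 - IAP/Keq)`` or a Monod x inhibition product. Rates are expressed in
mol per m^2 of catchment per day; dividing by the zone water storage
(mm = L/m^2) converts a rate into a concentration change.

The reaction step advances component totals with a Crank-Nicolson scheme
(average of start- and end-of-step rates) solved by Newton-Raphson; the step
is halved on convergence failure, up to ``MAX_HALVINGS`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chem import KINETIC_MONOD, KINETIC_TST, ReactionDef
from .speciation import (
    EquilibriumSystem,
    SpeciationError,
    SpeciationState,
    speciate,
)

__all__ = [
    "RateContext",
    "RateBreakdown",
    "ReactionStepError",
    "env_factor_T",
    "env_factor_Sw",
    "env_factor_Zw",
    "kinetic_rate",
    "rate_breakdown",
    "integrate_zone_reactions",
]

SEC_PER_DAY = 86400.0
MAX_HALVINGS = 12
#: largest fraction of a component's total a single Crank-Nicolson sub-step
#: may turn over before the step is halved for accuracy
MAX_REL_CHANGE = 0.1
NEWTON_TOL = 1e-10     # relative to the size of the step's mass turnover
NEWTON_MAX_ITER = 30
#: implicit availability guard for consumed solutes in Monod-kind reactions
#: (far below any meaningful half-saturation constant); also sets the
#: concentration scale over which a zero-order sink shuts off smoothly
GUARD_KM = 1e-9
T_REF = 20.0           # deg C reference of the Q10 response


class ReactionStepError(RuntimeError):
    """Reaction integration failed at the minimum sub-step."""


@dataclass
class RateContext:
    """Environmental drivers for one zone and step."""

    temp: float            # deg C
    sw: float              # saturation fraction in [0, 1]
    zw: float              # water table depth, m
    dt: float              # day
    water_volume: float    # mm = L/m^2
    substrate_conc: Mapping[str, float] = field(default_factory=dict)
    signed_q10: bool = False

    def __post_init__(self):
        if not (0.0 <= self.sw <= 1.0):
            raise ValueError("sw must lie in [0, 1]")
        if self.zw < 0:
            raise ValueError("zw must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


@dataclass
class RateBreakdown:
    raw_rate: float                    # mol/m^2/day (signed)
    env_factors: tuple[float, float, float]
    saturation_term: float | None      # 1 - IAP/Keq, TST only
    monod_term: float
    inhibition_term: float


def env_factor_T(temp: float, q10: float, signed: bool = False) -> float:
    """Temperature response ``q10 ** (|T - 20| / 10)``.

    q10 = 1 disables the dependence. The printed absolute-value form raises
    rates on both sides of 20 degC; pass ``signed=True`` for the conventional
    monotone form ``q10 ** ((T - 20) / 10)``.
    """
    if q10 <= 0:
        raise ValueError("q10 must be > 0")
    expo = (temp - T_REF) / 10.0 if signed else abs(temp - T_REF) / 10.0
    return float(q10 ** expo)


def env_factor_Sw(sw: float, swc: float, n: float) -> float:
    """Soil-moisture response: power law rising to 1 at the critical
    saturation swc and falling above it; n = 0 disables the dependence."""
    if not (0.0 < swc <= 1.0):
        raise ValueError("swc must lie in (0, 1]")
    if n == 0:
        return 1.0
    if sw <= swc:
        return float((sw / swc) ** n)
    return float(((1.0 - sw) / (1.0 - swc)) ** n)


def env_factor_Zw(zw: float, alpha_beta: float) -> float:
    """Water-table-depth response ``exp(-(alpha*beta) * Zw)``.

    Only the product alpha*beta is prescribed; a positive product makes rates
    fall as the table drops (rise as it shallows), a negative product the
    opposite, zero disables the dependence.
    """
    if zw < 0:
        raise ValueError("zw must be >= 0")
    return float(np.exp(-alpha_beta * zw))


def _env_product(rxn: ReactionDef, ctx: RateContext) -> tuple[float, float, float]:
    ft = env_factor_T(ctx.temp, rxn.env.q10, signed=ctx.signed_q10)
    fsw = env_factor_Sw(ctx.sw, rxn.env.swc, rxn.env.n)
    fzw = env_factor_Zw(ctx.zw, rxn.env.alpha_beta)
    return ft, fsw, fzw


def _term_conc(species: str, state: SpeciationState, ctx: RateContext) -> float:
    """Concentration entering a Monod/inhibition term: aqueous species read
    from the speciated state, solid/pseudo-gas substrates from the prescribed
    per-zone availability (mol/L-equivalent)."""
    if species in state.conc:
        return state.conc[species]
    if species in ctx.substrate_conc:
        return float(ctx.substrate_conc[species])
    raise KeyError(
        f"no concentration available for rate-law species {species!r}; "
        "declare a substrate availability for it in the zone configuration"
    )


def rate_breakdown(
    rxn: ReactionDef,
    state: SpeciationState,
    ctx: RateContext,
    area: float,
) -> RateBreakdown:
    """Full factor decomposition of one kinetic rate (mol/m^2 catchment/day)."""
    if rxn.kind not in (KINETIC_TST, KINETIC_MONOD):
        raise ValueError(f"{rxn.id!r} is not a kinetic reaction")
    ft, fsw, fzw = _env_product(rxn, ctx)
    base = (10.0 ** rxn.log10_k) * SEC_PER_DAY * area * ft * fsw * fzw

    saturation = None
    monod = 1.0
    inhibition = 1.0
    if rxn.kind == KINETIC_TST:
        if rxn.log10_keq is None:
            raise ValueError(f"TST reaction {rxn.id!r} lacks an equilibrium constant")
        from .speciation import log_ion_activity_product

        log_iap = log_ion_activity_product(state, rxn)
        saturation = 1.0 - 10.0 ** (log_iap - rxn.log10_keq)
        chem = saturation
        for s, m in rxn.catalyst_terms.items():
            chem *= state.activity(s) ** m
    else:
        for s, km in rxn.monod_terms.items():
            c = _term_conc(s, state, ctx)
            monod *= c / (c + km)
        for s, ki in rxn.inhibition_terms.items():
            c = _term_conc(s, state, ctx)
            inhibition *= ki / (c + ki)
        # availability guard: a consumed solute cannot be drawn below zero
        for s, nu in rxn.stoichiometry.items():
            if nu < 0 and s in state.conc:
                c = max(state.conc[s], 0.0)
                monod *= c / (c + GUARD_KM)
        chem = monod * inhibition
    return RateBreakdown(
        raw_rate=float(base * chem),
        env_factors=(ft, fsw, fzw),
        saturation_term=saturation,
        monod_term=monod,
        inhibition_term=inhibition,
    )


def kinetic_rate(
    rxn: ReactionDef,
    state: SpeciationState,
    ctx: RateContext,
    area: float,
) -> float:
    """Signed reaction rate in mol/m^2 catchment/day (negative TST rate =
    precipitation)."""
    return rate_breakdown(rxn, state, ctx, area).raw_rate


# ---------------------------------------------------------------------------
# Zone reaction integration (Crank-Nicolson + Newton-Raphson, adaptive halving)
# ---------------------------------------------------------------------------

def _stoich_matrix(rxns: Sequence[ReactionDef], sys: EquilibriumSystem) -> np.ndarray:
    """(n_rxn, n_prim) stoichiometry expressed on component totals.

    A kinetic reaction producing a secondary species (e.g. dissolved CO2)
    increments the component totals of the primaries that secondary is built
    from, via the tableau.
    """
    prim = sys.primaries
    p_index = {p: j for j, p in enumerate(prim)}
    s_index = {s: i for i, s in enumerate(sys.secondaries)}
    S = np.zeros((len(rxns), len(prim)))
    for i, rxn in enumerate(rxns):
        for name, nu in rxn.stoichiometry.items():
            if name in p_index:
                S[i, p_index[name]] += nu
            elif name in s_index:
                S[i, :] += nu * sys.tableau[s_index[name], :]
            # solids / pseudo-gases carry no balanced total
    return S


def integrate_zone_reactions(
    totals: Mapping[str, float],
    rxns: Sequence[ReactionDef],
    ctx: RateContext,
    sys: EquilibriumSystem,
    areas: Mapping[str, float],
    guess: Mapping[str, float] | None = None,
) -> tuple[SpeciationState, dict[str, float]]:
    """Advance one zone's component totals over ``ctx.dt`` under its kinetic
    reactions.

    Returns the re-speciated end state and the time-averaged rate of each
    reaction (mol/m^2/day). The update satisfies, to machine precision,

        delta(total_p) = sum_rxn stoich[p] * mean_rate * dt / V_w

    because the mean rates are accumulated from the same Crank-Nicolson
    increments applied to the totals.
    """
    prim = sys.primaries
    t = np.array([float(totals[p]) for p in prim])
    area_vec = np.array([float(areas.get(r.id, 0.0)) for r in rxns])
    S = _stoich_matrix(rxns, sys)
    state0 = speciate(dict(zip(prim, t)), sys, guess=guess)
    if not rxns:
        return state0, {}

    def rates(state: SpeciationState) -> np.ndarray:
        return np.array([
            rate_breakdown(r, state, ctx, a).raw_rate
            for r, a in zip(rxns, area_vec)
        ])

    vw = ctx.water_volume  # L/m^2: converts mol/m^2 to mol/L
    mean_rate_num = np.zeros(len(rxns))
    remaining = ctx.dt
    dt_sub = ctx.dt
    halvings = 0
    state_cur = state0
    t_cur = t.copy()

    while remaining > 1e-15 * ctx.dt:
        dt_try = min(dt_sub, remaining)
        r0 = rates(state_cur)
        try:
            t_new, r1, state_new = _cn_substep(
                t_cur, r0, rxns, S, area_vec, ctx, sys, vw, dt_try, state_cur
            )
            # accuracy control: a sub-step that turns over a large share of
            # an established component is re-done at half the step (growth
            # from an empty pool is exempt — its relative change is always 1)
            denom = np.abs(t_cur)
            big = denom > 1e-10
            if np.any(np.abs(t_new - t_cur)[big] > MAX_REL_CHANGE * denom[big]) \
                    and halvings < MAX_HALVINGS:
                t_new = None
        except (SpeciationError, np.linalg.LinAlgError, FloatingPointError):
            t_new = None
        if t_new is None:
            halvings += 1
            if halvings > MAX_HALVINGS:
                raise ReactionStepError(
                    f"reaction step failed to converge after {MAX_HALVINGS} "
                    f"halvings (dt={dt_try:g} d, zone totals={dict(zip(prim, t_cur))})"
                )
            dt_sub = dt_try / 2.0
            continue
        mean_rate_num += 0.5 * (r0 + r1) * dt_try
        t_cur = t_new
        state_cur = state_new
        remaining -= dt_try
        halvings = 0
        dt_sub = min(dt_try * 2.0, ctx.dt)  # recover after a successful step

    mean_rates = {r.id: float(mean_rate_num[i] / ctx.dt) for i, r in enumerate(rxns)}
    return state_cur, mean_rates


def _cn_substep(t0, r0, rxns, S, area_vec, ctx, sys, vw, dt, state_prev):
    """One Crank-Nicolson sub-step; returns (t1, end rates, end state) or
    raises on non-convergence."""
    prim = sys.primaries
    n = len(prim)

    def residual(t1):
        state1 = speciate(dict(zip(prim, t1)), sys, guess=state_prev.conc)
        r1 = np.array([
            rate_breakdown(r, state1, ctx, a).raw_rate
            for r, a in zip(rxns, area_vec)
        ])
        g = t1 - t0 - (dt / (2.0 * vw)) * (S.T @ (r0 + r1))
        return g, r1, state1

    # predictor: implicit-free start from the current state
    t1 = t0.copy()
    g, r1, state1 = residual(t1)
    # tolerance scales with both the totals and the step's mass turnover,
    # so components sitting near zero (e.g. alkalinity crossing sign) are
    # judged against the reaction fluxes instead of an empty total
    turnover = (dt / (2.0 * vw)) * (np.abs(S).T @ (np.abs(r0) + np.abs(r1)))
    scale = np.maximum(np.maximum(np.abs(t0), turnover), 1e-16)
    jac = None
    for it in range(NEWTON_MAX_ITER):
        if np.all(np.abs(g) <= NEWTON_TOL * scale):
            # enforce the discrete identity exactly: totals advance by the
            # same trapezoidal increment that is reported as the mean rate
            t1 = t0 + (dt / (2.0 * vw)) * (S.T @ (r0 + r1))
            state1 = speciate(dict(zip(prim, t1)), sys, guess=state1.conc)
            return t1, r1, state1
        if jac is None or it % 4 == 0:  # chord Newton, refresh occasionally
            jac = np.eye(n)
            for j in range(n):
                # keep the probe large enough to sense the availability guard
                h = max(1e-6 * abs(t1[j]), 1e-10)
                tp = t1.copy()
                tp[j] += h
                gp, _, _ = residual(tp)
                jac[:, j] = (gp - g) / h
        step = np.linalg.solve(jac, -g)
        # backtrack if the proposed totals are infeasible (speciation has no
        # solution, e.g. a negative total of a strictly positive component)
        for _ in range(6):
            try:
                g_new, r1_new, state1_new = residual(t1 + step)
                break
            except SpeciationError:
                step = step / 2.0
        else:
            raise SpeciationError("no feasible Newton step in reaction solve")
        t1 = t1 + step
        g, r1, state1 = g_new, r1_new, state1_new
        turnover = (dt / (2.0 * vw)) * (np.abs(S).T @ (np.abs(r0) + np.abs(r1)))
        scale = np.maximum(np.maximum(np.abs(t0), turnover), 1e-16)
    raise SpeciationError("Crank-Nicolson inner Newton did not converge")
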