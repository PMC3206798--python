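"""Crowding-constrained flux balance analysis.

The model finds, at a fixed proliferation rate μ, the non-negative fluxes
``f_i`` (mM/min) and compartment volume fractions ``φ_c`` (c ∈ {EnM, EM,
R, M}) that minimise the total nutrient import cost Σ_{i∈RI} c_i f_i,
subject to

* flux balance for every metabolite and macromolecule pool;
* a self-consistent protein balance: the protein-synthesis flux must cover
  growth dilution and basal turnover of non-metabolic protein (P0), of the
  protein tied up in enzyme complexes (n_PE Σ f_i/k_eff,i) and of ribosomal
  protein ((n_PR/v_R) φ_R);
* crowding links: φ_EnM (φ_EM) equal the summed enzyme volume demand of
  extra-(intra-)mitochondrial catalysis, φ_R covers ribosomes at a_R per
  unit protein-synthesis flux, and φ_M covers mitochondria at a_M,ATP per
  unit mitochondrial ATP production;
* the volume budget φ_EnM + φ_R + φ_M (+ optional φ_EM and the constant P0
  term) ≤ φ_max;
* box bounds (maintenance lower bound, proliferation flux pinned to μ).

μ is supplied in 1/day and converted to 1/min internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .biophysics import BiophysicalParams
from .network import (
    CELL_SPECIES,
    MAINTENANCE_ID,
    PROLIFERATION_ID,
    PROTEIN_SPECIES,
    PROTEIN_SYNTH_ID,
    Network,
)

__all__ = [
    "PER_DAY_TO_PER_MIN",
    "LPProblem",
    "FluxSolution",
    "protein_synthesis_demand",
    "assemble_lp",
    "solve_at_mu",
    "solve",
    "find_mu_max",
    "sweep_proliferation",
    "disable_crowding",
]

PER_DAY_TO_PER_MIN = 1.0 / (24.0 * 60.0)
PHI_COMPARTMENTS = ("EnM", "EM", "R", "M")

FEAS_TOL = 1e-9
OPT_TOL = 1e-9


def protein_synthesis_demand(fluxes, phi_R: float, mu_per_day: float,
                             params: BiophysicalParams,
                             keff=None) -> float:
    """Protein-synthesis flux (mM/min) required at steady state.

    (μ+k_D)[P0 + n_PE Σ_i f_i/k_eff,i + (n_PR/v_R) φ_R] with μ converted
    to 1/min.  ``fluxes`` maps reaction id -> mM/min for enzymatic
    reactions; ``keff`` maps reaction id -> 1/min (defaults to each
    reaction's ``keff`` when a Network-was-queried mapping is passed).
    """
    mu = mu_per_day * PER_DAY_TO_PER_MIN
    enzyme_conc = 0.0
    for rid, f in fluxes.items():
        k = keff[rid] if keff is not None else None
        if k is None:
            continue
        enzyme_conc += f / k
    return (mu + params.k_D) * (
        params.P0 + params.n_PE * enzyme_conc
        + (params.n_PR / params.v_R) * phi_R
    )


@dataclass
class LPProblem:
    """Assembled LP in scipy's linprog form, with tagged rows.

    Variables are ``[f_1..f_n, φ_EnM, φ_EM, φ_R, φ_M]``; every equality and
    inequality row carries a human-readable origin tag.
    """

    c: np.ndarray
    A_eq: np.ndarray
    b_eq: np.ndarray
    eq_tags: list[str]
    A_ub: np.ndarray
    b_ub: np.ndarray
    ub_tags: list[str]
    bounds: list[tuple[float, float]]
    reaction_ids: list[str]
    mu_per_day: float
    params: BiophysicalParams = field(repr=False)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def var_names(self) -> list[str]:
        return list(self.reaction_ids) + [f"phi_{c}" for c in PHI_COMPARTMENTS]


@dataclass
class FluxSolution:
    mu: float                      # 1/day
    fluxes: dict[str, float]       # mM/min per irreversible reaction
    phi: dict[str, float]          # volume fraction per compartment
    objective: float               # g/mmol · mM/min
    status: str                    # "optimal" | "infeasible"
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def net_fluxes(self, suffix: str = "_rev") -> dict[str, float]:
        """Collapse split forward/backward pairs to net fluxes."""
        net: dict[str, float] = {}
        for rid, f in self.fluxes.items():
            if rid.endswith(suffix):
                net[rid[: -len(suffix)]] = net.get(rid[: -len(suffix)], 0.0) - f
            else:
                net[rid] = net.get(rid, 0.0) + f
        return net


def _mito_atp_terms(net: Network, params: BiophysicalParams) -> dict[str, float]:
    """Positive-ATP stoichiometric coefficients of the reactions whose ATP
    output the mitochondrial crowding coefficient prices."""
    atp_ids = {m.id for m in net.metabolites if m.id.split("_")[0] == "atp"}
    out: dict[str, float] = {}
    for r in net.reactions:
        if r.rclass != "RM":
            continue
        if params.a_M_scope == "atp_synthase" and params.atp_synthase_ids:
            base = r.id[:-4] if r.id.endswith("_rev") else r.id
            if base not in params.atp_synthase_ids:
                continue
        coeff = sum(c for m, c in r.stoichiometry.items()
                    if m in atp_ids and c > 0)
        if coeff > 0:
            out[r.id] = coeff
    return out


def assemble_lp(net: Network, params: BiophysicalParams,
                mu_per_day: float) -> LPProblem:
    """Build the LP of the crowding model at proliferation rate μ (1/day).

    The network must already be split into irreversible reactions and every
    enzymatic reaction must carry a k_eff.
    """
    for r in net.reactions:
        if r.reversible:
            raise ValueError(
                f"reaction {r.id} still reversible; call split_reversible")
    for r in net.reactions:
        if r.is_enzymatic and (r.keff is None or r.keff <= 0):
            raise ValueError(f"reaction {r.id}: missing or invalid k_eff")

    mu = mu_per_day * PER_DAY_TO_PER_MIN
    n = len(net.reactions)
    nv = n + len(PHI_COMPARTMENTS)
    rid_pos = {r.id: j for j, r in enumerate(net.reactions)}
    phi_pos = {c: n + k for k, c in enumerate(PHI_COMPARTMENTS)}

    # objective: import costs
    c = np.zeros(nv)
    for j, r in enumerate(net.reactions):
        if r.rclass == "RI":
            c[j] = r.import_cost if r.import_cost is not None else 0.0

    eq_rows, b_eq, eq_tags = [], [], []
    ub_rows, b_ub, ub_tags = [], [], []

    # flux balance per metabolite
    growth_terms = (mu + params.k_D)
    for met in net.metabolites:
        row = np.zeros(nv)
        for j, r in enumerate(net.reactions):
            coeff = r.stoichiometry.get(met.id)
            if coeff:
                row[j] += coeff
        rhs = 0.0
        if met.id == PROTEIN_SPECIES:
            # self-consistent protein balance: dilution/turnover of P0,
            # enzyme-complex protein and ribosomal protein
            for j, r in enumerate(net.reactions):
                if r.is_enzymatic:
                    row[j] -= growth_terms * params.n_PE / r.keff
            row[phi_pos["R"]] -= growth_terms * params.n_PR / params.v_R
            rhs = growth_terms * params.P0
        if not row.any() and rhs == 0.0:
            continue  # orphan species (no producer/consumer)
        eq_rows.append(row)
        b_eq.append(rhs)
        eq_tags.append(f"balance:{met.id}")

    # crowding links: phi_EnM / phi_EM equalities
    for comp, rclass in (("EnM", "RnM"), ("EM", "RM")):
        row = np.zeros(nv)
        for j, r in enumerate(net.reactions):
            if r.rclass == rclass and r.is_enzymatic:
                row[j] = params.v_E / r.keff  # a_i
        row[phi_pos[comp]] = -1.0
        eq_rows.append(row)
        b_eq.append(0.0)
        eq_tags.append(f"crowding:phi_{comp}")

    # phi_M >= a_M,ATP * mitochondrial ATP production
    row = np.zeros(nv)
    for rid, coeff in _mito_atp_terms(net, params).items():
        row[rid_pos[rid]] = params.a_M_ATP * coeff
    row[phi_pos["M"]] = -1.0
    ub_rows.append(row)
    b_ub.append(0.0)
    ub_tags.append("crowding:phi_M")

    # phi_R >= a_R * f_protein_synthesis
    row = np.zeros(nv)
    if PROTEIN_SYNTH_ID in rid_pos:
        row[rid_pos[PROTEIN_SYNTH_ID]] = params.a_R
    row[phi_pos["R"]] = -1.0
    ub_rows.append(row)
    b_ub.append(0.0)
    ub_tags.append("crowding:phi_R")

    # volume budget
    if np.isfinite(params.phi_max):
        row = np.zeros(nv)
        row[phi_pos["EnM"]] = 1.0
        row[phi_pos["R"]] = 1.0
        row[phi_pos["M"]] = 1.0
        if params.count_EM_separately:
            row[phi_pos["EM"]] = 1.0
        ub_rows.append(row)
        b_ub.append(params.phi_max - params.p0_volume_fraction)
        ub_tags.append("crowding:budget")

    # bounds
    bounds: list[tuple[float, float]] = []
    for r in net.reactions:
        lo, hi = r.lower_bound, r.upper_bound
        if r.id == PROLIFERATION_ID:
            pinned = mu  # mM/min of cell-units (1 cell-unit ≡ 1 mM biomass)
            lo = hi = pinned
        bounds.append((lo, hi))
    phimax_bound = params.phi_max if np.isfinite(params.phi_max) else np.inf
    for comp in PHI_COMPARTMENTS:
        bounds.append((0.0, phimax_bound))

    A_eq = np.vstack(eq_rows) if eq_rows else np.zeros((0, nv))
    A_ub = np.vstack(ub_rows) if ub_rows else np.zeros((0, nv))
    return LPProblem(
        c=c, A_eq=A_eq, b_eq=np.array(b_eq), eq_tags=eq_tags,
        A_ub=A_ub, b_ub=np.array(b_ub), ub_tags=ub_tags, bounds=bounds,
        reaction_ids=[r.id for r in net.reactions],
        mu_per_day=mu_per_day, params=params,
    )


def _linprog(c, lp: LPProblem, extra_ub=None, extra_b=None):
    A_ub, b_ub = lp.A_ub, lp.b_ub
    if extra_ub is not None:
        A_ub = np.vstack([A_ub, extra_ub])
        b_ub = np.concatenate([b_ub, extra_b])
    return linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=lp.A_eq, b_eq=lp.b_eq,
        bounds=lp.bounds, method="highs",
        options={"presolve": True,
                 "primal_feasibility_tolerance": FEAS_TOL,
                 "dual_feasibility_tolerance": FEAS_TOL},
    )


def solve_at_mu(lp: LPProblem, minimize_total_flux: bool = True) -> FluxSolution:
    """Solve the assembled LP; infeasibility is a status, not an exception.

    After minimising the import cost, a secondary LP minimises total flux
    subject to the optimal objective, suppressing free forward+backward
    cycles so reported fluxes are reproducible.
    """
    res = _linprog(lp.c, lp)
    if res.status != 0:
        return FluxSolution(lp.mu_per_day, {}, {}, float("nan"),
                            "infeasible", res.message)
    obj = float(res.fun)
    x = res.x
    if minimize_total_flux:
        n = lp.n_reactions
        # secondary objective: total flux plus compartment fractions, so
        # both free cycles and slack volume are squeezed out and the
        # reported phi equal their binding lower limits
        c2 = np.ones(len(lp.c))
        cap = np.abs(obj) * OPT_TOL + 1e-12
        res2 = _linprog(c2, lp, extra_ub=lp.c[None, :],
                        extra_b=np.array([obj + cap]))
        if res2.status == 0:
            x = res2.x
    n = lp.n_reactions
    fluxes = {rid: float(x[j]) for j, rid in enumerate(lp.reaction_ids)}
    phi = {comp: float(x[n + k]) for k, comp in enumerate(PHI_COMPARTMENTS)}
    return FluxSolution(lp.mu_per_day, fluxes, phi, obj, "optimal")


def solve(net: Network, params: BiophysicalParams, mu_per_day: float,
          **kw) -> FluxSolution:
    """Assemble and solve in one call."""
    return solve_at_mu(assemble_lp(net, params, mu_per_day), **kw)


def disable_crowding(params: BiophysicalParams) -> BiophysicalParams:
    """Mathematically equivalent to φ_max = ∞: the budget row is dropped."""
    return params.replace(phi_max=float("inf"))


def find_mu_max(net: Network, params: BiophysicalParams,
                tol: float = 0.01, mu_hi: float = 16.0) -> float:
    """Largest feasible proliferation rate (1/day) by bisection.

    The upper bracket is grown by doubling until infeasible (capped), then
    the feasible/infeasible boundary is bisected to ``tol``.
    """
    lo = 0.0
    if not solve(net, params, lo, minimize_total_flux=False).optimal:
        raise ValueError("model infeasible at mu = 0")
    hi = 0.5
    while solve(net, params, hi, minimize_total_flux=False).optimal:
        lo = hi
        hi *= 2.0
        if hi > mu_hi:
            return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if solve(net, params, mid, minimize_total_flux=False).optimal:
            lo = mid
        else:
            hi = mid
    return lo


def sweep_proliferation(net: Network, params: BiophysicalParams,
                        mu_grid, track: list[str] | None = None
                        ) -> pd.DataFrame:
    """Solve across a μ grid; one row per μ with φ's, objective and the
    uptake/excretion fluxes plus any extra tracked reactions (net flux)."""
    track = list(track or [])
    records = []
    for mu in mu_grid:
        sol = solve(net, params, float(mu))
        rec: dict[str, float | str] = {"mu": float(mu), "status": sol.status}
        if sol.optimal:
            rec["objective"] = sol.objective
            for comp, v in sol.phi.items():
                rec[f"phi_{comp}"] = v
            net_f = sol.net_fluxes()
            for rid, r in ((r.id, r) for r in net.reactions):
                if r.rclass == "RI" or r.id.startswith("EX_"):
                    rec[rid] = net_f.get(rid, sol.fluxes.get(rid, 0.0))
            for rid in track:
                rec[rid] = net_f.get(rid, sol.fluxes.get(rid, 0.0))
        records.append(rec)
    return pd.DataFrame.from_records(records)


def flux_balance_residual(sol: FluxSolution, lp: LPProblem) -> float:
    """∞-norm of A_eq x − b over the metabolite-balance rows."""
    x = np.array([sol.fluxes[r] for r in lp.reaction_ids]
                 + [sol.phi[c] for c in PHI_COMPARTMENTS])
    resid = lp.A_eq @ x - lp.b_eq
    mask = [t.startswith("balance:") for t in lp.eq_tags]
    return float(np.max(np.abs(resid[mask]))) if any(mask) else 0.0
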