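"""Pathway accounting: ATP ledgers, flux traceback and overall reactions.

``atp_ledger`` ranks reactions by their gross ATP production in a flux
solution; ``trace_backbone`` walks flux-carrying producer reactions
upstream from a seed reaction (never through currency metabolites);
``compose_overall`` sums elementary reactions with exact rational
multipliers and cancels internal intermediates, reproducing textbook-style
overall reactions such as "glucose + 2 ADP + 2 Pi → 2 lactate + 2 ATP".
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import sympy

from .fba import FluxSolution
from .network import BalanceReport, Network, Reaction, check_reaction_balance

__all__ = [
    "CURRENCY_METABOLITES",
    "AtpLedger",
    "OverallReaction",
    "atp_ledger",
    "trace_backbone",
    "compose_overall",
    "find_multipliers",
    "pathway_yield",
]

#: Cofactor/solvent species a pathway traceback never expands through.
CURRENCY_METABOLITES = frozenset({
    "atp", "adp", "amp", "pi", "ppi", "nad", "nadh", "nadp", "nadph",
    "fad", "fadh2", "h", "h2o", "co2", "o2", "nh4", "coa",
})


def _is_currency(met_id: str, currency: frozenset[str]) -> bool:
    return met_id in currency or met_id.split("_")[0] in currency


@dataclass
class AtpLedger:
    """Gross ATP production per reaction (mM/min), sorted descending."""

    production: dict[str, float]
    maintenance: float  # reference consumption, mM/min

    @property
    def total(self) -> float:
        return sum(self.production.values())

    def top(self, k: int = 5) -> list[tuple[str, float]]:
        return list(self.production.items())[:k]


def atp_ledger(sol: FluxSolution, net: Network,
               atp_ids: Iterable[str] = ("atp",),
               maintenance_id: str = "ATPM",
               flux_floor: float = 1e-9) -> AtpLedger:
    """Rank ATP-producing reactions: positive ATP coefficient × flux."""
    atp_ids = set(atp_ids)
    prod: dict[str, float] = {}
    for r in net.reactions:
        coeff = sum(c for m, c in r.stoichiometry.items()
                    if m in atp_ids and c > 0)
        if coeff <= 0:
            continue
        f = sol.fluxes.get(r.id, 0.0)
        if f > flux_floor:
            prod[r.id] = coeff * f
    prod = dict(sorted(prod.items(), key=lambda kv: -kv[1]))
    maint = sol.fluxes.get(maintenance_id, 0.0)
    return AtpLedger(prod, maint)


def trace_backbone(sol: FluxSolution, net: Network, start_reaction: str,
                   stop_metabolites: Iterable[str] = (),
                   currency: frozenset[str] = CURRENCY_METABOLITES,
                   flux_threshold: float = 1e-6) -> list[tuple[str, float]]:
    """Breadth-first upstream traversal over flux-carrying producers.

    Starting from ``start_reaction``, each substrate that is neither a
    currency metabolite nor in ``stop_metabolites`` is expanded through the
    reactions that produce it above ``flux_threshold``.  Returns the ordered
    (reaction id, flux) list; the start reaction comes first.
    """
    stop = set(stop_metabolites)
    if start_reaction not in net.rxn_index:
        raise ValueError(f"unknown reaction {start_reaction!r}")
    f0 = sol.fluxes.get(start_reaction, 0.0)
    if f0 <= flux_threshold:
        raise ValueError(
            f"start reaction {start_reaction} carries no flux ({f0:g})")

    producers: dict[str, list[str]] = {}
    for r in net.reactions:
        if sol.fluxes.get(r.id, 0.0) > flux_threshold:
            for m, c in r.stoichiometry.items():
                if c > 0:
                    producers.setdefault(m, []).append(r.id)

    visited_rxns: list[tuple[str, float]] = []
    seen_rxns: set[str] = set()
    seen_mets: set[str] = set()
    queue: deque[str] = deque([start_reaction])
    while queue:
        rid = queue.popleft()
        if rid in seen_rxns:
            continue
        seen_rxns.add(rid)
        visited_rxns.append((rid, sol.fluxes[rid]))
        rxn = net.rxn_index[rid]
        for m, c in rxn.stoichiometry.items():
            if c >= 0 or m in seen_mets:
                continue
            seen_mets.add(m)
            if _is_currency(m, currency) or m in stop:
                continue
            for prod_rid in producers.get(m, []):
                if prod_rid not in seen_rxns:
                    queue.append(prod_rid)
    return visited_rxns


@dataclass
class OverallReaction:
    """Integer/rational combination of reactions with intermediates
    cancelled; stoichiometry is exact (Fractions)."""

    components: list[tuple[str, Fraction]]
    net_stoichiometry: dict[str, Fraction]
    balance: BalanceReport | None = None

    def coefficient(self, species: str) -> Fraction:
        return self.net_stoichiometry.get(species, Fraction(0))

    def equation(self) -> str:
        def side(items):
            return " + ".join(
                (f"{abs(c)} {m}" if abs(c) != 1 else m) for m, c in items)
        subs = sorted((m, c) for m, c in self.net_stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.net_stoichiometry.items() if c > 0)
        return f"{side(subs)} -> {side(prods)}"


def compose_overall(reactions: Sequence[Reaction],
                    multipliers: Sequence[int | Fraction],
                    net: Network | None = None) -> OverallReaction:
    """Exact multiplier-weighted sum of reactions; species whose net
    coefficient is zero (the cancelled intermediates) are dropped.  When a
    network is supplied, an elemental/charge balance report of the overall
    reaction is attached."""
    if len(reactions) != len(multipliers):
        raise ValueError("one multiplier per reaction required")
    total: dict[str, Fraction] = {}
    comps = []
    for rxn, mult in zip(reactions, multipliers):
        mult = Fraction(mult)
        comps.append((rxn.id, mult))
        for m, c in rxn.stoichiometry.items():
            total[m] = total.get(m, Fraction(0)) + \
                mult * Fraction(c).limit_denominator(10**6)
    total = {m: c for m, c in total.items() if c != 0}
    report = None
    if net is not None and total:
        pseudo = Reaction(id="overall",
                          stoichiometry={m: float(c) for m, c in total.items()})
        # exact re-check with rational coefficients
        report = check_reaction_balance(pseudo, net.met_index)
        elems: dict[str, Fraction] = {}
        charge = Fraction(0)
        for m, c in total.items():
            met = net.met_index[m]
            charge += c * met.charge
            for el, nn in met.formula.items():
                elems[el] = elems.get(el, Fraction(0)) + c * nn
        report = BalanceReport("overall",
                               {el: v for el, v in elems.items() if v != 0},
                               charge, exempt=False)
    return OverallReaction(comps, total, report)


def find_multipliers(reactions: Sequence[Reaction],
                     intermediates: Iterable[str]) -> list[int]:
    """Integer multipliers cancelling the given intermediates exactly.

    Computes the rational nullspace of the intermediate-species
    stoichiometric submatrix (rows = intermediates, columns = reactions)
    and rescales the unique basis vector to coprime positive integers.
    """
    intermediates = sorted(set(intermediates))
    mat = sympy.Matrix([
        [sympy.Rational(r.stoichiometry.get(m, 0)).limit_denominator(10**6)
         for r in reactions]
        for m in intermediates
    ])
    null = mat.nullspace()
    if len(null) != 1:
        raise ValueError(
            f"intermediate cancellation admits {len(null)} degrees of "
            "freedom; expected exactly one")
    vec = null[0]
    denoms = [sympy.Rational(v).q for v in vec]
    scale = sympy.ilcm(*denoms) if len(denoms) > 1 else denoms[0]
    ints = [int(v * scale) for v in vec]
    g = 0
    for v in ints:
        g = sympy.igcd(g, v)
    ints = [v // g for v in ints]
    if all(v <= 0 for v in ints):
        ints = [-v for v in ints]
    if any(v <= 0 for v in ints):
        raise ValueError("no strictly positive multiplier vector exists")
    return ints


def pathway_yield(overall: OverallReaction, product: str,
                  substrate: str) -> Fraction:
    """Net product per unit substrate consumed (substrate normalised to 1)."""
    sub = overall.coefficient(substrate)
    if sub >= 0:
        raise ValueError(f"{substrate} is not consumed by the overall reaction")
    return overall.coefficient(product) / (-sub)
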