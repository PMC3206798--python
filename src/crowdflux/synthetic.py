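"""Self-contained networks for testing and desk-scale reproduction.

Two constructions are provided:

* :func:`make_toy_network` — a hand-solvable overflow-metabolism model:
  lumped glycolysis (standard or ATP-neutral), lactate fermentation,
  lumped oxidative phosphorylation at 32 mol ATP / mol glucose, an ATP
  maintenance floor and an ATP-consuming proliferation sink.  Crowding
  coefficients make OxPhos volume-expensive and fermentation volume-cheap
  per ATP, so the LP optimum switches from pure respiration to overflow
  (lactate excretion) at an analytically computable proliferation rate.

* :func:`make_core_network` — a curated, synthetic stand-in for a
  genome-scale human reconstruction (which cannot be redistributed here):
  real stoichiometries of glycolysis, serine biosynthesis, the cytosolic
  and mitochondrial one-carbon cycles, the glycine cleavage system,
  glutaminolysis, lumped TCA/electron transport (coupled and uncoupled),
  essential-amino-acid driven protein synthesis and lumped lipid/RNA/DNA
  biomass.  Every non-pseudo reaction is elementally and charge balanced.

Plus :func:`vertex_oracle`, a brute-force LP optimum by basic-feasible-
solution enumeration, and :func:`make_random_network`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .biophysics import BiophysicalParams
from .fba import LPProblem, PER_DAY_TO_PER_MIN
from .network import (
    Metabolite,
    Network,
    PROLIFERATION_ID,
    Reaction,
    add_auxiliary_reactions,
)

__all__ = [
    "base_metabolites", "ToySpec", "make_toy_network", "toy_switch_mu",
    "make_core_network", "assign_uniform_keff", "CORE_MEDIUM",
    "vertex_oracle", "make_random_network",
]

# ------------------------------------------------------------ metabolites

_MET_TABLE = [
    # id, formula, charge, compartment
    ("glc_D", "C6H12O6", 0, "c"),
    ("lac_L", "C3H5O3", -1, "c"),
    ("ala_L", "C3H7NO2", 0, "c"),
    ("gln_L", "C5H10N2O3", 0, "c"),
    ("glu_L", "C5H8NO4", -1, "c"),
    ("akg", "C5H4O5", -2, "c"),
    ("pyr", "C3H3O3", -1, "c"),
    ("pep", "C3H2O6P", -3, "c"),
    ("2pg", "C3H4O7P", -3, "c"),
    ("3pg", "C3H4O7P", -3, "c"),
    ("13dpg", "C3H4O10P2", -4, "c"),
    ("g3p", "C3H5O6P", -2, "c"),
    ("dhap", "C3H5O6P", -2, "c"),
    ("fdp", "C6H10O12P2", -4, "c"),
    ("f6p", "C6H11O9P", -2, "c"),
    ("g6p", "C6H11O9P", -2, "c"),
    ("atp", "C10H12N5O13P3", -4, "c"),
    ("adp", "C10H12N5O10P2", -3, "c"),
    ("pi", "HO4P", -2, "c"),
    ("h", "H", 1, "c"),
    ("h2o", "H2O", 0, "c"),
    ("o2", "O2", 0, "c"),
    ("co2", "CO2", 0, "c"),
    ("nad", "C21H26N7O14P2", -1, "c"),
    ("nadh", "C21H27N7O14P2", -2, "c"),
    ("nadp", "C21H25N7O17P3", -3, "c"),
    ("nadph", "C21H26N7O17P3", -4, "c"),
    ("fad", "C27H31N9O15P2", -2, "m"),
    ("fadh2", "C27H33N9O15P2", -2, "m"),
    ("nh4", "H4N", 1, "c"),
    ("for", "CHO2", -1, "c"),
    ("ser_L", "C3H7NO3", 0, "c"),
    ("gly", "C2H5NO2", 0, "c"),
    ("3php", "C3H2O7P", -3, "c"),
    ("pser_L", "C3H6NO6P", -2, "c"),
    ("thf", "C19H21N7O6", -2, "c"),
    ("mlthf", "C20H21N7O6", -2, "c"),
    ("methf", "C20H20N7O6", -1, "c"),
    ("10fthf", "C20H21N7O7", -2, "c"),
    ("thf_m", "C19H21N7O6", -2, "m"),
    ("mlthf_m", "C20H21N7O6", -2, "m"),
    ("methf_m", "C20H20N7O6", -1, "m"),
    ("10fthf_m", "C20H21N7O7", -2, "m"),
    # essential amino acids
    ("his_L", "C6H9N3O2", 0, "c"),
    ("ile_L", "C6H13NO2", 0, "c"),
    ("leu_L", "C6H13NO2", 0, "c"),
    ("lys_L", "C6H15N2O2", 1, "c"),
    ("met_L", "C5H11NO2S", 0, "c"),
    ("phe_L", "C9H11NO2", 0, "c"),
    ("thr_L", "C4H9NO3", 0, "c"),
    ("trp_L", "C11H12N2O2", 0, "c"),
    ("val_L", "C5H11NO2", 0, "c"),
]


def base_metabolites(ids=None) -> list[Metabolite]:
    """Metabolites with BiGG-convention formulas and charges."""
    table = _MET_TABLE if ids is None else [
        row for row in _MET_TABLE if row[0] in set(ids)]
    return [Metabolite(id=i, formula=f, charge=q, compartment=comp)
            for i, f, q, comp in table]


def _rxn(rid, stoich, *, rev=False, rclass="RnM", keff=None, exempt=False,
         lb=0.0, subsystem="") -> Reaction:
    return Reaction(id=rid, stoichiometry=dict(stoich), reversible=rev,
                    rclass=rclass, keff=keff, exempt=exempt,
                    lower_bound=lb, subsystem=subsystem)


# Balanced reaction stoichiometries shared between the toy and core nets.
GLYC_UPPER = {"glc_D": -1, "nad": -2, "pi": -2, "3pg": 2, "nadh": 2, "h": 4}
GLYC_LOWER_STD = {"3pg": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1, "h2o": 1}
GLYC_LOWER_NZ = {"3pg": -1, "pyr": 1, "pi": 1}
LDH = {"pyr": -1, "nadh": -1, "h": -1, "lac_L": 1, "nad": 1}
# lumped pyruvate respiration: 12.5 ATP/pyruvate (P/O 2.5 + substrate level)
RESP_PYR = {"pyr": -1, "o2": -2.5, "adp": -12.5, "pi": -12.5, "h": -13.5,
            "co2": 3, "atp": 12.5, "h2o": 14.5}
RESP_NADH = {"nadh": -1, "o2": -0.5, "adp": -2.5, "pi": -2.5, "h": -3.5,
             "nad": 1, "atp": 2.5, "h2o": 3.5}


# ------------------------------------------------------------ toy model

@dataclass
class ToySpec:
    include_serine_pathway: bool = False
    glycolysis_variant: str = "standard"
    oxphos_yield: float = 32.0           # mol ATP / mol glucose (lumped)
    keff: float = 600.0                  # 1/min, all toy enzymes
    atp_per_cell: float = 10000.0        # ATP demand per cell-unit (1 mM)
    medium: tuple[str, ...] = ("glc_D", "o2", "pi", "h", "h2o")
    maintenance_flux: float = 6.0        # mM/min

    def __post_init__(self) -> None:
        glyc_yield = 2.0 if self.glycolysis_variant == "standard" else 0.0
        if self.oxphos_yield <= glyc_yield:
            raise ValueError("oxphos_yield must exceed the glycolytic yield")
        if self.keff <= 0 or self.atp_per_cell <= 0:
            raise ValueError("all coefficients must be positive")


def make_toy_network(spec: ToySpec | None = None) -> Network:
    """Overflow-metabolism toy model with a hand-computable switch point.

    Low μ: all ATP from respiration (32/glucose), no lactate.  High μ: the
    crowding budget caps mitochondrial ATP and the overflow goes to
    fermentation with lactate excretion.  See :func:`toy_switch_mu` for the
    closed-form switch location.
    """
    spec = spec or ToySpec()
    ids = {"glc_D", "o2", "pi", "h", "h2o", "atp", "adp", "nad", "nadh",
           "pyr", "lac_L", "co2", "3pg"}
    if spec.include_serine_pathway:
        ids |= {"glu_L", "akg", "3php", "pser_L", "ser_L", "gly", "thf",
                "mlthf", "methf", "10fthf", "for", "nadp", "nadph", "nh4",
                "thf_m", "mlthf_m", "methf_m", "10fthf_m"}
    mets = base_metabolites(ids)
    net = Network(metabolites=mets, reactions=[])
    k = spec.keff
    lower = (GLYC_LOWER_STD if spec.glycolysis_variant == "standard"
             else GLYC_LOWER_NZ)
    net.add_reaction(_rxn("GLYC_UP", GLYC_UPPER, keff=k,
                          subsystem="glycolysis"))
    net.add_reaction(_rxn("GLYC_LOW", lower, keff=k, subsystem="glycolysis"))
    net.add_reaction(_rxn("LDH_L", LDH, keff=k, subsystem="fermentation"))
    net.add_reaction(_rxn("RESP_PYR", RESP_PYR, rclass="RM", keff=k,
                          subsystem="oxphos"))
    net.add_reaction(_rxn("RESP_NADH", RESP_NADH, rclass="RM", keff=k,
                          subsystem="oxphos"))
    if spec.include_serine_pathway:
        for r in _serine_pathway_reactions(k):
            net.add_reaction(r)
    net.glycolysis_variant = spec.glycolysis_variant

    # proliferation: a pure ATP sink (b ATP per cell-unit of 1 mM)
    b = spec.atp_per_cell
    net.add_metabolite(Metabolite("cell", "cell biomass"))
    net.add_reaction(_rxn(
        PROLIFERATION_ID,
        {"atp": -b, "h2o": -b, "adp": b, "pi": b, "h": b, "cell": 1},
        exempt=True, subsystem="biomass"))
    medium = [s for s in spec.medium if s in net.met_index]
    if spec.include_serine_pathway and "glu_L" not in medium:
        medium.append("glu_L")  # nitrogen/amino donor for PSERT
    net = add_auxiliary_reactions(net, medium, biomass=None,
                                  maintenance_flux=spec.maintenance_flux)
    if spec.include_serine_pathway and "EX_akg_out" not in net.rxn_index:
        net.add_reaction(_rxn("EX_akg_out", {"akg": -1}, exempt=True,
                              subsystem="exchange"))
    return net


def toy_switch_mu(spec: ToySpec, params: BiophysicalParams) -> float:
    """Closed-form lactate-overflow threshold μ* of the toy model (1/day).

    Below μ*, the optimum is pure respiration: glucose uptake g = D/32 with
    ATP demand D(μ) = f_maint + b·μ̃.  The crowding budget binds when

        a_G·2g (upper+lower glycolysis) + 30·a_M·g + V0 = φ_max,

    where 30 = mitochondrial ATP per glucose and V0 the constant P0 volume
    term.  Solving for D and inverting D(μ) gives μ*; above it lactate
    excretion is strictly positive.
    """
    a_i = params.v_E / spec.keff
    budget = params.phi_max - params.p0_volume_fraction
    glyc_yield = 2.0 if spec.glycolysis_variant == "standard" else 0.0
    mito_atp_per_glc = spec.oxphos_yield - glyc_yield
    d_star = spec.oxphos_yield * budget / (
        2 * a_i + mito_atp_per_glc * params.a_M_ATP)
    mu_tilde = (d_star - spec.maintenance_flux) / spec.atp_per_cell
    return mu_tilde / PER_DAY_TO_PER_MIN


# ------------------------------------------------- serine/one-carbon set

def _serine_pathway_reactions(k: float | None = None) -> list[Reaction]:
    """Serine biosynthesis, both one-carbon cycles and glycine cleavage,
    with reconstruction-convention stoichiometries (all balanced)."""
    return [
        _rxn("PGCD", {"3pg": -1, "nad": -1, "3php": 1, "nadh": 1, "h": 1},
             keff=k, subsystem="serine"),
        _rxn("PSERT", {"3php": -1, "glu_L": -1, "pser_L": 1, "akg": 1},
             keff=k, subsystem="serine"),
        _rxn("PSP_L", {"pser_L": -1, "h2o": -1, "ser_L": 1, "pi": 1},
             keff=k, subsystem="serine"),
        _rxn("GHMT2r", {"ser_L": -1, "thf": -1, "gly": 1, "mlthf": 1,
                        "h2o": 1}, rev=True, keff=k, subsystem="one-carbon"),
        _rxn("MTHFD", {"mlthf": -1, "nadp": -1, "methf": 1, "nadph": 1},
             rev=True, keff=k, subsystem="one-carbon"),
        _rxn("MTHFC", {"h2o": -1, "methf": -1, "10fthf": 1, "h": 1},
             rev=True, keff=k, subsystem="one-carbon"),
        _rxn("FTHFL", {"atp": -1, "for": -1, "thf": -1, "10fthf": 1,
                       "adp": 1, "pi": 1}, rev=True, keff=k,
             subsystem="one-carbon"),
        # mitochondrial glycine cleavage (lumped lipoyl steps) and cycle
        _rxn("GCSm", {"gly": -1, "thf_m": -1, "nad": -1, "co2": 1,
                      "mlthf_m": 1, "nh4": 1, "nadh": 1}, rev=True,
             rclass="RM", keff=k, subsystem="glycine cleavage"),
        _rxn("MTHFDm", {"mlthf_m": -1, "nadp": -1, "methf_m": 1, "nadph": 1},
             rev=True, rclass="RM", keff=k, subsystem="one-carbon"),
        _rxn("MTHFCm", {"h2o": -1, "methf_m": -1, "10fthf_m": 1, "h": 1},
             rev=True, rclass="RM", keff=k, subsystem="one-carbon"),
        _rxn("FTHFLm", {"atp": -1, "for": -1, "thf_m": -1, "10fthf_m": 1,
                        "adp": 1, "pi": 1}, rev=True, rclass="RM", keff=k,
             subsystem="one-carbon"),
    ]


# ------------------------------------------------------------ core model

CORE_MEDIUM = ("glc_D", "gln_L", "his_L", "ile_L", "leu_L", "lys_L",
               "met_L", "phe_L", "thr_L", "trp_L", "val_L", "o2", "pi",
               "h", "h2o")

#: Amino-acid composition of the median protein (fractions over the
#: modelled residues; unmodelled residues are folded into ala/glu demand).
PROTEIN_AA_FRACTIONS = {
    "ala_L": 0.208, "ser_L": 0.090, "gly": 0.095, "glu_L": 0.152,
    "gln_L": 0.040, "his_L": 0.021, "ile_L": 0.047, "leu_L": 0.086,
    "lys_L": 0.072, "met_L": 0.021, "phe_L": 0.039, "thr_L": 0.058,
    "trp_L": 0.011, "val_L": 0.060,
}

#: Pool concentrations (mM) and lumped synthesis routes of the non-protein
#: biomass components; pseudo-reactions, exempt from elemental balance.
CORE_BIOMASS = {
    "protein": {"aa_fractions": PROTEIN_AA_FRACTIONS, "length": 355,
                "atp_per_residue": 4.3},
    "lipid": {"concentration_mM": 40.0,
              "synthesis": {"glc_D": -4, "atp": -7, "nadph": -14,
                            "adp": 7, "pi": 7, "nadp": 14}},
    "rna": {"concentration_mM": 45.0,
            "synthesis": {"glc_D": -0.5, "gln_L": -0.25, "atp": -2,
                          "adp": 2}},
    "dna": {"concentration_mM": 10.0,
            "synthesis": {"glc_D": -0.5, "gln_L": -0.25, "atp": -2,
                          "adp": 2}},
}


def core_glycolysis_reactions() -> list[Reaction]:
    """The ten glycolytic steps plus lactate dehydrogenase (BiGG ids)."""
    return [
        _rxn("HEX1", {"glc_D": -1, "atp": -1, "g6p": 1, "adp": 1, "h": 1}),
        _rxn("PGI", {"g6p": -1, "f6p": 1}, rev=True),
        _rxn("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1, "h": 1}),
        _rxn("FBA", {"fdp": -1, "dhap": 1, "g3p": 1}, rev=True),
        _rxn("TPI", {"dhap": -1, "g3p": 1}, rev=True),
        _rxn("GAPD", {"g3p": -1, "nad": -1, "pi": -1, "13dpg": 1,
                      "nadh": 1, "h": 1}, rev=True),
        _rxn("PGK", {"13dpg": -1, "adp": -1, "3pg": 1, "atp": 1}, rev=True),
        _rxn("PGM", {"3pg": -1, "2pg": 1}, rev=True),
        _rxn("ENO", {"2pg": -1, "pep": 1, "h2o": 1}, rev=True),
        _rxn("PYK", {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}),
        _rxn("LDH_L", {"pyr": -1, "nadh": -1, "h": -1, "lac_L": 1,
                       "nad": 1}, rev=True),
    ]


def _core_mito_reactions() -> list[Reaction]:
    return [
        # pyruvate dehydrogenase + TCA turn (lumped, incl. succinyl-CoA
        # substrate-level phosphorylation)
        _rxn("PDHTCAm", {"pyr": -1, "nad": -4, "fad": -1, "adp": -1,
                         "pi": -1, "h2o": -2, "co2": 3, "nadh": 4,
                         "fadh2": 1, "atp": 1, "h": 2},
             rclass="RM", subsystem="tca"),
        # respiratory chain coupled to ATP synthase (P/O 2.5 / 1.5)
        _rxn("NADHOXm", {"nadh": -1, "o2": -0.5, "adp": -2.5, "pi": -2.5,
                         "h": -3.5, "nad": 1, "atp": 2.5, "h2o": 3.5},
             rclass="RM", subsystem="oxphos"),
        _rxn("FADH2OXm", {"fadh2": -1, "o2": -0.5, "adp": -1.5, "pi": -1.5,
                          "h": -1.5, "fad": 1, "atp": 1.5, "h2o": 2.5},
             rclass="RM", subsystem="oxphos"),
        # uncoupled electron transport (proton leak): redox disposal
        # without phosphorylation
        _rxn("NADHLEAKm", {"nadh": -1, "o2": -0.5, "h": -1, "nad": 1,
                           "h2o": 1}, rclass="RM", subsystem="oxphos"),
        _rxn("FADH2LEAKm", {"fadh2": -1, "o2": -0.5, "fad": 1, "h2o": 1},
             rclass="RM", subsystem="oxphos"),
        # glutaminolysis and anaplerotic exit to pyruvate (lumped
        # akg -> succinate -> malate -> pyruvate with malic enzyme)
        _rxn("GLUNm", {"gln_L": -1, "h2o": -1, "glu_L": 1, "nh4": 1},
             rclass="RM", subsystem="glutaminolysis"),
        _rxn("GLUDm", {"glu_L": -1, "h2o": -1, "nad": -1, "akg": 1,
                       "nh4": 1, "nadh": 1, "h": 1}, rev=True,
             rclass="RM", subsystem="glutaminolysis"),
        _rxn("AKG2PYRm", {"akg": -1, "nad": -2, "fad": -1, "h2o": -2,
                          "pyr": 1, "co2": 2, "nadh": 2, "fadh2": 1,
                          "h": 1}, rclass="RM", subsystem="tca"),
        # transhydrogenase
        _rxn("NNTm", {"nadh": -1, "nadp": -1, "nad": 1, "nadph": 1},
             rev=True, rclass="RM", subsystem="oxphos"),
    ]


def make_core_network(glycolysis_variant: str = "standard",
                      maintenance_flux: float = 6.0) -> Network:
    """Curated core human-metabolism network (synthetic stand-in for a
    genome-scale reconstruction; ~60 reactions before splitting)."""
    from .network import set_glycolysis_variant

    net = Network(metabolites=base_metabolites(), reactions=[])
    for r in (core_glycolysis_reactions()
              + _serine_pathway_reactions()
              + _core_mito_reactions()):
        net.add_reaction(r)
    net.add_reaction(_rxn("ALATA_L", {"pyr": -1, "glu_L": -1, "ala_L": 1,
                                      "akg": 1}, rev=True,
                          subsystem="alanine"))
    net = add_auxiliary_reactions(net, CORE_MEDIUM, biomass=CORE_BIOMASS,
                                  maintenance_flux=maintenance_flux)
    if glycolysis_variant != "standard":
        net = set_glycolysis_variant(net, glycolysis_variant)
    return net


def assign_uniform_keff(net: Network, keff: float = 600.0) -> Network:
    """Give every enzymatic reaction the same k_eff (deterministic runs)."""
    net = net.copy()
    for r in net.reactions:
        if r.is_enzymatic:
            r.keff = keff
    return net


# ------------------------------------------------------------ LP oracle

@dataclass
class OracleResult:
    status: str
    objective: float | None
    x: np.ndarray | None
    n_bases: int = 0


def vertex_oracle(lp: LPProblem, max_bases: int = 2_000_000,
                  tol: float = 1e-9) -> OracleResult:
    """Brute-force LP optimum by enumerating basic feasible solutions.

    The LP is converted to standard form (shifted variables, slack columns
    for inequalities and finite upper bounds); every basis of the equality
    system is solved and the best feasible vertex returned.  Intended for
    small problems (a dozen structural variables); raises if the basis
    count exceeds ``max_bases``.
    """
    n = len(lp.c)
    lo = np.array([b[0] for b in lp.bounds], dtype=float)
    hi = np.array([b[1] for b in lp.bounds], dtype=float)

    # substitute fixed variables (lo == hi)
    fixed = np.isclose(lo, hi)
    free = ~fixed
    x_fix = np.where(fixed, lo, 0.0)
    c = lp.c[free]
    obj_off = float(lp.c[fixed] @ x_fix[fixed]) if fixed.any() else 0.0

    A_eq = lp.A_eq[:, free]
    b_eq = lp.b_eq - lp.A_eq[:, fixed] @ x_fix[fixed]
    A_ub = lp.A_ub[:, free]
    b_ub = lp.b_ub - lp.A_ub[:, fixed] @ x_fix[fixed]
    lo_f, hi_f = lo[free], hi[free]

    # shift to x' = x - lo >= 0
    b_eq = b_eq - A_eq @ lo_f
    b_ub = b_ub - A_ub @ lo_f
    obj_off += float(c @ lo_f)

    # drop all-zero equality rows (orphan balances)
    keep = np.abs(A_eq).sum(axis=1) > 0
    if np.any(~keep & (np.abs(b_eq) > tol)):
        return OracleResult("infeasible", None, None)
    A_eq, b_eq = A_eq[keep], b_eq[keep]

    n_free = int(free.sum())
    n_ub = A_ub.shape[0]
    ub_cols = np.vstack([np.zeros((A_eq.shape[0], n_ub)), np.eye(n_ub)])
    blocks = np.vstack([A_eq, A_ub])
    rhs = np.concatenate([b_eq, b_ub])
    # finite upper bounds become extra slack rows
    fin = np.isfinite(hi_f)
    n_cap = int(fin.sum())
    cap_rows = np.zeros((n_cap, n_free))
    cap_rows[np.arange(n_cap), np.where(fin)[0]] = 1.0
    A = np.vstack([
        np.hstack([blocks, ub_cols,
                   np.zeros((blocks.shape[0], n_cap))]),
        np.hstack([cap_rows, np.zeros((n_cap, n_ub)), np.eye(n_cap)]),
    ])
    b = np.concatenate([rhs, (hi_f - lo_f)[fin]])
    cost = np.concatenate([c, np.zeros(n_ub + n_cap)])

    m, ntot = A.shape
    n_combos = math.comb(ntot, m)
    if n_combos > max_bases:
        raise ValueError(
            f"{n_combos} bases exceed the oracle budget ({max_bases})")

    best_obj, best_x = None, None
    scale = max(1.0, float(np.max(np.abs(b))))
    for cols in itertools.combinations(range(ntot), m):
        B = A[:, cols]
        try:
            xb = np.linalg.solve(B, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(xb)) or np.min(xb) < -tol * scale:
            continue
        if np.max(np.abs(B @ xb - b)) > 1e-7 * scale:
            continue
        obj = float(cost[list(cols)] @ xb)
        if best_obj is None or obj < best_obj - 0.0:
            x_full = np.zeros(ntot)
            x_full[list(cols)] = xb
            best_obj, best_x = obj, x_full
    if best_obj is None:
        return OracleResult("infeasible", None, None, n_combos)
    x_free = best_x[:n_free] + lo_f
    x_out = x_fix.copy()
    x_out[free] = x_free
    return OracleResult("optimal", best_obj + obj_off, x_out, n_combos)


# ------------------------------------------------------- random networks

def make_random_network(n_mets: int, n_rxns: int, seed: int) -> Network:
    """Connected random chain-like network, one import and one export,
    guaranteed feasible at μ = 0; deterministic per seed."""
    if n_mets < 2:
        raise ValueError("need at least 2 metabolites")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}", compartment="c") for i in range(n_mets)]
    net = Network(metabolites=mets, reactions=[])
    net.add_reaction(_rxn("IMPORT", {"m0": 1}, rclass="RI", exempt=True))
    net.rxn_index["IMPORT"].import_cost = 1.0
    # a spanning chain guarantees connectivity m0 -> ... -> m_{n-1}
    n_chain = n_mets - 1
    if n_rxns < n_chain + 2:
        raise ValueError("n_rxns too small for a connected chain")
    for i in range(n_chain):
        net.add_reaction(_rxn(f"R{i}", {f"m{i}": -1, f"m{i+1}": 1},
                              keff=600.0))
    for j in range(n_chain, n_rxns - 2):
        a, bmet = rng.choice(n_mets, size=2, replace=False)
        coeff = float(rng.integers(1, 3))
        net.add_reaction(_rxn(f"R{j}", {f"m{a}": -1, f"m{bmet}": coeff},
                              keff=float(rng.uniform(60, 6000))))
    net.add_reaction(_rxn("EXPORT", {f"m{n_mets-1}": -1}, exempt=True))
    return net
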