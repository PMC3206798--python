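"""Stoichiometric network data model and I/O.

The network is a plain list of metabolites and reactions.  Reactions are
classified into three crowding classes:

* ``RI``  — nutrient import reactions (the only reactions with an import
  cost, equal to the molecular weight of the imported species in g/mmol);
* ``RnM`` — reactions catalysed outside the mitochondria;
* ``RM``  — reactions with at least one mitochondrial participant,
  including transport across the mitochondrial membrane.

Fluxes are expressed in mM/min throughout (mmol per litre of cell volume
per minute).  Reversible reactions are split into two irreversible copies
before any optimisation, each carrying its own effective turnover number.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_WEIGHTS",
    "parse_formula",
    "formula_weight",
    "Metabolite",
    "Reaction",
    "Network",
    "load_network",
    "load_metabolites",
    "load_sbml",
    "add_auxiliary_reactions",
    "set_glycolysis_variant",
    "split_reversible",
    "check_reaction_balance",
    "BalanceReport",
    "MAINTENANCE_ID",
    "PROTEIN_SYNTH_ID",
    "PROLIFERATION_ID",
    "PROTEIN_SPECIES",
    "CELL_SPECIES",
]

# Conventional ids for the auxiliary machinery; the FBA layer keys on these.
MAINTENANCE_ID = "ATPM"
PROTEIN_SYNTH_ID = "PROTEIN_SYNTH"
PROLIFERATION_ID = "PROLIFERATION"
PROTEIN_SPECIES = "protein"
CELL_SPECIES = "cell"

ATOMIC_WEIGHTS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Cl": 35.45, "Mg": 24.305,
    "Ca": 40.078, "Fe": 55.845, "Zn": 65.38, "Se": 78.971, "Co": 58.933,
    "R": 0.0,  # generic residue in pseudo-formulas
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula like ``C6H12O6`` into an element map."""
    if not formula:
        return {}
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        if not m.group(0):
            break
        el, n = m.group(1), m.group(2)
        if el not in ATOMIC_WEIGHTS:
            raise ValueError(f"unknown element {el!r} in formula {formula!r}")
        out[el] = out.get(el, 0) + (int(n) if n else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


def formula_weight(formula: Mapping[str, int] | str) -> float:
    """Molecular weight in g/mol from an elemental composition."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in formula.items())


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: dict[str, int] = field(default_factory=dict)
    charge: int = 0
    compartment: str = "c"
    molecular_weight: float = 0.0  # g/mol

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.molecular_weight == 0.0 and self.formula:
            self.molecular_weight = formula_weight(self.formula)
        if self.formula and self.molecular_weight > 0:
            fw = formula_weight(self.formula)
            if fw > 0 and abs(fw - self.molecular_weight) / fw > 0.005:
                raise ValueError(
                    f"metabolite {self.id}: molecular weight "
                    f"{self.molecular_weight} inconsistent with formula "
                    f"({fw:.2f} g/mol)"
                )

    @property
    def mw_g_per_mmol(self) -> float:
        return self.molecular_weight / 1000.0


@dataclass
class Reaction:
    """A (possibly reversible) reaction with signed stoichiometry.

    ``stoichiometry`` maps metabolite id -> signed coefficient (negative =
    substrate).  ``keff`` is the effective turnover number in 1/min and is
    absent (None) on auxiliary reactions, which therefore pay no enzyme
    volume and no protein-dilution cost.  ``exempt`` marks pseudo-reactions
    (biomass, maintenance, exchanges) that are excused from elemental
    balance.
    """

    id: str
    stoichiometry: dict[str, float]
    reversible: bool = False
    rclass: str = "RnM"  # one of RI, RnM, RM
    keff: float | None = None  # 1/min
    import_cost: float | None = None  # g/mmol, RI only
    name: str = ""
    exempt: bool = False
    lower_bound: float = 0.0
    upper_bound: float = float("inf")
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.rclass not in ("RI", "RnM", "RM"):
            raise ValueError(f"reaction {self.id}: bad rclass {self.rclass}")

    @property
    def is_enzymatic(self) -> bool:
        """Enzyme-catalysed (pays crowding volume and protein dilution);
        auxiliary/pseudo reactions are exempt."""
        return not self.exempt

    def reversed_copy(self, suffix: str = "_rev") -> "Reaction":
        return replace(
            self,
            id=self.id + suffix,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            lower_bound=0.0,
            upper_bound=float("inf"),
        )

    def equation(self) -> str:
        def side(items):
            return " + ".join(
                (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items
            )

        subs = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        prods = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}"


@dataclass
class Network:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    glycolysis_variant: str = "standard"
    medium: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._index()

    def _index(self) -> None:
        self.met_index = {m.id: m for m in self.metabolites}
        if len(self.met_index) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        self.rxn_index = {r.id: r for r in self.reactions}
        if len(self.rxn_index) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        for r in self.reactions:
            for m in r.stoichiometry:
                if m not in self.met_index:
                    raise ValueError(
                        f"reaction {r.id}: unknown metabolite {m!r}"
                    )

    def copy(self) -> "Network":
        return Network(
            metabolites=[replace(m, formula=dict(m.formula))
                         for m in self.metabolites],
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry))
                       for r in self.reactions],
            glycolysis_variant=self.glycolysis_variant,
            medium=set(self.medium),
        )

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.met_index:
            raise ValueError(f"duplicate metabolite {met.id}")
        self.metabolites.append(met)
        self.met_index[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.rxn_index:
            raise ValueError(f"duplicate reaction {rxn.id}")
        for m in rxn.stoichiometry:
            if m not in self.met_index:
                raise ValueError(f"reaction {rxn.id}: unknown metabolite {m!r}")
        self.reactions.append(rxn)
        self.rxn_index[rxn.id] = rxn

    def reactions_of_class(self, rclass: str) -> list[Reaction]:
        return [r for r in self.reactions if r.rclass == rclass]

    # ------------------------------------------------------------------ I/O

    def to_tsv(self) -> str:
        lines = ["id\tequation\treversible\trclass\tkeff\timport_cost\texempt"
                 "\tlower_bound\tsubsystem"]
        for r in self.reactions:
            lines.append("\t".join([
                r.id, r.equation(), "1" if r.reversible else "0", r.rclass,
                "" if r.keff is None else repr(r.keff),
                "" if r.import_cost is None else repr(r.import_cost),
                "1" if r.exempt else "0", repr(r.lower_bound), r.subsystem,
            ]))
        return "\n".join(lines) + "\n"

    def metabolites_to_tsv(self) -> str:
        lines = ["id\tname\tformula\tcharge\tcompartment\tmw"]
        for m in self.metabolites:
            f = "".join(f"{el}{n if n != 1 else ''}"
                        for el, n in sorted(m.formula.items()))
            lines.append("\t".join([
                m.id, m.name, f, str(m.charge), m.compartment,
                repr(m.molecular_weight),
            ]))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        """Canonical JSON dump (reproducibility manifest input)."""
        return json.dumps({
            "glycolysis_variant": self.glycolysis_variant,
            "medium": sorted(self.medium),
            "metabolites": [
                {"id": m.id, "name": m.name, "formula": m.formula,
                 "charge": m.charge, "compartment": m.compartment,
                 "mw": m.molecular_weight}
                for m in self.metabolites
            ],
            "reactions": [
                {"id": r.id, "stoichiometry": r.stoichiometry,
                 "reversible": r.reversible, "rclass": r.rclass,
                 "keff": r.keff, "import_cost": r.import_cost,
                 "exempt": r.exempt, "lower_bound": r.lower_bound,
                 "subsystem": r.subsystem}
                for r in self.reactions
            ],
        }, indent=1, sort_keys=True)


# ---------------------------------------------------------------- parsing

_ARROWS = ("<=>", "<->", "-->", "->", "=>")


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``a + 2 b -> c`` into a stoichiometry map and reversibility."""
    arrow = None
    for a in _ARROWS:
        if a in eq:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation {eq!r}")
    lhs, rhs = eq.split(arrow, 1)
    reversible = arrow in ("<=>", "<->")
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: int) -> None:
        for term in side.split("+"):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 2:
                coeff, met = float(parts[0]), parts[1]
            elif len(parts) == 1:
                coeff, met = 1.0, parts[0]
            else:
                raise ValueError(f"cannot parse term {term!r} in {eq!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff

    add_side(lhs, -1)
    add_side(rhs, +1)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    return stoich, reversible


def _split_tsv(text: str) -> list[dict[str, str]]:
    lines = [ln for ln in text.splitlines() if ln.strip()
             and not ln.lstrip().startswith("#")]
    header = [h.strip() for h in lines[0].split("\t")]
    rows = []
    for ln in lines[1:]:
        vals = ln.split("\t")
        vals += [""] * (len(header) - len(vals))
        rows.append(dict(zip(header, vals)))
    return rows


def load_metabolites(text: str) -> list[Metabolite]:
    """Parse a metabolite TSV (id, name, formula, charge, compartment, mw)."""
    mets = []
    for i, row in enumerate(_split_tsv(text), start=2):
        try:
            mets.append(Metabolite(
                id=row["id"].strip(),
                name=row.get("name", "").strip(),
                formula=parse_formula(row.get("formula", "").strip()),
                charge=int(row["charge"]) if row.get("charge", "").strip() else 0,
                compartment=row.get("compartment", "c").strip() or "c",
                molecular_weight=float(row["mw"]) if row.get("mw", "").strip() else 0.0,
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(f"metabolite table row {i}: {exc}") from exc
    return mets


def classify_reaction(stoich: Mapping[str, float],
                      met_index: Mapping[str, Metabolite],
                      is_import: bool = False) -> str:
    """RI for imports; RM if any participant is mitochondrial; else RnM."""
    if is_import:
        return "RI"
    for m in stoich:
        if met_index[m].compartment == "m":
            return "RM"
    return "RnM"


def load_network(reaction_table: str, metabolite_table: str | None = None,
                 metabolites: Iterable[Metabolite] | None = None) -> Network:
    """Load a network from the TSV reaction dialect.

    Columns: ``id``, ``equation`` (or explicit per-metabolite stoichiometry
    JSON in a ``stoichiometry`` column), ``reversible``, and optionally
    ``rclass``/``compartment``, ``keff``, ``import_cost``, ``exempt``,
    ``lower_bound``, ``subsystem``.  Parse errors name the offending row.
    """
    if metabolite_table is not None:
        mets = load_metabolites(metabolite_table)
    elif metabolites is not None:
        mets = list(metabolites)
    else:
        raise ValueError("a metabolite table is required")
    met_index = {m.id: m for m in mets}

    reactions: list[Reaction] = []
    for i, row in enumerate(_split_tsv(reaction_table), start=2):
        rid = row.get("id", "").strip()
        try:
            if row.get("stoichiometry", "").strip():
                stoich = {k: float(v) for k, v
                          in json.loads(row["stoichiometry"]).items()}
                reversible_eq = None
            else:
                stoich, reversible_eq = parse_equation(row["equation"])
            for m in stoich:
                if m not in met_index:
                    raise ValueError(f"unknown metabolite {m!r}")
            rev_field = row.get("reversible", "").strip()
            if rev_field:
                reversible = rev_field in ("1", "true", "True", "yes")
            elif reversible_eq is not None:
                reversible = reversible_eq
            else:
                raise ValueError("missing reversibility")
            rclass = row.get("rclass", "").strip() or row.get(
                "compartment", "").strip()
            if rclass not in ("RI", "RnM", "RM"):
                # fall back to the compartment-suffix rule
                is_import = rclass.lower() in ("import", "ri") or all(
                    c > 0 for c in stoich.values())
                rclass = classify_reaction(stoich, met_index, is_import)
            keff = float(row["keff"]) if row.get("keff", "").strip() else None
            cost = (float(row["import_cost"])
                    if row.get("import_cost", "").strip() else None)
            if rclass == "RI" and cost is None:
                imported = [m for m, c in stoich.items() if c > 0]
                if len(imported) != 1:
                    raise ValueError(
                        "RI reaction must import exactly one species")
                cost = met_index[imported[0]].mw_g_per_mmol
            reactions.append(Reaction(
                id=rid, stoichiometry=stoich, reversible=reversible,
                rclass=rclass, keff=keff, import_cost=cost,
                exempt=row.get("exempt", "").strip() in ("1", "true", "True"),
                lower_bound=(float(row["lower_bound"])
                             if row.get("lower_bound", "").strip() else 0.0),
                subsystem=row.get("subsystem", "").strip(),
            ))
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"reaction table row {i} ({rid or '?'}): {exc}") from exc
    return Network(metabolites=mets, reactions=reactions)


def load_sbml(path: str) -> Network:
    """Load an SBML model via cobra and convert to a :class:`Network`."""
    import cobra.io  # lazy; optional dependency

    model = cobra.io.read_sbml_model(path)
    mets = [
        Metabolite(
            id=m.id, name=m.name or "",
            formula=parse_formula(m.formula or ""),
            charge=int(m.charge or 0), compartment=m.compartment or "c",
        )
        for m in model.metabolites
    ]
    met_index = {m.id: m for m in mets}
    rxns = []
    for r in model.reactions:
        stoich = {m.id: c for m, c in r.metabolites.items()}
        is_import = r.boundary and all(c > 0 for c in stoich.values())
        rxns.append(Reaction(
            id=r.id, stoichiometry=stoich,
            reversible=r.lower_bound < 0,
            rclass=classify_reaction(stoich, met_index, is_import),
            subsystem=r.subsystem or "",
            exempt=r.boundary,
        ))
    return Network(metabolites=mets, reactions=rxns)


# ------------------------------------------------- auxiliary reactions

#: Byproducts given an excretion valve when present in the network.
DEFAULT_EXCRETIONS = ("lac_L", "ala_L", "nh4", "co2", "for", "gly", "h",
                      "h2o", "pi", "urea", CELL_SPECIES)


def add_auxiliary_reactions(
    net: Network,
    medium: Iterable[str],
    biomass: Mapping | None = None,
    maintenance_flux: float = 6.0,
) -> Network:
    """Attach uptake, excretion, maintenance and biomass machinery.

    ``medium`` lists importable species; one RI reaction per species is
    created with import cost equal to the species molecular weight (g/mmol).
    ``biomass`` describes the macromolecule pools::

        {"protein": {"aa_fractions": {aa_id: fraction}, "length": 355,
                     "atp_per_residue": 4.3},
         "lipid":   {"concentration_mM": 40.0, "synthesis": {stoich}},
         ...}

    Pools other than protein get a synthesis pseudo-reaction and are consumed
    by a proliferation reaction (pool coefficients = pool concentrations in
    mM) producing the ``cell`` species.  Protein demand is *not* part of the
    proliferation reaction: it is carried by the growth-dilution terms of the
    protein balance row in the LP (see :mod:`crowdflux.fba`).
    """
    net = net.copy()
    medium = list(medium)
    missing = [s for s in medium if s not in net.met_index]
    if missing:
        raise ValueError(f"medium species absent from network: {missing}")

    for sp in medium:
        net.add_reaction(Reaction(
            id=f"EX_{sp}_in", stoichiometry={sp: 1.0}, reversible=False,
            rclass="RI", import_cost=net.met_index[sp].mw_g_per_mmol,
            exempt=True, subsystem="exchange",
        ))
    net.medium = set(medium)

    for sp in DEFAULT_EXCRETIONS:
        if sp in net.met_index and f"EX_{sp}_out" not in net.rxn_index:
            net.add_reaction(Reaction(
                id=f"EX_{sp}_out", stoichiometry={sp: -1.0},
                reversible=False, rclass="RnM", exempt=True,
                subsystem="exchange",
            ))

    if all(s in net.met_index for s in ("atp", "adp", "pi", "h", "h2o")):
        net.add_reaction(Reaction(
            id=MAINTENANCE_ID,
            stoichiometry={"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1},
            reversible=False, rclass="RnM", exempt=True,
            lower_bound=maintenance_flux, subsystem="maintenance",
        ))

    biomass = dict(biomass or {})
    pools: dict[str, float] = {}
    protein_spec = biomass.pop("protein", None)
    if protein_spec is not None:
        if PROTEIN_SPECIES not in net.met_index:
            net.add_metabolite(Metabolite(PROTEIN_SPECIES, "protein pool"))
        length = protein_spec.get("length", 355)
        atp_per_res = protein_spec.get("atp_per_residue", 4.3)
        stoich: dict[str, float] = {PROTEIN_SPECIES: 1.0}
        for aa, frac in protein_spec["aa_fractions"].items():
            if aa not in net.met_index:
                raise ValueError(f"protein composition species {aa!r} "
                                 "absent from network")
            stoich[aa] = stoich.get(aa, 0.0) - frac * length
        n_atp = atp_per_res * length
        for sp, c in (("atp", -n_atp), ("h2o", -n_atp), ("adp", n_atp),
                      ("pi", n_atp), ("h", n_atp)):
            stoich[sp] = stoich.get(sp, 0.0) + c
        net.add_reaction(Reaction(
            id=PROTEIN_SYNTH_ID, stoichiometry=stoich, reversible=False,
            rclass="RnM", exempt=True, subsystem="biomass",
        ))

    for pool, spec in biomass.items():
        if pool not in net.met_index:
            net.add_metabolite(Metabolite(pool, f"{pool} pool"))
        pools[pool] = float(spec["concentration_mM"])
        stoich = {pool: 1.0}
        for sp, c in spec.get("synthesis", {}).items():
            stoich[sp] = stoich.get(sp, 0.0) + c
        net.add_reaction(Reaction(
            id=f"{pool.upper()}_SYNTH", stoichiometry=stoich,
            reversible=False, rclass="RnM", exempt=True, subsystem="biomass",
        ))

    if pools:
        if CELL_SPECIES not in net.met_index:
            net.add_metabolite(Metabolite(CELL_SPECIES, "cell biomass"))
        prolif = {pool: -conc for pool, conc in pools.items()}
        prolif[CELL_SPECIES] = 1.0
        net.add_reaction(Reaction(
            id=PROLIFERATION_ID, stoichiometry=prolif, reversible=False,
            rclass="RnM", exempt=True, subsystem="biomass",
        ))
        if f"EX_{CELL_SPECIES}_out" not in net.rxn_index:
            net.add_reaction(Reaction(
                id=f"EX_{CELL_SPECIES}_out",
                stoichiometry={CELL_SPECIES: -1.0}, reversible=False,
                rclass="RnM", exempt=True, subsystem="exchange",
            ))
    return net


# ------------------------------------------------- glycolysis variant

#: Stoichiometries of the pyruvate-kinase step in the two variants.  The
#: ATP-independent variant releases inorganic phosphate instead of
#: phosphorylating ADP; written with water so the step is elementally and
#: charge balanced.
PK_STANDARD = {"pep": -1, "adp": -1, "h": -1, "pyr": 1, "atp": 1}
PK_NET_ZERO = {"pep": -1, "h2o": -1, "pyr": 1, "pi": 1}


def find_pyruvate_kinase(net: Network) -> Reaction:
    for rid in ("PYK", "PK"):
        if rid in net.rxn_index:
            return net.rxn_index[rid]
    for r in net.reactions:
        s = r.stoichiometry
        if s.get("pep", 0) < 0 and s.get("pyr", 0) > 0 and len(s) <= 5:
            return r
    raise ValueError("pyruvate kinase reaction not found")


def set_glycolysis_variant(net: Network, variant: str) -> Network:
    """Swap the pyruvate-kinase step between the standard (ATP-coupled) and
    net-zero (ATP-independent dephosphorylation) forms, preserving its id."""
    if variant not in ("standard", "net_zero"):
        raise ValueError(f"unknown glycolysis variant {variant!r}")
    net = net.copy()
    pk = find_pyruvate_kinase(net)
    target = PK_STANDARD if variant == "standard" else PK_NET_ZERO
    pk.stoichiometry = dict(target)
    net.glycolysis_variant = variant
    return net


# ------------------------------------------------- reversible splitting

def split_reversible(net: Network, suffix: str = "_rev") -> Network:
    """Replace every reversible reaction by forward/backward irreversible
    copies.  Each direction gets its own (still unassigned) keff slot."""
    net = net.copy()
    out: list[Reaction] = []
    for r in net.reactions:
        if r.reversible:
            fwd = replace(r, reversible=False, lower_bound=max(0.0, r.lower_bound),
                          stoichiometry=dict(r.stoichiometry))
            out.append(fwd)
            out.append(r.reversed_copy(suffix))
        else:
            out.append(r)
    return Network(metabolites=net.metabolites, reactions=out,
                   glycolysis_variant=net.glycolysis_variant,
                   medium=set(net.medium))


# ------------------------------------------------- balance checking

@dataclass
class BalanceReport:
    reaction_id: str
    element_imbalance: dict[str, Fraction]
    charge_imbalance: Fraction
    exempt: bool

    @property
    def balanced(self) -> bool:
        if self.exempt:
            return True
        return (all(v == 0 for v in self.element_imbalance.values())
                and self.charge_imbalance == 0)


def check_reaction_balance(rxn: Reaction,
                           mets: Mapping[str, Metabolite]) -> BalanceReport:
    """Per-element and charge imbalance of a reaction (exact rationals).

    Pseudo/auxiliary reactions are flagged exempt rather than judged."""
    if rxn.exempt:
        return BalanceReport(rxn.id, {}, Fraction(0), exempt=True)
    elems: dict[str, Fraction] = {}
    charge = Fraction(0)
    for mid, coeff in rxn.stoichiometry.items():
        met = mets[mid]
        c = Fraction(coeff).limit_denominator(10**6)
        charge += c * met.charge
        for el, n in met.formula.items():
            elems[el] = elems.get(el, Fraction(0)) + c * n
    elems = {el: v for el, v in elems.items() if v != 0}
    return BalanceReport(rxn.id, elems, charge, exempt=False)
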