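"""Network model, I/O round trips, auxiliary machinery and balance checks."""

import pytest

from crowdflux.network import (
    Metabolite, Network, Reaction, add_auxiliary_reactions,
    check_reaction_balance, load_network, parse_equation, parse_formula,
    set_glycolysis_variant, split_reversible, formula_weight,
)
from crowdflux.synthetic import base_metabolites


TOY_TSV = """id\tequation\treversible\trclass
GLYC\tglc_D + 2 adp + 2 pi + 2 nad -> 2 pyr + 2 atp + 2 h2o + 2 nadh + 2 h\t0\tRnM
LDH\tpyr + nadh + h <=> lac_L + nad\t1\t
PGI\tg6p <=> f6p\t1\tRnM
HEX\tglc_D + atp -> g6p + adp + h\t0\tRnM
PYRT\tpyr -> pyr_m\t0\t
PDH\tpyr_m + nad -> nadh + co2\t0\t
"""

MET_TSV = """id\tname\tformula\tcharge\tcompartment
glc_D\tglucose\tC6H12O6\t0\tc
pyr\tpyruvate\tC3H3O3\t-1\tc
pyr_m\tpyruvate\tC3H3O3\t-1\tm
lac_L\tlactate\tC3H5O3\t-1\tc
g6p\t\tC6H11O9P\t-2\tc
f6p\t\tC6H11O9P\t-2\tc
atp\t\tC10H12N5O13P3\t-4\tc
adp\t\tC10H12N5O10P2\t-3\tc
pi\t\tHO4P\t-2\tc
nad\t\tC21H26N7O14P2\t-1\tc
nadh\t\tC21H27N7O14P2\t-2\tc
h\t\tH\t1\tc
h2o\t\tH2O\t0\tc
co2\t\tCO2\t0\tc
"""


class TestParsing:
    def test_formula_round_trip(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert abs(formula_weight("C6H12O6") - 180.156) < 1e-9

    def test_equation_parser(self):
        stoich, rev = parse_equation("a + 2 b -> 3 c")
        assert stoich == {"a": -1.0, "b": -2.0, "c": 3.0} and not rev
        _, rev = parse_equation("a <=> b")
        assert rev

    def test_load_classifies_and_counts(self):
        net = load_network(TOY_TSV, MET_TSV)
        assert len(net.reactions) == 6
        assert not net.reactions_of_class("RI")
        # mitochondrial participant (suffix _m compartment) -> RM
        assert net.rxn_index["PDH"].rclass == "RM"
        assert net.rxn_index["PYRT"].rclass == "RM"  # membrane transport
        assert net.rxn_index["LDH"].rclass == "RnM"

    def test_unknown_metabolite_is_hard_error_naming_row(self):
        bad = TOY_TSV + "BAD\tunobtainium -> pyr\t0\t\n"
        with pytest.raises(ValueError, match="BAD"):
            load_network(bad, MET_TSV)

    def test_missing_reversibility_is_hard_error(self):
        # explicit stoichiometry carries no arrow, so the flag is mandatory
        table = ('id\tstoichiometry\treversible\n'
                 'X\t{"glc_D": -1, "pyr": 2}\t\n')
        with pytest.raises(ValueError, match="reversib"):
            load_network(table, MET_TSV)

    def test_tsv_round_trip_is_lossless(self):
        net = load_network(TOY_TSV, MET_TSV)
        again = load_network(net.to_tsv(), net.metabolites_to_tsv())
        for r in net.reactions:
            r2 = again.rxn_index[r.id]
            assert r2.stoichiometry == r.stoichiometry
            assert r2.reversible == r.reversible
            assert r2.rclass == r.rclass


class TestAuxiliary:
    def _net(self):
        return load_network(TOY_TSV, MET_TSV)

    def test_one_import_per_medium_species_with_mw_cost(self):
        net = add_auxiliary_reactions(self._net(), ["glc_D"])
        ri = net.reactions_of_class("RI")
        assert len(ri) == 1
        assert ri[0].import_cost == pytest.approx(0.180156, rel=1e-4)

    def test_import_count_equals_medium_size(self):
        net = add_auxiliary_reactions(self._net(), ["glc_D", "pyr", "h2o"])
        assert len(net.reactions_of_class("RI")) == 3

    def test_empty_medium_adds_only_valves_and_maintenance(self):
        net = add_auxiliary_reactions(self._net(), [])
        assert not net.reactions_of_class("RI")
        new = set(net.rxn_index) - set(self._net().rxn_index)
        assert all(rid.startswith("EX_") or rid == "ATPM" for rid in new)
        assert net.rxn_index["ATPM"].lower_bound == pytest.approx(6.0)

    def test_missing_medium_species_error_lists_them(self):
        with pytest.raises(ValueError, match="glucose_of_theseus"):
            add_auxiliary_reactions(self._net(), ["glucose_of_theseus"])


class TestGlycolysisVariant:
    def test_net_zero_removes_adenine_nucleotides(self, core_net_standard):
        net = set_glycolysis_variant(core_net_standard, "net_zero")
        pk = net.rxn_index["PYK"]
        assert pk.stoichiometry.get("atp", 0) == 0
        assert pk.stoichiometry.get("adp", 0) == 0
        assert pk.stoichiometry["pi"] == 1
        assert pk.stoichiometry["pep"] == -1

    def test_changes_exactly_one_reaction(self, core_net_standard):
        net = set_glycolysis_variant(core_net_standard, "net_zero")
        changed = [r.id for r in core_net_standard.reactions
                   if net.rxn_index[r.id].stoichiometry != r.stoichiometry]
        assert changed == ["PYK"]

    def test_round_trip_idempotent(self, core_net_standard):
        once = set_glycolysis_variant(core_net_standard, "net_zero")
        back = set_glycolysis_variant(once, "standard")
        again = set_glycolysis_variant(back, "net_zero")
        assert (again.rxn_index["PYK"].stoichiometry
                == once.rxn_index["PYK"].stoichiometry)
        assert (back.rxn_index["PYK"].stoichiometry
                == core_net_standard.rxn_index["PYK"].stoichiometry)

    def test_missing_pk_is_error(self):
        net = load_network(TOY_TSV, MET_TSV)  # lumped: no PEP step
        with pytest.raises(ValueError, match="pyruvate kinase"):
            set_glycolysis_variant(net, "net_zero")


class TestSplitReversible:
    def test_counts_and_negation(self):
        net = load_network(TOY_TSV, MET_TSV)
        n_rev = sum(r.reversible for r in net.reactions)
        split = split_reversible(net)
        assert len(split.reactions) == len(net.reactions) + n_rev
        assert not any(r.reversible for r in split.reactions)
        fwd, rev = split.rxn_index["LDH"], split.rxn_index["LDH_rev"]
        assert rev.stoichiometry == {m: -c for m, c
                                     in fwd.stoichiometry.items()}

    def test_irreversible_untouched(self):
        net = load_network(TOY_TSV, MET_TSV)
        split = split_reversible(net)
        assert (split.rxn_index["GLYC"].stoichiometry
                == net.rxn_index["GLYC"].stoichiometry)


class TestBalance:
    def test_net_zero_pk_is_balanced(self):
        mets = {m.id: m for m in base_metabolites()}
        rxn = Reaction(id="PYK_nz", stoichiometry={"pep": -1, "h2o": -1,
                                                   "pyr": 1, "pi": 1})
        rep = check_reaction_balance(rxn, mets)
        assert rep.balanced and not rep.element_imbalance

    def test_corrupted_coefficient_shows_carbon_imbalance(self):
        mets = {m.id: m for m in base_metabolites()}
        rxn = Reaction(id="bad", stoichiometry={"pep": -1, "h2o": -1,
                                                "pyr": 2, "pi": 1})
        rep = check_reaction_balance(rxn, mets)
        assert rep.element_imbalance.get("C") == 3

    def test_pseudo_reactions_are_exempt(self, toy_net):
        rep = check_reaction_balance(toy_net.rxn_index["PROLIFERATION"],
                                     toy_net.met_index)
        assert rep.exempt and rep.balanced

    @pytest.mark.parametrize("fixture", ["toy_net", "core_net_net_zero",
                                         "core_net_standard"])
    def test_every_non_exempt_reaction_balances(self, fixture, request):
        net = request.getfixturevalue(fixture)
        for r in net.reactions:
            rep = check_reaction_balance(r, net.met_index)
            assert rep.balanced, (r.id, rep.element_imbalance,
                                  rep.charge_imbalance)


def test_mw_formula_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        Metabolite("glc", formula="C6H12O6", molecular_weight=150.0)
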