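"""ATP ledgers, flux traceback and exact overall-reaction composition."""

from fractions import Fraction

import pytest

from crowdflux.fba import FluxSolution, solve
from crowdflux.network import Network, Reaction
from crowdflux.pathways import (atp_ledger, compose_overall,
                                find_multipliers, pathway_yield,
                                trace_backbone)
from crowdflux.pipeline import (glycolysis_composition,
                                novel_pathway_composition)
from crowdflux.synthetic import base_metabolites


def _sol(fluxes, mu=1.0):
    return FluxSolution(mu, fluxes, {}, 0.0, "optimal")


class TestLedger:
    def _net(self):
        mets = base_metabolites({"atp", "adp", "pi", "h", "h2o", "glc_D"})
        net = Network(metabolites=mets, reactions=[])
        net.add_reaction(Reaction("ATPS", {"adp": -1, "pi": -1, "h": -1,
                                           "atp": 1, "h2o": 1},
                                  rclass="RM", exempt=True))
        net.add_reaction(Reaction("ATPM", {"atp": -1, "h2o": -1, "adp": 1,
                                           "pi": 1, "h": 1}, exempt=True))
        return net

    def test_single_producer(self):
        led = atp_ledger(_sol({"ATPS": 10.0, "ATPM": 4.0}), self._net())
        assert led.production == {"ATPS": 10.0}
        assert led.maintenance == 4.0
        assert led.total == 10.0

    def test_zero_flux_gives_empty_ledger(self):
        led = atp_ledger(_sol({"ATPS": 0.0}), self._net())
        assert led.production == {}

    def test_ledger_total_matches_lp_production_half(self, core_lp_net_zero,
                                                     params):
        sol = solve(core_lp_net_zero, params, 2.0)
        led = atp_ledger(sol, core_lp_net_zero)
        expected = sum(
            c * sol.fluxes[r.id]
            for r in core_lp_net_zero.reactions
            for m, c in r.stoichiometry.items()
            if m == "atp" and c > 0 and sol.fluxes[r.id] > 1e-9)
        assert led.total == pytest.approx(expected, rel=1e-12)
        assert led.total >= led.maintenance - 1e-9


class TestTraceback:
    def test_linear_chain_returns_exactly_its_reactions(self):
        mets = base_metabolites({"glc_D", "g6p", "f6p", "fdp"})
        net = Network(metabolites=mets, reactions=[])
        net.add_reaction(Reaction("A", {"glc_D": -1, "g6p": 1}))
        net.add_reaction(Reaction("B", {"g6p": -1, "f6p": 1}))
        net.add_reaction(Reaction("C", {"f6p": -1, "fdp": 1}))
        out = trace_backbone(_sol({"A": 1.0, "B": 1.0, "C": 1.0}), net, "C",
                             stop_metabolites=["glc_D"])
        assert [rid for rid, _ in out] == ["C", "B", "A"]

    def test_zero_flux_start_is_an_error(self):
        mets = base_metabolites({"glc_D", "g6p"})
        net = Network(metabolites=mets, reactions=[])
        net.add_reaction(Reaction("A", {"glc_D": -1, "g6p": 1}))
        with pytest.raises(ValueError, match="no flux"):
            trace_backbone(_sol({"A": 0.0}), net, "A")

    def test_cytosolic_fthfl_traces_to_serine_synthesis(self,
                                                        core_lp_net_zero,
                                                        params):
        sol = solve(core_lp_net_zero, params, 2.79)
        out = dict(trace_backbone(sol, core_lp_net_zero, "FTHFL_rev",
                                  stop_metabolites=["3pg"]))
        assert {"MTHFC", "MTHFD", "GHMT2r", "PSP_L", "PSERT",
                "PGCD"} <= set(out)
        assert "PGK" not in out  # stopped at 3-phosphoglycerate

    def test_mito_fthfl_traces_through_glycine_cleavage(self,
                                                        core_lp_net_zero,
                                                        params):
        sol = solve(core_lp_net_zero, params, 2.79)
        out = dict(trace_backbone(sol, core_lp_net_zero, "FTHFLm_rev",
                                  stop_metabolites=["3pg"]))
        assert {"MTHFCm", "MTHFDm", "GCSm", "GHMT2r"} <= set(out)

    def test_never_expands_through_currency_metabolites(self,
                                                        core_lp_net_zero,
                                                        params):
        sol = solve(core_lp_net_zero, params, 2.79)
        out = dict(trace_backbone(sol, core_lp_net_zero, "FTHFL_rev",
                                  stop_metabolites=["3pg"]))
        # ATP/NADH producers unrelated to the backbone must not be dragged in
        assert "NADHOXm" not in out
        assert "ATPM" not in out
        assert "EX_o2_in" not in out


class TestCompose:
    def test_empty_set_is_null_reaction(self):
        overall = compose_overall([], [])
        assert overall.net_stoichiometry == {}

    def test_exact_cancellation_of_intermediates(self, core_net_standard):
        rxns = [core_net_standard.rxn_index[i] for i in ("PGM", "ENO")]
        overall = compose_overall(rxns, [1, 1], core_net_standard)
        assert overall.coefficient("2pg") == 0
        assert overall.coefficient("3pg") == Fraction(-1)
        assert overall.coefficient("pep") == Fraction(1)
        assert overall.balance.balanced

    def test_glycolysis_table(self, core_net_standard):
        overall = glycolysis_composition(core_net_standard)
        c = overall.coefficient
        assert c("glc_D") == -1
        assert c("atp") == 2 and c("adp") == -2 and c("pi") == -2
        assert c("lac_L") == 2 and c("h2o") == 2
        assert overall.balance.balanced

    def test_novel_pathway_table(self, core_net_standard):
        overall = novel_pathway_composition(core_net_standard)
        c = overall.coefficient
        assert c("glc_D") == -1
        assert c("atp") == 4
        assert c("nh4") == 2 and c("akg") == 2 and c("co2") == 2
        assert c("nadh") == 6 and c("nad") == -6
        assert c("nadph") == 4 and c("nadp") == -4
        assert c("glu_L") == -2
        assert overall.balance.balanced
        # proton/water/formate bookkeeping, reported not asserted upstream:
        # exact composition carries 4 formate, 10 H+ out, 4 H2O in
        assert c("for") == 4

    def test_multiplier_uniqueness_guard(self, core_net_standard):
        rxns = [core_net_standard.rxn_index[i] for i in ("PGM", "ENO")]
        with pytest.raises(ValueError, match="degrees of freedom"):
            find_multipliers(rxns, [])  # nothing to cancel -> 2 dof


class TestYield:
    def test_glycolysis_yield_2(self, core_net_standard):
        overall = glycolysis_composition(core_net_standard)
        assert pathway_yield(overall, "atp", "glc_D") == 2

    def test_novel_pathway_yield_4(self, core_net_standard):
        overall = novel_pathway_composition(core_net_standard)
        assert pathway_yield(overall, "atp", "glc_D") == 4

    def test_serine_to_glycine_cycle_yields_1_atp_per_serine(
            self, core_net_standard):
        net = core_net_standard
        ids = ["GHMT2r", "MTHFD", "MTHFC"]
        rxns = [net.rxn_index[i] for i in ids]
        rxns.append(net.rxn_index["FTHFL"].reversed_copy())
        mults = find_multipliers(rxns, ["thf", "mlthf", "methf", "10fthf"])
        overall = compose_overall(rxns, mults, net)
        assert pathway_yield(overall, "atp", "ser_L") == 1
        assert pathway_yield(overall, "gly", "ser_L") == 1

    def test_serine_through_glycine_cleavage_yields_2_atp(
            self, core_net_standard):
        net = core_net_standard
        rxns = [net.rxn_index[i] for i in
                ("GHMT2r", "MTHFD", "MTHFC", "GCSm", "MTHFDm", "MTHFCm")]
        rxns.append(net.rxn_index["FTHFL"].reversed_copy())
        rxns.append(net.rxn_index["FTHFLm"].reversed_copy())
        mults = find_multipliers(rxns, ["thf", "mlthf", "methf", "10fthf",
                                        "gly", "thf_m", "mlthf_m",
                                        "methf_m", "10fthf_m"])
        overall = compose_overall(rxns, mults, net)
        assert pathway_yield(overall, "atp", "ser_L") == 2
        assert pathway_yield(overall, "nh4", "ser_L") == 1

    def test_substrate_must_be_consumed(self, core_net_standard):
        overall = glycolysis_composition(core_net_standard)
        with pytest.raises(ValueError):
            pathway_yield(overall, "glc_D", "atp")
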