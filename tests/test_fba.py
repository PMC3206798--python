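"""Crowding LP assembly, solving, closed forms and optimality properties."""

import numpy as np
import pytest

from crowdflux.biophysics import default_params
from crowdflux.fba import (
    PER_DAY_TO_PER_MIN, assemble_lp, disable_crowding, find_mu_max,
    flux_balance_residual, protein_synthesis_demand, solve, solve_at_mu,
    sweep_proliferation,
)
from crowdflux.synthetic import (ToySpec, make_random_network,
                                 make_toy_network, toy_switch_mu,
                                 vertex_oracle)


class TestProteinSynthesisDemand:
    def test_worked_example(self, params):
        # mu chosen so that mu + k_D = 0.001/min exactly
        mu_day = (0.001 - params.k_D) / PER_DAY_TO_PER_MIN
        got = protein_synthesis_demand({"X": 10.0}, phi_R=0.01,
                                       mu_per_day=mu_day, params=params,
                                       keff={"X": 600.0})
        expected = 0.001 * (3.59 + 2.4 * 10 / 600 + (82 / 2.4) * 0.01)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.003972, abs=5e-7)

    def test_zero_fluxes_reduce_to_p0_dilution(self, params):
        mu_day = 1.0
        got = protein_synthesis_demand({}, 0.0, mu_day, params)
        mu = mu_day * PER_DAY_TO_PER_MIN
        assert got == pytest.approx((mu + params.k_D) * params.P0)

    def test_no_growth_no_turnover_means_no_demand(self, params):
        p = params.replace(k_D=1e-300)
        got = protein_synthesis_demand({"X": 50.0}, 0.3, 0.0, p,
                                       keff={"X": 600.0})
        assert got == pytest.approx(0.0, abs=1e-290)


class TestAssembly:
    def test_requires_split_network(self, core_net_net_zero, params):
        with pytest.raises(ValueError, match="reversible"):
            assemble_lp(core_net_net_zero, params, 0.0)

    def test_missing_keff_names_reaction(self, toy_net, params):
        net = toy_net.copy()
        net.rxn_index["LDH_L"].keff = None
        with pytest.raises(ValueError, match="LDH_L"):
            assemble_lp(net, params, 0.0)

    def test_every_row_is_tagged(self, toy_net, params):
        lp = assemble_lp(toy_net, params, 0.5)
        assert len(lp.eq_tags) == lp.A_eq.shape[0]
        assert len(lp.ub_tags) == lp.A_ub.shape[0]
        assert all(t for t in lp.eq_tags + lp.ub_tags)

    def test_objective_zero_outside_imports(self, toy_net, params):
        lp = assemble_lp(toy_net, params, 0.5)
        for j, rid in enumerate(lp.reaction_ids):
            if lp.c[j] != 0:
                assert toy_net.rxn_index[rid].rclass == "RI"


class TestSolve:
    def test_mu_zero_imports_only_maintenance_needs(self, toy_spec, toy_net,
                                                    params):
        sol = solve(toy_net, params, 0.0)
        assert sol.optimal
        # cheapest route: all maintenance ATP from respiration (32/glucose)
        glc = sol.fluxes["EX_glc_D_in"]
        assert glc == pytest.approx(toy_spec.maintenance_flux / 32,
                                    rel=1e-6)
        assert sol.fluxes["EX_lac_L_out"] == pytest.approx(0.0, abs=1e-9)

    def test_flux_balance_residual_is_tiny(self, toy_net, params):
        lp = assemble_lp(toy_net, params, 1.0)
        sol = solve_at_mu(lp)
        fmax = max(abs(v) for v in sol.fluxes.values())
        assert flux_balance_residual(sol, lp) <= 1e-8 * max(1.0, fmax)

    def test_infeasible_mu_is_a_status_not_an_exception(self, toy_net,
                                                        params):
        sol = solve(toy_net, params, 1e5)
        assert sol.status == "infeasible"

    def test_objective_nondecreasing_in_mu(self, toy_net, params):
        objs = [solve(toy_net, params, mu).objective
                for mu in (0.0, 0.5, 1.0, 1.5, 2.0)]
        assert all(b >= a - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_relaxation_never_costs_more(self, toy_net, params):
        for mu in (0.03, 1.0, 2.0):
            crowded = solve(toy_net, params, mu).objective
            relaxed = solve(toy_net, disable_crowding(params), mu).objective
            assert relaxed <= crowded + 1e-12

    def test_oracle_equivalence_on_seeded_lps(self, params):
        for seed in range(12):
            net = make_random_network(4, 6, seed)
            net.rxn_index["EXPORT"].lower_bound = 1.0
            lp = assemble_lp(net, params, 0.0)
            sol = solve_at_mu(lp, minimize_total_flux=False)
            oracle = vertex_oracle(lp)
            assert sol.status == oracle.status == "optimal"
            assert sol.objective == pytest.approx(oracle.objective,
                                                  rel=1e-9, abs=1e-12)

    def test_oracle_matches_infeasible_verdict(self, params):
        net = make_random_network(4, 6, 0)
        net.rxn_index["EXPORT"].lower_bound = 1.0
        net.rxn_index["IMPORT"].upper_bound = 0.0  # starve the chain
        lp = assemble_lp(net, params, 0.0)
        assert solve_at_mu(lp).status == "infeasible"
        assert vertex_oracle(lp).status == "infeasible"


class TestCrowdingSwitch:
    def test_lactate_overflow_brackets_analytic_threshold(self, toy_spec,
                                                          toy_net, params):
        mu_star = toy_switch_mu(toy_spec, params)
        below = solve(toy_net, params, 0.97 * mu_star)
        above = solve(toy_net, params, 1.03 * mu_star)
        assert below.fluxes["EX_lac_L_out"] == pytest.approx(0.0, abs=1e-8)
        assert above.fluxes["EX_lac_L_out"] > 1e-3

    def test_no_crowding_means_no_switch(self, toy_spec, toy_net, params):
        mu_star = toy_switch_mu(toy_spec, params)
        relaxed = disable_crowding(params)
        for mu in (1.1 * mu_star, 3 * mu_star):
            sol = solve(toy_net, relaxed, mu)
            assert sol.fluxes["EX_lac_L_out"] == pytest.approx(0.0, abs=1e-8)

    def test_mito_atp_grows_monotonically_without_crowding(self, toy_net,
                                                           params):
        relaxed = disable_crowding(params)
        mito = []
        for mu in (0.5, 1.5, 3.0, 5.0):
            sol = solve(toy_net, relaxed, mu)
            mito.append(12.5 * sol.fluxes["RESP_PYR"]
                        + 2.5 * sol.fluxes["RESP_NADH"])
        assert all(b >= a - 1e-9 for a, b in zip(mito, mito[1:]))

    def test_switch_shifts_with_parameters(self, toy_spec, params):
        base = toy_switch_mu(toy_spec, params)
        assert toy_switch_mu(toy_spec, params.replace(a_M_ATP=0.03)) < base
        assert toy_switch_mu(toy_spec, params.replace(phi_max=0.5)) > base


class TestMuMax:
    def test_toy_capacity_recovered_within_tolerance(self, params):
        # exhaust fermentation too: only respiration allowed, so mu_max is
        # exactly where pure-OxPhos demand fills the budget (the toy switch
        # threshold with lactate disabled)
        spec = ToySpec()
        net = make_toy_network(spec)
        net.rxn_index["LDH_L"].upper_bound = 0.0
        expected = toy_switch_mu(spec, params)
        got = find_mu_max(net, params, tol=0.005)
        assert got == pytest.approx(expected, abs=0.01)

    def test_mu_max_nondecreasing_in_phi_max(self, params):
        spec = ToySpec()
        net = make_toy_network(spec)
        net.rxn_index["LDH_L"].upper_bound = 0.0
        lo = find_mu_max(net, params, tol=0.02)
        hi = find_mu_max(net, params.replace(phi_max=0.8), tol=0.02)
        assert hi >= lo - 0.02


class TestSweep:
    def test_sweep_reports_phi_and_exchanges(self, toy_net, params):
        df = sweep_proliferation(toy_net, params, [0.1, 1.0, 2.0])
        assert list(df["mu"]) == [0.1, 1.0, 2.0]
        assert (df["status"] == "optimal").all()
        assert {"phi_M", "phi_R", "EX_glc_D_in", "EX_lac_L_out"} <= set(
            df.columns)
        assert df["phi_M"].is_monotonic_increasing

    def test_phi_r_nondecreasing_on_core(self, core_lp_net_zero, params):
        df = sweep_proliferation(core_lp_net_zero, params,
                                 [0.03, 0.8, 1.6, 2.4])
        assert (df["status"] == "optimal").all()
        phi_r = df["phi_R"].to_numpy()
        assert np.all(np.diff(phi_r) >= -1e-9)
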