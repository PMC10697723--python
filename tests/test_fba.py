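"""Constraint-based modeling: network invariants, LP correctness, ensembles."""
import numpy as np
import pandas as pd
import pytest

from vesselflux import (
    DEFAULT_OMITTED_AMINO_ACIDS,
    ExchangeRate,
    build_constraints,
    compare_flux_conditions,
    ensemble_fba,
    load_network,
    solve_fba,
    toy_core_network,
)
from vesselflux.exceptions import ConstraintError, NetworkError
from vesselflux.network import (
    AMINO_ACIDS,
    MetabolicNetwork,
    Reaction,
    network_from_dict,
    network_to_dict,
    read_sbml,
    save_network_json,
    write_sbml,
)
from vesselflux.synthetic import condition_culture_parameters, condition_exchange_rates

from lp_oracle import brute_force_max, random_bounded_network


@pytest.fixture(scope="module")
def net():
    return toy_core_network()


def condition_constraints(net, condition):
    culture = condition_culture_parameters(condition)
    return build_constraints(
        condition_exchange_rates(condition), net, rates_in_model_units=True,
        growth_rate=culture["growth_rate"][0],
        growth_rate_sd=culture["growth_rate"][1],
        o2_rate=culture["o2"][0], o2_rate_sd=culture["o2"][1],
    )


class TestNetworkStructure:
    def test_packaged_asset_loads_and_validates(self):
        net = load_network()
        report = net.validate()
        assert set(report) == {"HA_synthesis", "ATP_demand", "growth", "O2_exchange"}

    def test_every_exchange_has_one_nonzero_entry(self, net):
        for rxn in net.exchange_reactions():
            assert len([c for c in rxn.stoich.values() if c != 0]) == 1

    def test_all_20_amino_acids_exchangeable(self, net):
        assert set(AMINO_ACIDS) <= set(net.exchange_map)
        assert len(AMINO_ACIDS) == 20

    def test_default_bounds_admit_positive_ha_flux(self, net):
        sol = solve_fba(net)
        assert sol.status == "optimal"
        assert sol.objective_value > 0
        assert sol.fluxes["HAS"] > 0

    def test_reversed_bounds_rejected(self):
        with pytest.raises(NetworkError):
            Reaction("bad", {"x": -1.0}, lb=1.0, ub=-1.0)

    def test_missing_tagged_reaction_named_in_error(self, net):
        data = network_to_dict(net)
        for rxn in data["reactions"]:
            if rxn["id"] == "ATPM":
                rxn["tags"] = []
        broken = network_from_dict(data)
        with pytest.raises(NetworkError, match="ATP_demand"):
            broken.validate()

    def test_json_roundtrip_preserves_stoichiometry(self, net, tmp_path):
        path = tmp_path / "net.json"
        save_network_json(net, path)
        back = load_network(path)
        np.testing.assert_array_equal(
            back.stoichiometry_matrix(), net.stoichiometry_matrix()
        )

    def test_sbml_roundtrip_preserves_stoichiometry(self, net, tmp_path):
        path = tmp_path / "net.xml"
        write_sbml(net, path)
        back = read_sbml(path)
        assert back.reaction_ids == net.reaction_ids
        for original, restored in zip(net.reactions, back.reactions):
            assert dict(restored.stoich) == dict(original.stoich)
            assert restored.lb == original.lb
            assert restored.ub == original.ub


class TestBuildConstraints:
    def test_default_omit_list_is_the_canonical_eight(self):
        assert set(DEFAULT_OMITTED_AMINO_ACIDS) == {
            "glycine", "leucine", "lysine", "phenylalanine",
            "threonine", "tryptophan", "tyrosine", "valine",
        }

    def test_twelve_amino_acids_constrained_when_all_20_measured(self, net):
        rates = {aa: ExchangeRate(aa, -0.02, 0.003) for aa in AMINO_ACIDS}
        cs = build_constraints(rates, net, rates_in_model_units=True)
        constrained_aas = {
            rid for rid in cs.exchange_bounds
            if rid.removeprefix("EX_") in AMINO_ACIDS
        }
        assert len(constrained_aas) == 12
        for aa in DEFAULT_OMITTED_AMINO_ACIDS:
            assert net.exchange_map[aa] not in cs.exchange_bounds

    def test_zero_rate_zero_sd_pins_exchange(self, net):
        cs = build_constraints(
            {"glutamate": ExchangeRate("glutamate", 0.0, 0.0)},
            net, rates_in_model_units=True,
        )
        assert cs.exchange_bounds["EX_glutamate"] == (0.0, 0.0)

    def test_unknown_metabolite_raises_listing_it(self, net):
        rates = {"unobtainium": ExchangeRate("unobtainium", 1.0, 0.1)}
        with pytest.raises(ConstraintError, match="unobtainium"):
            build_constraints(rates, net, rates_in_model_units=True)

    def test_fmol_rates_converted_to_model_units(self, net):
        # -150 fmol/cell/h at 300 pg dry mass per cell -> -0.5 mmol/gDW/h
        cs = build_constraints(
            {"glucose": ExchangeRate("glucose", -150.0, 0.0)}, net
        )
        lo, hi = cs.exchange_bounds["EX_glucose"]
        assert lo == pytest.approx(-0.5)
        assert hi == pytest.approx(-0.5)


class TestSolveFba:
    def test_hand_solvable_three_reaction_chain(self):
        chain = MetabolicNetwork(
            metabolites=["a", "b"],
            reactions=[
                Reaction("EX_a", {"a": -1.0}, -2.0, 0.0, ("exchange",)),
                Reaction("CONV", {"a": -1.0, "b": 1.0}, 0.0, 10.0),
                Reaction("EX_b", {"b": -1.0}, 0.0, 10.0, ("exchange",)),
            ],
            objective={"EX_b": 1.0},
        )
        sol = solve_fba(chain)
        assert sol.objective_value == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(np.abs(sol.fluxes), 2.0, atol=1e-9)

    def test_matches_vertex_enumeration_on_random_networks(self):
        """LP optimum equals exhaustive vertex enumeration (10 random small
        systems here; the full 50-network sweep runs in the acceptance suite)."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 10:
            S, lb, ub, c = random_bounded_network(rng)
            oracle = brute_force_max(S, lb, ub, c)
            mets = [f"m{i}" for i in range(S.shape[0])]
            rxns = [
                Reaction(f"r{j}", {mets[i]: S[i, j] for i in range(S.shape[0])
                                   if S[i, j] != 0.0}, lb[j], ub[j])
                for j in range(S.shape[1])
            ]
            net = MetabolicNetwork(mets, rxns, {f"r{j}": c[j] for j in range(len(c))})
            sol = solve_fba(net, parsimonious=False)
            if oracle is None:
                assert sol.status != "optimal"
            else:
                assert sol.status == "optimal"
                assert sol.objective_value == pytest.approx(oracle, abs=1e-9)
            checked += 1

    def test_optimal_solutions_satisfy_mass_balance_and_bounds(self, net):
        S = net.stoichiometry_matrix()
        for cond in ("ctrl_cm", "huvec_cm"):
            cs = condition_constraints(net, cond)
            sol = solve_fba(net, cs)
            assert sol.status == "optimal"
            v = sol.fluxes.to_numpy()
            assert np.max(np.abs(S @ v)) <= 1e-8
            lb, ub = cs.apply(net)
            assert np.all(v >= lb - 1e-9)
            assert np.all(v <= ub + 1e-9)

    def test_no_glucose_means_no_hyaluronic_acid(self, net):
        """HA needs glucose-derived UDP-sugars; pinning glucose exchange to
        zero zeroes the objective."""
        cs = build_constraints(
            {"glucose": ExchangeRate("glucose", 0.0, 0.0)},
            net, rates_in_model_units=True,
        )
        sol = solve_fba(net, cs)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_constraints_report_status_without_fluxes(self, net):
        # forced lactate secretion with every carbon source shut off
        rates = {"glucose": ExchangeRate("glucose", 0.0, 0.0),
                 "lactate": ExchangeRate("lactate", 5.0, 0.0)}
        rates.update({aa: ExchangeRate(aa, 0.0, 0.0) for aa in AMINO_ACIDS})
        cs = build_constraints(rates, net, omit=(), rates_in_model_units=True)
        sol = solve_fba(net, cs)
        assert sol.status == "infeasible"
        assert sol.fluxes is None

    def test_relaxing_an_upper_bound_never_decreases_optimum(self, net):
        """Objective monotonicity over exchange relaxations."""
        base = solve_fba(net).objective_value
        data = network_to_dict(net)
        for rxn_id in ("EX_glucose", "EX_glutamine", "EX_o2", "EX_lactate"):
            relaxed = network_to_dict(net)
            for rxn in relaxed["reactions"]:
                if rxn["id"] == rxn_id:
                    rxn["ub"] = rxn["ub"] + 5.0
            sol = solve_fba(network_from_dict(relaxed))
            assert sol.objective_value >= base - 1e-9

    def test_agrees_with_cobrapy_on_packaged_network(self, net):
        """Independent cross-check: the same LP solved through cobrapy's
        solver stack returns the same optimum."""
        cobra = pytest.importorskip("cobra")
        from vesselflux.network import _to_cobra

        model = _to_cobra(net)
        cobra_obj = model.optimize().objective_value
        ours = solve_fba(net).objective_value
        assert ours == pytest.approx(cobra_obj, abs=1e-6)


class TestEnsemble:
    def test_zero_sd_ensemble_repeats_single_solve(self, net):
        rates = {
            "glucose": ExchangeRate("glucose", -0.4, 0.0),
            "glutamine": ExchangeRate("glutamine", -0.2, 0.0),
        }
        cs = build_constraints(rates, net, rates_in_model_units=True)
        single = solve_fba(net, cs)
        ens = ensemble_fba(net, cs, n=5, seed=0)
        assert ens.infeasible_count == 0
        for _, row in ens.fluxes.iterrows():
            np.testing.assert_allclose(
                row.to_numpy(), single.fluxes.to_numpy(), atol=1e-9
            )

    def test_fixed_seed_is_bit_identical(self, net):
        cs = condition_constraints(net, "huvec_cm")
        e1 = ensemble_fba(net, cs, n=20, seed=7)
        e2 = ensemble_fba(net, cs, n=20, seed=7)
        assert e1.fluxes.equals(e2.fluxes)
        assert e1.infeasible_count == e2.infeasible_count

    def test_ensemble_mean_objective_consistent_with_mean_constraints(self, net):
        """With 5% relative SDs the ensemble-mean objective stays within
        2 SEM of the solve at the mean constraints."""
        rates = {
            met: ExchangeRate(met, r.rate, abs(r.rate) * 0.05)
            for met, r in condition_exchange_rates("ctrl_cm").items()
        }
        cs = build_constraints(rates, net, rates_in_model_units=True)
        center = solve_fba(net, cs).objective_value
        ens = ensemble_fba(net, cs, n=100, seed=3)
        values = ens.fluxes["HAS"].to_numpy()
        sem = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - center) <= 2 * sem + 1e-12

    def test_mostly_infeasible_ensemble_warns(self, net, caplog):
        rates = {"glucose": ExchangeRate("glucose", 0.0, 0.001),
                 "lactate": ExchangeRate("lactate", 5.0, 0.001)}
        rates.update({aa: ExchangeRate(aa, 0.0, 0.0) for aa in AMINO_ACIDS})
        cs = build_constraints(rates, net, omit=(), rates_in_model_units=True)
        with caplog.at_level("WARNING"):
            ens = ensemble_fba(net, cs, n=6, seed=0)
        assert ens.infeasible_count == 6
        assert any("infeasible" in r.message for r in caplog.records)


class TestCompareConditions:
    def test_identical_ensembles_have_zero_differences(self, net):
        cs = condition_constraints(net, "ctrl_cm")
        e = ensemble_fba(net, cs, n=10, seed=1, condition="x")
        e2 = ensemble_fba(net, cs, n=10, seed=1, condition="y")
        table = compare_flux_conditions(e, e2, net)
        np.testing.assert_allclose(table["difference"], 0.0, atol=1e-12)

    def test_single_reaction_subset_gives_one_row(self, net):
        cs = condition_constraints(net, "ctrl_cm")
        e = ensemble_fba(net, cs, n=4, seed=1, condition="a")
        e2 = ensemble_fba(net, cs, n=4, seed=2, condition="b")
        table = compare_flux_conditions(e, e2, net, reactions=["HAS"])
        assert list(table.index) == ["HAS"]

    def test_mismatched_networks_rejected(self, net):
        cs = condition_constraints(net, "ctrl_cm")
        e = ensemble_fba(net, cs, n=2, seed=1)
        other = MetabolicNetwork(
            metabolites=["a"],
            reactions=[Reaction("EX_a", {"a": -1.0}, -1, 1, ("exchange",)),
                       Reaction("SINK", {"a": -1.0}, 0, 1)],
            objective={"SINK": 1.0},
        )
        e_other = ensemble_fba(
            other,
            build_constraints({}, other, rates_in_model_units=True),
            n=2, seed=1,
        )
        with pytest.raises(NetworkError):
            compare_flux_conditions(e, e_other, net)

    def test_cm_condition_raises_ha_and_atp_demand(self, net):
        """Conditioned-medium-style constraints (more glucose uptake, more
        lactate secretion, more O2 consumption, glutamate uptake) raise both
        the HA-synthesis and ATP-demand ensemble means."""
        e_cm = ensemble_fba(net, condition_constraints(net, "huvec_cm"),
                            n=60, seed=5, condition="huvec_cm")
        e_ctrl = ensemble_fba(net, condition_constraints(net, "ctrl_cm"),
                              n=60, seed=6, condition="ctrl_cm")
        table = compare_flux_conditions(e_cm, e_ctrl, net)
        assert table.loc["HAS", "difference"] > 0
        assert table.loc["ATPM", "difference"] > 0
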