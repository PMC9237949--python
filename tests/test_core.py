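"""Core framework: flux primitives, composition, ODE assembly, simulation,
conservation bookkeeping and config round-trips."""

import io

import numpy as np
import pytest

from nksignal.core import (
    CompositionError,
    ModelError,
    Parameter,
    PortMapping,
    RateLaw,
    Reaction,
    SimulationSpec,
    Species,
    SubModel,
    TimeSeries,
    assemble_odes,
    compose,
    conserved_totals,
    hill_flux,
    mass_action_flux,
    simulate,
    submodel_from_dict,
    submodel_to_dict,
)
from nksignal.fcepsilonri import build_fcepsilonri, FCParameterSet, FCInitialConditions


# ---------------------------------------------------------------- fluxes

class TestMassActionFlux:
    def test_unit_concentrations_return_rate_constant(self):
        # Lyn rephosphorylation J3 = k3 [Pi][Lyn] at 1 µM each
        r = Reaction("R3", {"Lyn": 1, "Pi": 1}, {"pLyn": 1},
                     constants={"k": "k_f3"})
        flux = mass_action_flux(r, {"Lyn": 1.0, "Pi": 1.0, "pLyn": 0.0},
                                {"k": 1.0887})
        assert flux == pytest.approx(1.0887)

    def test_reversible_equilibrium_net_zero(self):
        r = Reaction("R", {"A": 1, "B": 1}, {"AB": 1},
                     law=RateLaw.MASS_ACTION_REVERSIBLE,
                     constants={"kf": "kf", "kr": "kr"})
        # kf[A][B] == kr[AB]  ->  net 0
        flux = mass_action_flux(r, {"A": 2.0, "B": 3.0, "AB": 1.5},
                                {"kf": 1.0, "kr": 4.0})
        assert flux == pytest.approx(0.0, abs=1e-15)

    def test_zero_reactant_zero_flux(self):
        r = Reaction("R", {"A": 1, "B": 1}, {"C": 1}, constants={"k": "k"})
        assert mass_action_flux(r, {"A": 0.0, "B": 5.0, "C": 0.0}, {"k": 7.0}) == 0.0

    def test_negative_concentration_rejected(self):
        r = Reaction("R", {"A": 1}, {"B": 1}, constants={"k": "k"})
        with pytest.raises(ModelError, match="negative"):
            mass_action_flux(r, {"A": -0.1, "B": 0.0}, {"k": 1.0})

    def test_missing_species_rejected(self):
        r = Reaction("R", {"A": 1}, {"B": 1}, constants={"k": "k"})
        with pytest.raises(ModelError, match="missing"):
            mass_action_flux(r, {"A": 1.0}, {"k": 1.0})


class TestHillFlux:
    def test_half_maximum_at_kp(self):
        assert hill_flux(0.3, VMP=2.0, Kp=0.3, np_=4.0) == pytest.approx(1.0)

    def test_zero_substrate(self):
        assert hill_flux(0.0, 2.0, 0.3, 2.0) == 0.0

    def test_saturates_monotonically(self):
        vals = [hill_flux(c, 1.0, 0.5, 2.0) for c in (0.5, 1, 5, 50, 500)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.0, rel=1e-4)

    def test_nonpositive_kp_rejected(self):
        with pytest.raises(ModelError):
            hill_flux(1.0, 1.0, 0.0, 2.0)


# ---------------------------------------------------------------- helpers

def two_pool(name="m", k=0.5, a0=2.0):
    return SubModel(
        name=name,
        species=[Species("A", initial_concentration=a0), Species("B")],
        parameters=[Parameter("k", k)],
        reactions=[Reaction("r", {"A": 1}, {"B": 1}, constants={"k": "k"})],
        ports=["A", "B", "k"],
    )


# ---------------------------------------------------------------- compose

class TestCompose:
    def test_disjoint_union(self):
        comp = compose([two_pool("x"), two_pool("y")])
        assert len(comp.species) == 4
        assert len(comp.reactions) == 2  # flattening preserves reaction count
        assert set(comp.parameters) == {"x/k", "y/k"}

    def test_identity_merge_shares_one_state(self):
        comp = compose([two_pool("x", a0=2.0), two_pool("y", a0=0.0)],
                       [PortMapping(("x", "B"), ("y", "A"))])
        assert len(comp.species) == 3
        assert comp.canonical("y/A") == "x/B"
        # the shared pool feeds y's reaction: mass flows x/A -> x/B -> y/B
        ts = simulate(comp, SimulationSpec(t_end=40.0, n_points=51))
        assert ts["y/B"][-1] > 1.5

    def test_dangling_port_rejected(self):
        with pytest.raises(CompositionError, match="port"):
            compose([two_pool("x"), two_pool("y")],
                    [PortMapping(("x", "nope"), ("y", "A"))])

    def test_species_parameter_identity_mismatch_rejected(self):
        with pytest.raises(CompositionError, match="units"):
            compose([two_pool("x"), two_pool("y")],
                    [PortMapping(("x", "k"), ("y", "A"))])

    def test_double_identity_target_rejected(self):
        with pytest.raises(CompositionError, match="two identity"):
            compose([two_pool("x"), two_pool("y"), two_pool("z")],
                    [PortMapping(("x", "B"), ("z", "A")),
                     PortMapping(("y", "B"), ("z", "A"))])

    def test_composition_neutrality(self):
        """A sub-model simulates identically standalone and inside a
        composite with an unrelated neighbour."""
        # solver tolerances well below the 1e-9 comparison level: the two
        # runs take different step sequences, so each must be individually
        # accurate to better than the agreement we assert
        spec = SimulationSpec(t_end=10.0, n_points=101,
                              rel_tol=1e-12, abs_tol=1e-14)
        alone = simulate(two_pool("x"), spec)
        together = simulate(compose([two_pool("x"), two_pool("other", k=3.0)]),
                            spec)
        for col in ("x/A", "x/B"):
            np.testing.assert_allclose(together[col], alone[col],
                                       rtol=1e-9, atol=1e-11)


# ---------------------------------------------------------------- odes

class TestAssembleOdes:
    def test_hand_stoichiometry_pgrb2(self):
        """d[pGrb2]/dt equals the R7 flux k_f7·[pSyk·Grb2] (its only
        producing reaction, no consumer)."""
        model = compose([build_fcepsilonri()])
        system = assemble_odes(model)
        y = np.linspace(0.1, 1.2, len(system.y0))
        i = system.index["FCepsilonRI/pGrb2"]
        j = system.index["FCepsilonRI/pSyk_Grb2"]
        k_f7 = model.parameter_value("FCepsilonRI/k_f7")
        assert system.rhs(0.0, y)[i] == pytest.approx(k_f7 * y[j], rel=1e-12)

    def test_clamped_species_never_moves(self):
        model = compose([build_fcepsilonri()])
        system = assemble_odes(model)
        i = system.index["FCepsilonRI/Pi"]
        rng = np.random.default_rng(3)
        for _ in range(5):
            assert system.rhs(0.0, rng.uniform(0, 2, len(system.y0)))[i] == 0.0

    def test_all_rates_zero_gives_zero_derivative(self):
        params = FCParameterSet(**{k: 0.0 for k in
                                   ("k_f1", "k_f2", "k_f3", "k_f4", "k_f5",
                                    "k_f6", "k_f7", "k_r1", "k_r4", "k_r6")})
        system = assemble_odes(compose([build_fcepsilonri(params)]))
        y = np.full(len(system.y0), 0.7)
        np.testing.assert_array_equal(system.rhs(0.0, y), 0.0)

    def test_fast_path_matches_independent_hand_coded_derivative(self):
        """Brute-force oracle: the full cascade derivative written out by
        hand, term by term, agrees with the assembled system at 100 random
        states to 1e-12 relative."""
        model = compose([build_fcepsilonri()])
        system = assemble_odes(model)
        p = {k: model.parameter_value(f"FCepsilonRI/{k}") for k in
             ("k_f1", "k_f2", "k_f3", "k_f4", "k_f5", "k_f6", "k_f7",
              "k_r1", "k_r4", "k_r6")}
        names = [n.split("/")[1] for n in system.species_names]

        def hand(yv):
            s = dict(zip(names, yv))
            J1 = p["k_f1"] * s["FC"] * s["pLyn"] - p["k_r1"] * s["FC_pLyn"]
            J2 = p["k_f2"] * s["FC_pLyn"]
            J3 = p["k_f3"] * s["Lyn"] * s["Pi"]
            J4 = p["k_f4"] * s["pFC"] * s["Syk"] - p["k_r4"] * s["pFC_Syk"]
            J5 = p["k_f5"] * s["pFC_Syk"]
            J6 = p["k_f6"] * s["pSyk"] * s["Grb2"] - p["k_r6"] * s["pSyk_Grb2"]
            J7 = p["k_f7"] * s["pSyk_Grb2"]
            d = {
                "FC": -J1, "pLyn": -J1 + J3, "FC_pLyn": J1 - J2,
                "pFC": J2 - J4 + J5, "Lyn": J2 - J3,
                "Syk": -J4, "pFC_Syk": J4 - J5, "pSyk": J5 - J6 + J7,
                "Grb2": -J6, "pSyk_Grb2": J6 - J7, "pGrb2": J7, "Pi": 0.0,
            }
            return np.array([d[n] for n in names])

        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.uniform(0.0, 5.0, len(system.y0))
            got, want = system.rhs(0.0, y), hand(y)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)


# ---------------------------------------------------------------- simulate

class TestSimulate:
    def test_zero_rates_constant_trajectory(self):
        sm = two_pool(k=0.0)
        ts = simulate(sm, SimulationSpec(t_end=50.0, n_points=11))
        np.testing.assert_allclose(ts["m/A"], 2.0, rtol=1e-12)
        np.testing.assert_allclose(ts["m/B"], 0.0, atol=1e-12)

    def test_tolerance_convergence(self):
        """Halving rel_tol moves the final state by less than 10·rel_tol."""
        sm = build_fcepsilonri()
        rel = 1e-6
        final = []
        for rt in (rel, rel / 2):
            ts = simulate(sm, SimulationSpec(t_end=3600.0, n_points=2,
                                             rel_tol=rt, abs_tol=1e-12))
            final.append(ts.values[-1])
        # relative to a 1e-6 µM resolution floor: pools that have decayed
        # to the solver noise level carry no converged digits to compare
        scale = np.maximum(np.abs(final[1]), 1e-6)
        assert np.max(np.abs(final[0] - final[1]) / scale) < 10 * rel

    def test_negative_drive_is_reported_not_hidden(self):
        """A pathological constant sink drives the state negative: the
        output keeps the negative values (never silently clipped) and the
        run is flagged."""
        from nksignal.core import register_rate

        register_rate("const_sink", species=[], params=["rate"])(
            lambda rate: -rate)
        sm = SubModel("sink", [Species("X", initial_concentration=0.1)],
                      [Parameter("rate", 0.01)],
                      [Reaction("r", {}, {"X": 1}, law=RateLaw.CUSTOM,
                                rate_fn="const_sink")])
        ts = simulate(sm, SimulationSpec(t_end=100.0, n_points=21,
                                         rel_tol=1e-8, abs_tol=1e-10))
        assert ts["sink/X"][-1] < -0.5
        assert ts.metadata["clip_triggered"]


# ----------------------------------------------------- conserved_totals

class TestConservedTotals:
    def test_zero_rate_simulation_has_zero_drift(self):
        ts = simulate(two_pool(k=0.0), SimulationSpec(t_end=10.0, n_points=5))
        drift = conserved_totals(ts, {"all": ["m/A", "m/B"]})
        assert drift["all"] == 0.0

    def test_produced_only_group_reports_nonzero_drift(self):
        ts = simulate(two_pool(), SimulationSpec(t_end=10.0, n_points=5))
        drift = conserved_totals(ts, {"b_alone": ["m/B"]})
        assert drift["b_alone"] > 0.1  # not conserved, reported, no error

    def test_empty_group_rejected(self):
        ts = simulate(two_pool(), SimulationSpec(t_end=1.0, n_points=3))
        with pytest.raises(ModelError, match="empty"):
            conserved_totals(ts, {"nothing": []})


# ---------------------------------------------------------------- config

class TestConfigRoundTrip:
    def test_submodel_dict_round_trip_is_lossless(self):
        sm = build_fcepsilonri()
        again = submodel_from_dict(submodel_to_dict(sm))
        assert submodel_to_dict(again) == submodel_to_dict(sm)

    def test_trajectory_csv_round_trip(self):
        ts = simulate(two_pool(), SimulationSpec(t_end=20.0, n_points=21))
        buf = io.StringIO()
        ts.to_csv(buf)
        buf.seek(0)
        header = buf.readline()
        assert header.startswith("time_s,")
        buf.seek(0)
        back = TimeSeries.from_csv(buf)
        assert back.species == ts.species
        np.testing.assert_allclose(back.values, ts.values, rtol=1e-11)

    def test_simulation_spec_validation(self):
        with pytest.raises(ModelError):
            SimulationSpec(t_start=10.0, t_end=1.0)
        with pytest.raises(ModelError):
            SimulationSpec(t_end=10.0, output_times=np.array([0.0, 20.0]))
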