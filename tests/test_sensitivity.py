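"""Sensitivity tools: OAT error landscapes, three-way classification and
the feasible-parameter census."""

import numpy as np
import pytest

from nksignal.calibration import Dataset
from nksignal.core import (
    ModelError,
    Parameter,
    RateLaw,
    Reaction,
    SimulationSpec,
    Species,
    SubModel,
    register_rate,
)
from nksignal.datasets import generate_synthetic_timecourse
from nksignal.sensitivity import (
    AcceptanceBand,
    OATProfile,
    classify,
    find_alternate_solutions,
    oat_sweep,
)

GRID = np.linspace(-2, 2, 21)


class TestClassify:
    def test_constant_curve_is_flat(self):
        prof = OATProfile("p", GRID, np.full_like(GRID, 3.0), 1.0)
        assert classify(prof).label == "flat"

    def test_monotone_decreasing_curve_is_edge_minimum(self):
        prof = OATProfile("p", GRID, np.linspace(9.0, 1.0, GRID.size), 1.0)
        cls = classify(prof)
        assert cls.label == "edge_minimum"
        assert cls.argmin_exponent == GRID[-1]

    def test_v_shape_with_interior_argmin_is_sensitive(self):
        errors = (GRID - 0.3) ** 2 + 0.1
        cls = classify(OATProfile("p", GRID, errors, 2.0))
        assert cls.label == "sensitive"
        assert abs(cls.argmin_exponent - 0.3) <= (GRID[1] - GRID[0])

    def test_invariant_under_uniform_rescaling(self):
        errors = (GRID + 0.5) ** 2 + 0.2
        a = classify(OATProfile("p", GRID, errors, 1.0))
        b = classify(OATProfile("p", GRID, errors * 1e6, 1.0))
        assert (a.label, a.argmin_exponent) == (b.label, b.argmin_exponent)
        assert a.relative_range == pytest.approx(b.relative_range, rel=1e-12)

    def test_all_infinite_profile_unclassifiable(self):
        prof = OATProfile("p", GRID, np.full_like(GRID, np.inf), 1.0)
        with pytest.raises(ModelError, match="finite"):
            classify(prof)

    def test_failed_grid_points_do_not_block_classification(self):
        errors = (GRID - 0.2) ** 2 + 0.1
        errors[0] = np.inf  # one failed simulation at the boundary
        assert classify(OATProfile("p", GRID, errors, 1.0)).label == "sensitive"


def decay_model(k=1.0):
    return SubModel(
        "decay",
        [Species("A", initial_concentration=2.0), Species("B"),
         Species("ghost")],
        [Parameter("k", k), Parameter("k_ghost", 1.0)],
        [Reaction("r", {"A": 1}, {"B": 1}, constants={"k": "k"}),
         # a reaction whose sole reactant starts and stays at zero
         Reaction("g", {"ghost": 1}, {}, constants={"k": "k_ghost"})],
        ports=["A", "B"],
    )


class TestOatSweep:
    def setup_method(self):
        self.times = np.linspace(0.2, 6.0, 15)
        (self.ds,) = generate_synthetic_timecourse(decay_model(1.0),
                                                   ["decay/B"], self.times)
        self.sim = SimulationSpec(t_end=6.0, rel_tol=1e-9, abs_tol=1e-12)

    def test_known_optimum_found_within_one_grid_step(self):
        prof = oat_sweep(decay_model(), [self.ds], "decay/k", (-2, 2),
                         grid_size=41, sim=self.sim)
        cls = classify(prof)
        assert cls.label == "sensitive"
        step = prof.exponents[1] - prof.exponents[0]
        assert abs(cls.argmin_exponent - 0.0) <= step

    def test_parameter_the_model_ignores_sweeps_flat(self):
        """The ghost reaction's substrate is always zero, so its rate
        constant cannot move the objective."""
        prof = oat_sweep(decay_model(), [self.ds], "decay/k_ghost", (-2, 2),
                         grid_size=11, sim=self.sim)
        assert classify(prof).label == "flat"
        assert np.ptp(prof.errors) == pytest.approx(0.0, abs=1e-20)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ModelError):
            oat_sweep(decay_model(), [self.ds], "decay/k", (2, -2))


def saturating_model(k=1.0):
    """X' = k(1 − X): rises to 1, concave — its curve mean exceeds half its
    maximum, a convenient shape for band-acceptance checks."""
    register_rate("saturating_rise", species=["X"], params=["k"])(
        lambda X, k: k * (1.0 - X))
    return SubModel(
        "sat",
        [Species("X")],
        [Parameter("k", k)],
        [Reaction("r", {}, {"X": 1}, law=RateLaw.CUSTOM,
                  rate_fn="saturating_rise")],
        ports=["X"],
    )


class TestCensus:
    CHECK = np.linspace(1.0, 6.0, 6)
    SIM = SimulationSpec(t_end=6.0, rel_tol=1e-9, abs_tol=1e-12)

    def census(self, multiplier, mean, n_scale=2, seed=3):
        band = AcceptanceBand(means={"X": mean}, multiplier=multiplier)
        return find_alternate_solutions(
            saturating_model(), {"sat/k": (-2.0, 2.0)}, band, self.CHECK,
            observables={"X": "sat/X"}, n_scale=n_scale, seed=seed,
            sim=self.SIM)

    def test_generating_set_is_accepted_with_its_own_band(self):
        """A band built from a model's own mean prediction accepts the
        parameter set that produced it."""
        times = self.CHECK
        (ds,) = generate_synthetic_timecourse(saturating_model(1.0),
                                              ["sat/X"], times, sim=self.SIM)
        band = AcceptanceBand(means={"X": float(ds.values.mean())})
        result = find_alternate_solutions(
            saturating_model(), {"sat/k": (-1e-4, 1e-4)}, band, times,
            observables={"X": "sat/X"}, n_scale=1, seed=0, sim=self.SIM,
            datasets=[ds])
        assert len(result.accepted) == result.n_sampled  # all ~k_true pass
        assert min(result.ssqs) < 1e-6

    def test_acceptance_count_monotone_in_multiplier(self):
        counts = [len(self.census(m, mean=0.5, n_scale=4).accepted)
                  for m in (0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_boundary_is_inclusive(self):
        """Predictions exactly at multiplier×mean are accepted: with X
        clamped at v and mean v/2, every sample sits exactly on the bound."""
        sm = SubModel("sat", [Species("X", initial_concentration=0.4,
                                      clamped=True)],
                      [Parameter("k", 1.0)],
                      [Reaction("r", {}, {"X": 1}, law=RateLaw.CUSTOM,
                                rate_fn="saturating_rise")],
                      ports=["X"])
        band = AcceptanceBand(means={"X": 0.2}, multiplier=2.0)
        result = find_alternate_solutions(
            sm, {"sat/k": (-1.0, 1.0)}, band, self.CHECK,
            observables={"X": "sat/X"}, n_scale=1, seed=0, sim=self.SIM)
        assert len(result.accepted) == result.n_sampled
        # ... and a mean just below the prediction rejects everything
        band = AcceptanceBand(means={"X": 0.2 * (1 - 1e-9)}, multiplier=2.0)
        result = find_alternate_solutions(
            sm, {"sat/k": (-1.0, 1.0)}, band, self.CHECK,
            observables={"X": "sat/X"}, n_scale=1, seed=0, sim=self.SIM)
        assert result.accepted == []

    def test_gross_overprediction_rejected(self):
        """A band ten times below the plateau rejects every fast-rising
        sample."""
        result = self.census(2.0, mean=0.05, n_scale=2)
        # samples with k >~ 0.1 plateau near 1 >> 2x0.05
        assert len(result.accepted) < result.n_sampled

    def test_reproducible_for_fixed_seed(self):
        a = self.census(2.0, mean=0.5, seed=9)
        b = self.census(2.0, mean=0.5, seed=9)
        assert a.accepted == b.accepted
        assert np.array_equal(a.ssqs, b.ssqs, equal_nan=True)

    def test_band_validation(self):
        with pytest.raises(ModelError):
            AcceptanceBand(means={"X": 0.0})
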