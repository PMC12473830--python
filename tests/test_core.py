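"""Core engine: flux law, mass balance, analytic and matrix-exponential oracles."""

import numpy as np
import pytest
from scipy.linalg import expm

from dermapk.core import (
    Compartment,
    CompartmentSystem,
    Interface,
    InvalidInputError,
    ModelConfigError,
    build_rhs,
    flux,
    simulate,
    total_mass,
)


def two_compartment(p=1.0, a=1.0, kp=1.0, v=(1.0, 1.0), amounts=(10.0, 0.0), lag=0.0):
    return CompartmentSystem(
        [Compartment("a", v[0], amounts[0]), Compartment("b", v[1], amounts[1])],
        [Interface("a", "b", p, a, kp, lag_time=lag)],
    )


def random_linear_system(rng, n):
    comps = [
        Compartment(f"c{i}", volume=rng.uniform(0.5, 5.0), initial_amount=rng.uniform(0.0, 20.0))
        for i in range(n)
    ]
    # chain plus a random extra edge to vary the topology
    itfs = [
        Interface(f"c{i}", f"c{i+1}", rng.uniform(0.1, 2.0), rng.uniform(0.2, 2.0), rng.uniform(0.05, 5.0))
        for i in range(n - 1)
    ]
    if n >= 4:
        itfs.append(Interface("c0", f"c{n-1}", rng.uniform(0.1, 1.0), 1.0, rng.uniform(0.1, 3.0)))
    return CompartmentSystem(comps, itfs)


class TestFlux:
    @pytest.mark.parametrize(
        "p,a,c1,c2,kp,t,lag,expected",
        [
            (1.0, 1.0, 2.0, 0.0, 1.0, 1.0, 0.0, 2.0),  # direct substitution
            (3.0, 2.0, 1.0, 4.0, 4.0, 1.0, 0.0, 0.0),  # partition equilibrium C2/C1 = Kp
            (1.0, 1.0, 5.0, 0.0, 1.0, 0.5, 1.0, 0.0),  # lag gate closed
        ],
    )
    def test_flux_values(self, p, a, c1, c2, kp, t, lag, expected):
        itf = Interface("x", "y", p, a, kp, lag_time=lag)
        assert flux(itf, c1, c2, t) == pytest.approx(expected)

    def test_non_finite_inputs_rejected(self):
        itf = Interface("x", "y", 1.0, 1.0, 1.0)
        with pytest.raises(InvalidInputError):
            flux(itf, np.nan, 0.0, 1.0)


class TestBuildRhs:
    def test_single_flux_antisymmetry(self):
        sys2 = two_compartment()
        dy = build_rhs(sys2)(0.0, np.array([10.0, 0.0]))
        assert dy == pytest.approx([-10.0, 10.0])

    def test_isolated_compartments_have_zero_derivative(self):
        system = CompartmentSystem([Compartment("a", 1.0, 5.0), Compartment("b", 2.0)], [])
        assert build_rhs(system)(1.0, np.array([5.0, 0.0])) == pytest.approx([0.0, 0.0])

    def test_chain_derivatives_sum_to_zero(self, rng):
        system = random_linear_system(rng, 3)
        state = rng.uniform(0.0, 10.0, 3)
        assert build_rhs(system)(0.3, state).sum() == pytest.approx(0.0, abs=1e-12)

    def test_dangling_endpoint_rejected(self):
        with pytest.raises(ModelConfigError):
            CompartmentSystem([Compartment("a", 1.0)], [Interface("a", "ghost", 1.0, 1.0, 1.0)])

    def test_duplicate_pair_rejected(self):
        comps = [Compartment("a", 1.0), Compartment("b", 1.0)]
        with pytest.raises(ModelConfigError):
            CompartmentSystem(
                comps,
                [Interface("a", "b", 1.0, 1.0, 1.0), Interface("b", "a", 1.0, 1.0, 1.0)],
            )


class TestSimulate:
    def test_symmetric_equilibrium(self):
        res = simulate(two_compartment(), np.linspace(0, 20, 41))
        assert res.amounts[-1] == pytest.approx([5.0, 5.0], rel=1e-6)

    def test_matches_closed_form_exponential(self):
        # C1(t) - C2(t) = 10 exp(-2 P A t / V) for the symmetric pair
        res = simulate(two_compartment(), np.linspace(0, 3, 61), rtol=1e-8)
        diff = res.amount("a") - res.amount("b")
        expected = 10.0 * np.exp(-2.0 * res.times)
        assert np.max(np.abs(diff - expected) / np.maximum(expected, 1e-30)) < 1e-6

    def test_initial_state_exact(self):
        res = simulate(two_compartment(amounts=(7.0, 3.0)), np.linspace(0, 1, 11))
        assert res.amounts[0] == pytest.approx([7.0, 3.0], abs=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mass_conservation_random_systems(self, seed):
        rng = np.random.default_rng(seed)
        system = random_linear_system(rng, int(rng.integers(3, 6)))
        res = simulate(system, np.linspace(0, 10, 31))
        totals = res.amounts.sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) / totals[0] < 1e-6

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matrix_exponential_oracle(self, seed):
        """Lag-free linear systems must agree with expm of the rate matrix."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        system = random_linear_system(rng, n)
        t_grid = np.linspace(0, 5, 11)
        res = simulate(system, t_grid)
        # independent oracle: assemble M from first principles and use expm
        m = np.zeros((n, n))
        vols = system.volumes
        for itf in system.interfaces:
            i, j = system.index(itf.source), system.index(itf.target)
            pa = itf.permeability * itf.area
            m[i, i] -= pa / vols[i]
            m[i, j] += pa / (vols[j] * itf.partition_coefficient)
            m[j, i] += pa / vols[i]
            m[j, j] -= pa / (vols[j] * itf.partition_coefficient)
        y0 = system.initial_amounts
        scale = y0.sum()
        for k, t in enumerate(t_grid[1:], start=1):
            exact = expm(m * t) @ y0
            assert np.max(np.abs(res.amounts[k] - exact)) / scale < 1e-5

    def test_partition_equilibrium_ratio(self):
        kp = 3.7
        system = two_compartment(p=2.0, kp=kp)
        res = simulate(system, np.linspace(0, 200, 51))
        ratio = res.concentration("b")[-1] / res.concentration("a")[-1]
        assert ratio == pytest.approx(kp, rel=1e-3)

    def test_lag_gates_downstream_amounts(self):
        lag = 2.0
        system = CompartmentSystem(
            [Compartment("a", 1.0, 10.0), Compartment("b", 1.0), Compartment("c", 1.0)],
            [
                Interface("a", "b", 1.0, 1.0, 1.0, lag_time=lag),
                Interface("b", "c", 1.0, 1.0, 1.0),
            ],
        )
        res = simulate(system, np.linspace(0, 5, 51))
        before = res.times <= lag
        assert np.all(res.amount("b")[before] <= 1e-9)
        assert np.all(res.amount("c")[before] <= 1e-9)
        assert res.amount("b")[-1] > 1.0

    def test_non_negative_output(self):
        res = simulate(two_compartment(kp=0.01), np.linspace(0, 50, 101))
        assert np.all(res.amounts >= 0.0)

    @pytest.mark.parametrize(
        "grid", [[1.0, 2.0], [0.0, 1.0, 1.0], [0.0, 2.0, 1.0], [0.0]]
    )
    def test_bad_grid_rejected(self, grid):
        with pytest.raises(InvalidInputError):
            simulate(two_compartment(), grid)


class TestTotalMass:
    def test_matches_initial_total(self):
        system = two_compartment(amounts=(7.0, 3.0))
        res = simulate(system, np.linspace(0, 5, 21))
        assert total_mass(res, 0.0) == pytest.approx(10.0)
        assert total_mass(res, 3.3) == pytest.approx(10.0, rel=1e-6)

    def test_single_compartment_constant(self):
        system = CompartmentSystem([Compartment("only", 2.0, 500.0)], [])
        res = simulate(system, np.linspace(0, 10, 11))
        for t in (0.0, 4.5, 10.0):
            assert total_mass(res, t) == pytest.approx(500.0)

    def test_out_of_range_rejected(self):
        res = simulate(two_compartment(), np.linspace(0, 1, 11))
        with pytest.raises(InvalidInputError):
            total_mass(res, 2.0)


class TestSerialization:
    def test_json_round_trip(self, rng):
        system = random_linear_system(rng, 4)
        clone = CompartmentSystem.from_json(system.to_json())
        assert clone.to_dict() == system.to_dict()
        res_a = simulate(system, np.linspace(0, 2, 5))
        res_b = simulate(clone, np.linspace(0, 2, 5))
        assert np.array_equal(res_a.amounts, res_b.amounts)

    def test_long_format_frame(self):
        res = simulate(two_compartment(), np.linspace(0, 1, 3))
        df = res.to_frame()
        assert list(df.columns) == ["time_h", "compartment", "amount_ug", "concentration_ug_mL"]
        assert len(df) == 6
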