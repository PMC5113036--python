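"""Unit and property tests for the derivative function and its Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tipstalk as ts
from tipstalk.model import N_SPECIES, N_STATE

NOMINAL = ts.ModelParams()
NEUTRAL = ts.Modulators()


def state_strategy(lo=0.0, hi=50.0):
    return st.lists(
        st.floats(lo, hi, allow_nan=False), min_size=N_STATE, max_size=N_STATE
    ).map(np.array)


class TestEffectiveVegf:
    def test_zero_filopodia_identity(self):
        assert ts.effective_vegf(5.0, 0.0, NOMINAL) == 5.0

    def test_zero_ligand(self):
        assert ts.effective_vegf(0.0, 100.0, NOMINAL) == 0.0

    def test_hand_value(self):
        # 2 * (1 + 0.001 * 10**2) = 2.2
        assert ts.effective_vegf(2.0, 10.0, NOMINAL) == pytest.approx(2.2)

    def test_monotone_in_filopodia(self):
        levels = [ts.effective_vegf(1.0, f, NOMINAL) for f in (0, 1, 5, 20, 100)]
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            ts.effective_vegf(-1.0, 0.0, NOMINAL)
        with pytest.raises(ValueError):
            ts.effective_vegf(1.0, -1.0, NOMINAL)


class TestReactionRates:
    def test_cold_start_all_zero(self):
        rates = ts.reaction_rates(ts.default_initial_state(), ts.ExternalInputs())
        for name, vals in rates.items():
            assert np.all(vals == 0.0), name

    def test_v1_hand_value(self):
        # v1 = k1 * V * R2 = 0.1 * 1 * 1 at the default initial state
        rates = ts.reaction_rates(ts.default_initial_state(), ts.ExternalInputs(V1=1.0))
        assert rates["v1"][0] == pytest.approx(0.1)
        assert rates["v1"][1] == 0.0

    def test_v4_hill_hand_value(self):
        y = ts.default_initial_state()
        y[1] = 1.0  # cell1 VR2
        rates = ts.reaction_rates(y, ts.ExternalInputs())
        assert rates["v4"][0] == pytest.approx(0.1 * 1.0 / 2.0)

    def test_hill_rates_below_theta(self):
        y = np.full(N_STATE, 30.0)
        rates = ts.reaction_rates(y, ts.ExternalInputs(V1=1, V2=1))
        assert np.all(rates["v4"] < NOMINAL.theta)
        assert np.all(rates["v8"] < NOMINAL.theta)

    def test_lfng_scales_association_only(self):
        y = np.full(N_STATE, 2.0)
        base = ts.reaction_rates(y, ts.ExternalInputs(V1=1, V2=1), mods=ts.Modulators())
        up = ts.reaction_rates(
            y, ts.ExternalInputs(V1=1, V2=1), mods=ts.Modulators(lfng=2.0)
        )
        assert np.allclose(up["v5"], 2.0 * base["v5"])
        assert np.allclose(up["v6"], base["v6"])


class TestDerivatives:
    def test_hand_values_at_initial_state(self):
        d = ts.derivatives(0.0, ts.default_initial_state(), ts.ExternalInputs())
        assert d[0] == pytest.approx(-0.001 * 1.0 + 0.005)  # R2'
        assert d[2] == pytest.approx(NOMINAL.beta)  # DLL'
        assert d[7] == pytest.approx(NOMINAL.gamma)  # filo'
        assert d[1] == 0.0  # VR2'

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(y=state_strategy(), v1=st.floats(0, 10), v2=st.floats(0, 10),
           d1=st.floats(0, 5), d2=st.floats(0, 5))
    def test_exchange_symmetry(self, y, v1, v2, d1, d2):
        inp = ts.ExternalInputs(V1=v1, V2=v2, Dext1=d1, Dext2=d2)
        lhs = ts.derivatives(0.0, ts.swap_cells(y), inp.swapped())
        rhs = ts.swap_cells(ts.derivatives(0.0, y, inp))
        assert np.array_equal(lhs, rhs)

    def test_symmetric_state_symmetric_derivative(self):
        y = np.tile(np.linspace(0.5, 4.0, N_SPECIES), 2)
        d = ts.derivatives(0.0, y, ts.ExternalInputs(V1=2, V2=2, Dext1=1, Dext2=1))
        assert np.array_equal(d[:N_SPECIES], d[N_SPECIES:])

    def test_modulator_neutrality(self):
        y = np.abs(np.sin(np.arange(N_STATE))) * 3.0
        inp = ts.ExternalInputs(V1=2, V2=1, Dext1=0.5, Dext2=0.2)
        explicit = ts.derivatives(0.0, y, inp, mods=ts.Modulators(sirt1=1.0, lfng=1.0))
        default = ts.derivatives(0.0, y, inp)
        assert np.array_equal(explicit, default)

    def test_sirt1_isolated_to_nicd_rows(self):
        y = np.abs(np.cos(np.arange(N_STATE))) * 2.0 + 0.1
        inp = ts.ExternalInputs(V1=1, V2=1)
        d1 = ts.derivatives(0.0, y, inp, mods=ts.Modulators(sirt1=1.0))
        d2 = ts.derivatives(0.0, y, inp, mods=ts.Modulators(sirt1=2.0))
        diff = d2 - d1
        nicd_rows = [5, 5 + N_SPECIES]
        for i in range(N_STATE):
            if i in nicd_rows:
                expected = -NOMINAL.gamma * y[i]  # extra (sirt1-1)*gamma*nicd decay
                assert diff[i] == pytest.approx(expected)
            else:
                assert diff[i] == 0.0

    def test_invalid_state_rejected(self):
        y = ts.default_initial_state()
        y[0] = np.nan
        with pytest.raises(ValueError):
            ts.derivatives(0.0, y, ts.ExternalInputs())
        with pytest.raises(ValueError):
            ts.derivatives(0.0, y[:5], ts.ExternalInputs())

    def test_wiring_variants_evaluate(self):
        y = np.abs(np.sin(np.arange(N_STATE) + 1.0)) * 2.0
        inp = ts.ExternalInputs(V1=2, V2=1, Dext1=0.5, Dext2=1.0)
        for debit in ts.DllDebit:
            for mode in ts.DextMode:
                d = ts.make_rhs(inp, NOMINAL, NEUTRAL, debit, mode)(0.0, y)
                assert np.all(np.isfinite(d))
        # the variants genuinely differ from the default
        d_own = ts.make_rhs(inp, NOMINAL, NEUTRAL)(0.0, y)
        d_nb = ts.make_rhs(inp, NOMINAL, NEUTRAL, ts.DllDebit.NEIGHBOUR)(0.0, y)
        assert not np.array_equal(d_own, d_nb)


class TestJacobian:
    @pytest.mark.parametrize("n", [2.0, 1.0, 2.7])
    def test_matches_finite_differences(self, n):
        params = NOMINAL.replace(n=n)
        y = np.abs(np.sin(np.arange(N_STATE) * 1.7)) * 4.0 + 0.05
        inp = ts.ExternalInputs(V1=2, V2=1, Dext1=0.3, Dext2=0.8)
        Ja = ts.jacobian(y, inp, params)
        Jf = ts.fd_jacobian(y, inp, params)
        scale = max(np.max(np.abs(Jf)), 1.0)
        assert np.max(np.abs(Ja - Jf)) / scale < 1e-6

    def test_swap_conjugation(self):
        y = np.abs(np.cos(np.arange(N_STATE) * 0.9)) * 3.0
        inp = ts.ExternalInputs(V1=1.5, V2=0.5, Dext1=0.2, Dext2=1.0)
        P = np.zeros((N_STATE, N_STATE))
        for i in range(N_SPECIES):
            P[i, N_SPECIES + i] = 1.0
            P[N_SPECIES + i, i] = 1.0
        J_swapped = ts.jacobian(ts.swap_cells(y), inp.swapped())
        assert np.allclose(J_swapped, P @ ts.jacobian(y, inp) @ P.T)


class TestTrajectoryBounds:
    @pytest.mark.parametrize(
        "inputs",
        [
            ts.ExternalInputs(),
            ts.ExternalInputs(V1=5, V2=1),
            ts.ExternalInputs(V1=3.5, V2=3.5, Dext1=0.0, Dext2=2.0),
            ts.ExternalInputs(V1=8, V2=8),
        ],
    )
    def test_bounded_and_nonnegative_except_dll_pool(self, inputs):
        traj = ts.integrate(None, inputs)
        assert np.all(np.isfinite(traj.states))
        non_dll = [i for i in range(N_STATE) if i not in (2, 10)]
        assert traj.states[:, non_dll].min() > -1e-6
        # the DLL pool may be overdrawn, but only by a bounded amount
        assert traj.states[:, [2, 10]].min() > -10.0
        assert traj.states.max() < 1e5

    def test_state_containers_roundtrip(self):
        y = np.arange(N_STATE, dtype=float)
        tc = ts.TwoCellState.from_array(y)
        assert np.array_equal(tc.to_array(), y)
        assert tc.cell2.R2 == 8.0
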