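"""Tests for integration, pattern classification, sweeps and scans."""

import numpy as np
import pytest

import tipstalk as ts
from tipstalk.model import make_rhs


class TestIntegrate:
    def test_zero_input_reaches_equilibrium(self):
        traj = ts.integrate(None, ts.ExternalInputs())
        y = traj.final_state
        resid = make_rhs(ts.ExternalInputs())(0.0, y)
        assert np.max(np.abs(resid)) < 1e-7
        # basal notch tone quenches the receptor: R2 far below gamma/phi,
        # DLL near its basal beta/phi = 1, HE high
        assert y[0] < 0.1
        assert y[2] == pytest.approx(1.0, abs=0.2)
        assert y[6] > 10.0

    def test_first_state_is_initial_condition(self):
        y0 = ts.default_initial_state()
        traj = ts.integrate(y0, ts.ExternalInputs(V1=1), horizon=100.0)
        assert np.array_equal(traj.states[0], y0)
        assert np.all(np.diff(traj.times) > 0)

    def test_symmetric_inputs_symmetric_trajectory(self):
        traj = ts.integrate(None, ts.ExternalInputs(V1=2, V2=2), horizon=5000.0)
        assert np.allclose(
            traj.states[:, :8], traj.states[:, 8:], rtol=1e-7, atol=1e-9
        )

    def test_unit_bolus_resolves_symmetric_tie(self):
        # symmetric VEGF near threshold: bare, both cells activate together;
        # a unit external-DLL bolus on cell2 resolves the tie in cell1's favour
        V = 3.45
        bare = ts.classify_pattern(ts.integrate(None, ts.ExternalInputs(V1=V, V2=V)))
        bolus = ts.classify_pattern(
            ts.integrate(None, ts.ExternalInputs(V1=V, V2=V, Dext1=0.0, Dext2=1.0))
        )
        assert bare.label in ("A:A", "unresolved")
        assert bolus.label == "A:I"

    def test_solver_tolerance_robustness(self):
        inp = ts.ExternalInputs(V1=5, V2=1)
        t1 = ts.classify_pattern(ts.integrate(None, inp)).patterning_time
        t2 = ts.classify_pattern(
            ts.integrate(None, inp, rtol=5e-9, atol=5e-11)
        ).patterning_time
        assert abs(t1 - t2) / t1 < 0.01

    def test_horizon_validation(self):
        with pytest.raises(ValueError):
            ts.integrate(None, ts.ExternalInputs(), horizon=-1.0)
        with pytest.raises(ValueError):
            ts.integrate(np.zeros(5), ts.ExternalInputs())

    def test_schedule_requires_vegf(self):
        sched = ts.make_switch_schedule("abrupt", 2.0, 1000.0)
        with pytest.raises(ValueError):
            ts.integrate(None, sched, horizon=100.0)


class TestClassifyPattern:
    @staticmethod
    def _mock_traj(dll1, dll2):
        """Constant-DLL trajectory through the real container."""
        n = 50
        states = np.zeros((n, 16))
        states[:, 2] = dll1
        states[:, 10] = dll2
        times = np.linspace(0.0, 100.0, n)
        traj = ts.Trajectory.__new__(ts.Trajectory)
        traj.times = times
        traj.states = states
        traj.inputs_used = ts.ExternalInputs()
        traj._segments = []
        return traj

    def test_threshold_labels(self):
        assert ts.classify_pattern(self._mock_traj(20.0, 0.1)).label == "A:I"
        assert ts.classify_pattern(self._mock_traj(0.1, 20.0)).label == "I:A"
        assert ts.classify_pattern(self._mock_traj(20.0, 20.0)).label == "A:A"
        assert ts.classify_pattern(self._mock_traj(0.1, 0.1)).label == "I:I"
        assert ts.classify_pattern(self._mock_traj(1.0, 1.0)).label == "unresolved"

    def test_time_only_for_differential(self):
        assert ts.classify_pattern(self._mock_traj(20, 20)).patterning_time is None
        assert ts.classify_pattern(self._mock_traj(1, 1)).patterning_time is None
        out = ts.classify_pattern(self._mock_traj(20, 0.1))
        assert out.patterning_time is not None

    def test_patterning_time_resolution_and_persistence(self):
        traj = ts.integrate(None, ts.ExternalInputs(V1=5, V2=1))
        out = ts.classify_pattern(traj)
        assert out.label == "A:I"
        t = out.patterning_time
        assert 0 < t < 20000
        # persistence: condition holds from t to the horizon
        for probe in np.linspace(t + 1.0, traj.times[-1], 7):
            y = traj.at(probe)
            assert y[2] > ts.ACTIVE_DLL and y[10] < ts.INACTIVE_DLL
        # and fails just before t (1 s resolution)
        y = traj.at(t - 2.0)
        assert not (y[2] > ts.ACTIVE_DLL and y[10] < ts.INACTIVE_DLL)

    def test_threshold_argument_validation(self):
        with pytest.raises(ValueError):
            ts.classify_pattern(self._mock_traj(1, 1), active_thresh=0.4)


class TestSweep:
    def test_swap_covariance(self, vegf_sweep):
        L = vegf_sweep.label_matrix()
        T = vegf_sweep.time_matrix()
        flip = {"A:I": "I:A", "I:A": "A:I"}
        n = L.shape[0]
        for i in range(n):
            for j in range(n):
                assert L[i, j] == flip.get(L[j, i], L[j, i])
        assert np.allclose(np.nan_to_num(T), np.nan_to_num(T.T), rtol=1e-2)

    def test_vegf_contrast_monotonicity(self, vegf_sweep):
        """Within a row, patterning accelerates with the VEGF contrast."""
        T = vegf_sweep.time_matrix()
        n = T.shape[0]
        for i in range(n):
            for cols in (range(0, i), range(n - 1, i, -1)):
                # iterate toward the diagonal: |V1 - V2| decreases
                times = [T[i, j] for j in cols if not np.isnan(T[i, j])]
                assert all(
                    b >= a - 1.0 for a, b in zip(times, times[1:])
                ), f"row {i}"

    def test_active_winners_exceed_threshold(self, vegf_sweep):
        diff = [o for o in vegf_sweep.outcomes if o.label in ("A:I", "I:A")]
        assert len(diff) > 50
        assert all(max(o.final_dll) > ts.ACTIVE_DLL for o in diff)

    def test_errors_recorded_not_raised(self, monkeypatch):
        import tipstalk.simulate as sim

        calls = {"n": 0}
        real = sim.integrate

        def flaky(*args, **kwargs):
            calls["n"] += 1
            if calls["n"] == 1:
                raise RuntimeError("boom")
            return real(*args, **kwargs)

        monkeypatch.setattr(sim, "integrate", flaky)
        res = sim.sweep(
            [ts.ExternalInputs(V1=5, V2=1), ts.ExternalInputs(V1=1, V2=5)],
            horizon=500.0,
        )
        assert res.outcomes[0].error == "boom"
        assert res.outcomes[1].error is None


class TestModulatorScan:
    def test_neutral_level_reproduces_control(self):
        res = ts.modulator_scan("sirt1", [1.0])
        control = ts.classify_pattern(ts.integrate(None, ts.SIRT1_SCAN_BASE))
        assert res.table.label.iloc[0] == control.label
        assert res.table.DLL1_final.iloc[0] == control.final_dll[0]

    def test_lfng_directions(self):
        """Weak Lfng releases both cells (A:A); strong Lfng silences both."""
        res = ts.modulator_scan("lfng", [0.5, 1.0, 2.0])
        labels = list(res.table.label)
        assert labels[0] == "A:A"
        assert labels[1] in ("A:I", "I:A")
        # at double Lfng neither cell reaches the active state
        assert labels[2] in ("I:I", "unresolved")
        assert max(res.table.DLL1_final.iloc[2], res.table.DLL2_final.iloc[2]) < ts.ACTIVE_DLL

    def test_scan_input_validation(self):
        with pytest.raises(ValueError):
            ts.modulator_scan("sirt1", [2.0, 1.0])
        with pytest.raises(ValueError):
            ts.modulator_scan("other", [1.0])


class TestPositionSwitch:
    def test_abrupt_switch_completes(self):
        sched = ts.make_switch_schedule("abrupt", 12.0, 40000.0)
        traj, labels = ts.run_position_switch(sched, horizon=80000.0)
        # starts A:I, ends I:A
        assert labels.cell1.iloc[0] == "A" and labels.cell2.iloc[0] == "I"
        assert labels.cell1.iloc[-1] == "I" and labels.cell2.iloc[-1] == "A"

    def test_gradual_switch_has_longer_intermediate_phase(self):
        kinds = {}
        for kind in ("abrupt", "gradual"):
            sched = ts.make_switch_schedule(kind, 12.0, 60000.0)
            traj, _ = ts.run_position_switch(sched, horizon=100000.0)
            d = traj.dll()
            patterned = ((d[:, 0] > 13) & (d[:, 1] < 0.5)) | (
                (d[:, 1] > 13) & (d[:, 0] < 0.5)
            )
            dt = float(np.median(np.diff(traj.times)))
            kinds[kind] = float((~patterned).sum() * dt)
        assert kinds["gradual"] > 1.5 * kinds["abrupt"]

    def test_sirt1_shortens_plateau(self):
        plateaus = {}
        for s1 in (1.0, 2.0):
            sched = ts.make_switch_schedule("gradual", 12.0, 40000.0)
            traj, labels = ts.run_position_switch(
                sched, mods=ts.Modulators(sirt1=s1), horizon=80000.0
            )
            both_pi = (labels.cell1 == "pI") & (labels.cell2 == "pI")
            plateaus[s1] = int(both_pi.sum())
        assert plateaus[2.0] < plateaus[1.0]
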