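"""Objective functions: spectral measurements and window deviations."""

import numpy as np
import pytest

from procdesign.objectives import (
    OscillatorSpec,
    SwitchSpec,
    amplitude,
    dominant_frequency,
    oscillator_objectives,
    relative_discrepancy,
    switch_objectives,
)
from procdesign.simulate import SamplingGrid, Trajectory


def signal_traj(fn, t_start=0.0, t_end=28.0, rate=40.0, species="x"):
    grid = SamplingGrid.regular(t_start, t_end, rate)
    return Trajectory(grid, [species], fn(grid.times)[None, :])


class TestDominantFrequency:
    def test_pure_sinusoid_1hz(self):
        traj = signal_traj(lambda t: np.sin(2 * np.pi * t))
        f = dominant_frequency(traj, "x", t0=2.0)
        assert f == pytest.approx(1.0, abs=1.0 / 26.0)  # within one bin

    def test_constant_signal_returns_zero(self):
        traj = signal_traj(lambda t: np.full_like(t, 3.3))
        assert dominant_frequency(traj, "x", t0=2.0) == 0.0

    def test_mixture_picks_dominant_component(self):
        traj = signal_traj(
            lambda t: np.sin(2 * np.pi * t) + 0.1 * np.sin(2 * np.pi * 5 * t)
        )
        assert dominant_frequency(traj, "x", t0=2.0) == pytest.approx(1.0, abs=1.0 / 26.0)

    def test_matches_brute_force_dft_argmax_on_random_signals(self):
        """Oracle: explicit DFT magnitudes, argmax over nonzero bins."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            n_comp = rng.integers(1, 4)
            freqs = rng.uniform(0.2, 15.0, n_comp)
            amps = rng.uniform(0.1, 2.0, n_comp)
            phases = rng.uniform(0, 2 * np.pi, n_comp)

            def fn(t):
                return sum(
                    a * np.sin(2 * np.pi * f * t + p)
                    for f, a, p in zip(freqs, amps, phases)
                ) + rng.normal(0, 0.01, len(t))

            traj = signal_traj(fn)
            x = traj.get("x")[traj.grid.times >= 2.0]
            x = x - x.mean()
            ks = np.arange(1, len(x) // 2 + 1)
            dft = np.exp(-2j * np.pi * np.outer(ks, np.arange(len(x))) / len(x))
            mags = np.abs(dft @ x)
            expected = np.fft.rfftfreq(len(x), d=1 / 40.0)[1:][np.argmax(mags)]
            assert dominant_frequency(traj, "x", t0=2.0) == pytest.approx(expected)


class TestAmplitude:
    def test_sinusoid_peak_to_trough_is_2(self):
        traj = signal_traj(lambda t: np.sin(2 * np.pi * t))
        assert amplitude(traj, "x", t0=2.0) == pytest.approx(2.0, abs=1e-2)

    def test_constant_is_zero(self):
        traj = signal_traj(lambda t: np.full_like(t, 7.0))
        assert amplitude(traj, "x", t0=2.0) == 0.0

    def test_offset_sinusoid(self):
        traj = signal_traj(lambda t: 0.5 + 0.05 * np.sin(2 * np.pi * t))
        assert amplitude(traj, "x", t0=2.0) == pytest.approx(0.1, abs=1e-3)


class TestOscillatorObjectives:
    def test_exact_target_sinusoid_scores_origin(self):
        spec = OscillatorSpec("x", f_target=1.0, a_target=2.0)
        traj = signal_traj(lambda t: np.sin(2 * np.pi * t))
        obj = oscillator_objectives(traj, spec)
        assert obj == pytest.approx([0.0, 0.0], abs=0.05)

    def test_zero_amplitude_scores_one_on_amplitude(self):
        spec = OscillatorSpec("x", f_target=1.0, a_target=0.1)
        traj = signal_traj(lambda t: np.full_like(t, 0.3))
        obj = oscillator_objectives(traj, spec)
        assert obj[1] == 1.0

    def test_double_frequency_scores_half(self):
        # measured = 2*target: |f - 2f| / max(f, 2f) = 0.5
        assert relative_discrepancy(1.0, 2.0) == pytest.approx(0.5)
        spec = OscillatorSpec("x", f_target=1.0, a_target=2.0)
        traj = signal_traj(lambda t: np.sin(2 * np.pi * 2.0 * t))
        obj = oscillator_objectives(traj, spec)
        assert obj[0] == pytest.approx(0.5, abs=0.02)

    def test_failed_trajectory_maps_to_worst(self):
        grid = SamplingGrid.regular(0, 28, 40)
        traj = Trajectory(grid, ["x"], np.full((1, len(grid)), np.nan), ok=False)
        obj = oscillator_objectives(traj, OscillatorSpec("x", 1.0, 0.1))
        assert np.all(obj == 1.0)

    def test_components_always_in_unit_interval(self):
        rng = np.random.default_rng(5)
        spec = OscillatorSpec("x", f_target=1.0, a_target=0.1)
        for _ in range(20):
            traj = signal_traj(
                lambda t: rng.uniform(0, 10) * np.sin(2 * np.pi * rng.uniform(0.05, 19) * t)
                + rng.uniform(-5, 5)
            )
            obj = oscillator_objectives(traj, spec)
            assert np.all((0 <= obj) & (obj <= 1))


def switch_traj(values, grid=None):
    grid = grid or SamplingGrid.integers(0, 100)
    return Trajectory(grid, ["B"], np.asarray(values, float)[None, :],
                      kind="ensemble-mean", n_realizations=100)


class TestSwitchObjectives:
    SPEC = SwitchSpec("B", high_level=10.0, alpha=(10, 45), beta=(60, 95))

    def test_ideal_profile_scores_origin(self):
        t = np.arange(101.0)
        b = np.where((t >= 10) & (t <= 45), 10.0, 0.0)
        assert switch_objectives(switch_traj(b), self.SPEC) == pytest.approx([0.0, 0.0])

    def test_flat_zero_scores_one_zero(self):
        assert switch_objectives(switch_traj(np.zeros(101)), self.SPEC) == pytest.approx(
            [1.0, 0.0]
        )

    def test_half_level_everywhere_scores_half_half(self):
        b = np.full(101, 5.0)
        assert switch_objectives(switch_traj(b), self.SPEC) == pytest.approx([0.5, 0.5])

    def test_deviation_monotonicity_until_clamp(self):
        t = np.arange(101.0)
        vals = []
        for level in (10.0, 8.0, 6.0, 0.0):
            b = np.where((t >= 10) & (t <= 45), level, 0.0)
            vals.append(switch_objectives(switch_traj(b), self.SPEC)[0])
        assert vals == sorted(vals)
        assert vals[0] == 0.0 and vals[-1] == 1.0

    def test_expected_profile_from_fixture_scores_origin(self):
        from procdesign.casestudies import build_toggle_task, expected_switch_profile

        task = build_toggle_task()
        traj = expected_switch_profile(task.objective, task.grid)
        assert switch_objectives(traj, task.objective) == pytest.approx([0.0, 0.0])
        assert set(np.unique(traj.values)) == {0.0, task.objective.high_level}

    def test_empty_alpha_window_is_an_error(self):
        from procdesign.casestudies import expected_switch_profile

        spec = SwitchSpec("B", 10.0, alpha=(10.2, 10.8), beta=(60, 95))
        with pytest.raises(ValueError, match="alpha"):
            expected_switch_profile(spec, SamplingGrid.integers(0, 100))

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            SwitchSpec("B", 10.0, alpha=(10, 60), beta=(50, 95))
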