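"""Design objectives: trajectory -> minimized objective vector.

Every objective component is normalized to a finite, a-priori known
domain [0, 1] with the optimum at 0, as required for the hypervolume
ranking to be well defined.  Two families are provided:

* switching objectives for the toggle-switch task — mean relative
  deviation of the observed protein count from the target level H over a
  "high" window alpha, and mean level relative to H over a "low" window
  beta;
* oscillation objectives for the negative-feedback oscillator — the
  relative discrepancy between the target and measured dominant
  frequency (largest component of the Fourier spectrum of the post-
  transient signal) and between the target and measured peak-to-trough
  amplitude.

Relative discrepancies use the symmetric form |target - measured| /
max(target, measured), which lies in [0, 1] by construction.  Failed
simulations map to the worst vector (all ones) so that optimization
stays total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import Trajectory

__all__ = [
    "SwitchSpec",
    "OscillatorSpec",
    "dominant_frequency",
    "amplitude",
    "oscillator_objectives",
    "switch_objectives",
    "relative_discrepancy",
]


@dataclass(frozen=True)
class SwitchSpec:
    """Expected switching behaviour of an observed protein count.

    The inducer schedule (injections driving the switch) is part of the
    spec because the windows only make sense relative to it: the first
    inducer pulse should drive the observed protein high on ``alpha``
    (target level H), the second should drive it to 0 on ``beta``.
    """

    species: str
    high_level: float
    alpha: tuple[float, float]
    beta: tuple[float, float]
    schedule: tuple[tuple[float, str, float], ...] = ()

    def __post_init__(self):
        a0, a1 = self.alpha
        b0, b1 = self.beta
        if max(a0, b0) < min(a1, b1) and max(a0, b0) < min(a1, b1):
            if not (a1 <= b0 or b1 <= a0):
                raise ValueError("alpha and beta windows must be disjoint")
        if self.high_level <= 0:
            raise ValueError("high_level must be positive")


@dataclass(frozen=True)
class OscillatorSpec:
    """Target oscillation (frequency in Hz, peak-to-trough amplitude in
    concentration units) of an observed species, evaluated after a
    transient cutoff ``t0``."""

    species: str
    f_target: float
    a_target: float
    t0: float = 2.0

    def __post_init__(self):
        if self.f_target <= 0 or self.a_target <= 0:
            raise ValueError("targets must be positive")


def _post_transient(traj: Trajectory, species: str, t0: float) -> tuple[np.ndarray, float]:
    t = traj.grid.times
    mask = t >= t0
    if mask.sum() < 4:
        raise ValueError("transient cutoff leaves too few samples")
    dt = np.diff(t[mask])
    if not np.allclose(dt, dt[0]):
        raise ValueError("dominant_frequency requires uniform sampling after t0")
    return traj.get(species)[mask], dt[0]


def dominant_frequency(traj: Trajectory, species: str, t0: float = 0.0) -> float:
    """Frequency (Hz) of the largest-magnitude nonzero component of the
    discrete Fourier spectrum of the post-``t0``, mean-removed signal.
    A constant signal returns 0."""
    x, dt = _post_transient(traj, species, t0)
    x = x - x.mean()
    if np.allclose(x, 0):
        return 0.0
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=dt)
    k = int(np.argmax(spec[1:])) + 1  # skip the (zeroed) DC bin
    return float(freqs[k])


def amplitude(traj: Trajectory, species: str, t0: float = 0.0) -> float:
    """Peak-to-trough (max - min) amplitude of the post-``t0`` signal."""
    x, _ = _post_transient(traj, species, t0)
    return float(x.max() - x.min())


def relative_discrepancy(target: float, measured: float) -> float:
    """|target - measured| / max(target, measured), in [0, 1]."""
    m = max(abs(target), abs(measured))
    if m == 0:
        return 0.0
    return min(1.0, abs(target - measured) / m)


def oscillator_objectives(traj: Trajectory, spec: OscillatorSpec) -> np.ndarray:
    """(frequency discrepancy, amplitude discrepancy), each in [0, 1];
    failed simulations map to (1, 1)."""
    if not traj.ok or not np.all(np.isfinite(traj.values)):
        return np.array([1.0, 1.0])
    f_hat = dominant_frequency(traj, spec.species, spec.t0)
    a_hat = amplitude(traj, spec.species, spec.t0)
    return np.array(
        [
            relative_discrepancy(spec.f_target, f_hat),
            relative_discrepancy(spec.a_target, a_hat),
        ]
    )


def switch_objectives(traj: Trajectory, spec: SwitchSpec) -> np.ndarray:
    """(O1, O2): interval-normalized deviations of the ensemble-mean
    observed count from the ideal profile (H on alpha, 0 on beta), each
    clamped to [0, 1]; failed simulations map to (1, 1)."""
    if not traj.ok or not np.all(np.isfinite(traj.values)):
        return np.array([1.0, 1.0])
    t = traj.grid.times
    b = traj.get(spec.species)
    H = spec.high_level
    in_alpha = (t >= spec.alpha[0]) & (t <= spec.alpha[1])
    in_beta = (t >= spec.beta[0]) & (t <= spec.beta[1])
    if not in_alpha.any():
        raise ValueError("alpha window contains no sample points")
    if not in_beta.any():
        raise ValueError("beta window contains no sample points")
    o1 = float(np.mean(np.abs(b[in_alpha] - H)) / H)
    o2 = float(np.mean(b[in_beta]) / H)
    return np.array([min(1.0, o1), min(1.0, o2)])
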