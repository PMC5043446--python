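"""Trajectory production: deterministic ODE integration and Gillespie
stochastic simulation with ensemble averaging.

Deterministic networks are integrated with an adaptive embedded
Dormand–Prince 5(4) scheme compiled with numba (defaults rtol=1e-6,
atol=1e-9); a SciPy LSODA path is available as an independent
cross-check and as a fallback for genuinely stiff parameter corners.
Stochastic networks are simulated with the Gillespie direct method;
trajectories are right-continuous piecewise-constant evaluated at the
grid times, and the ensemble mean over ``n_real`` realizations is
returned.  Reproducibility contract: realization ``i`` of a run with
master seed ``s`` depends only on ``(s, i)``.

Both simulators accept a piecewise-constant input schedule: events that
add to, or clamp ("set"), a species count at given times — used to
drive the toggle switch with its prescribed inducer pulses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .network import CompiledNetwork, NetworkError, ReactionNetwork, UnsupportedRateLaw

__all__ = [
    "SamplingGrid",
    "Trajectory",
    "SimulationError",
    "simulate_ode",
    "simulate_ssa",
    "realization_seeds",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SamplingGrid:
    t_start: float
    t_end: float
    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if not (np.isclose(t[0], self.t_start) and np.isclose(t[-1], self.t_end)):
            raise ValueError("sample times must cover [t_start, t_end]")
        object.__setattr__(self, "times", t)

    @classmethod
    def regular(cls, t_start: float, t_end: float, rate_hz: float) -> "SamplingGrid":
        """Uniform sampling at ``rate_hz`` samples per time unit."""
        n = int(round((t_end - t_start) * rate_hz))
        return cls(t_start, t_end, t_start + np.arange(n + 1) / rate_hz)

    @classmethod
    def integers(cls, t_start: int, t_end: int) -> "SamplingGrid":
        return cls(float(t_start), float(t_end), np.arange(t_start, t_end + 1, dtype=float))

    def __len__(self):
        return len(self.times)


@dataclass
class Trajectory:
    grid: SamplingGrid
    species: list[str]
    values: np.ndarray  # (n_species, n_samples)
    kind: str = "single"  # single | ensemble-mean
    n_realizations: int = 1
    ok: bool = True
    n_failed: int = 0

    def __post_init__(self):
        if self.values.shape != (len(self.species), len(self.grid)):
            raise ValueError("trajectory matrix shape must be (n_species, n_samples)")

    def get(self, species: str) -> np.ndarray:
        return self.values[self.species.index(species)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"time": self.grid.times, **{s: self.values[i] for i, s in enumerate(self.species)}}
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


Event = tuple  # (time, species, value[, mode]); mode "add" (default) or "set"


def _event_parts(e):
    t, sp, val = e[0], e[1], e[2]
    mode = e[3] if len(e) > 3 else "add"
    if mode not in ("add", "set"):
        raise ValueError(f"unknown event mode {mode!r}")
    return float(t), sp, float(val), mode


def _compiled(net) -> CompiledNetwork:
    return net if isinstance(net, CompiledNetwork) else net.compile()


def _segments(grid: SamplingGrid, events: list[Event] | None):
    """Split the grid at event times; events at/before t_start apply
    immediately."""
    evs = sorted(events or [], key=lambda e: e[0])
    bounds = sorted({e[0] for e in evs if grid.t_start < e[0] < grid.t_end})
    return evs, bounds


def simulate_ode(
    net: ReactionNetwork | CompiledNetwork,
    params: dict[str, float] | np.ndarray,
    grid: SamplingGrid,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    events: list[Event] | None = None,
    method: str = "rk45",
    max_steps: int = 5_000_000,
) -> Trajectory:
    """Deterministic trajectory on the grid.

    Integration failure does not raise: the returned trajectory is
    flagged ``ok=False`` so that objective evaluation can map it to
    worst-case objective values.
    """
    cn = _compiled(net)
    p = cn.param_vector(params) if isinstance(params, dict) else np.asarray(params, float)
    sidx = cn.net.species_index()
    y = cn.net.initial_vector()
    # half-saturation constants enter only as K**n: precompute per reaction
    Kn = np.zeros(cn.n_reactions)
    hill = cn.kind == 1
    if hill.any():
        Kn[hill] = p[cn.K_idx[hill]] ** p[cn.n_idx[hill]]
    out = np.empty((cn.n_species, len(grid)))
    evs, bounds = _segments(grid, events)
    for e in evs:
        t0, sp, amt, mode = _event_parts(e)
        if t0 <= grid.t_start:
            y[sidx[sp]] = amt if mode == "set" else y[sidx[sp]] + amt

    t = grid.times
    cut_times = [grid.t_start] + bounds + [grid.t_end]
    ok = True
    for a, b in zip(cut_times[:-1], cut_times[1:]):
        mask = (t >= a) & (t <= b)
        sub = t[mask]
        if len(sub) == 0 or sub[0] > a:
            sub = np.concatenate(([a], sub))
            pad = 1
        else:
            pad = 0
        if sub[-1] < b:
            sub = np.concatenate((sub, [b]))
        seg_out = np.empty((cn.n_species, len(sub)))
        if method == "rk45":
            status, y_end = _kernels.rk45_integrate(
                y, sub, p,
                cn.in_ptr, cn.in_sp, cn.in_st, cn.stoich, cn.kind,
                cn.k_idx, cn.n_idx, cn.sub_idx, cn.cat_idx, Kn,
                rtol, atol, max_steps, seg_out,
            )
            ok = ok and status == _kernels.OK
        elif method == "lsoda":
            from scipy.integrate import solve_ivp

            def f(_t, _y):
                from .network import _rates

                return _rates(cn, _y, p) @ cn.stoich

            sol = solve_ivp(f, (sub[0], sub[-1]), y, method="LSODA",
                            t_eval=sub, rtol=rtol, atol=atol)
            ok = ok and sol.success
            if sol.success:
                seg_out[:, :] = sol.y
                y_end = sol.y[:, -1].copy()
            else:
                seg_out[:, :] = y[:, None]
                y_end = y
        else:
            raise ValueError(f"unknown method {method!r}")
        if not ok:
            out[:, :] = np.nan
            break
        n_keep = int(mask.sum())
        out[:, mask] = seg_out[:, pad:pad + n_keep]
        y = y_end
        for e in evs:
            t0, sp, amt, mode = _event_parts(e)
            if np.isclose(t0, b) and b < grid.t_end:
                y[sidx[sp]] = amt if mode == "set" else y[sidx[sp]] + amt
    return Trajectory(grid, list(cn.net.species), out, kind="single", n_realizations=1, ok=ok)


def realization_seeds(master_seed: int, n_real: int) -> np.ndarray:
    """Counter-based per-realization seeds: realization i depends only on
    (master_seed, i), so ensembles are order- and size-extensible."""
    out = np.empty(n_real, dtype=np.int64)
    for i in range(n_real):
        out[i] = int(np.random.SeedSequence((master_seed, i)).generate_state(1)[0] % (2**31 - 1))
    return out


def simulate_ssa(
    net: ReactionNetwork | CompiledNetwork,
    params: dict[str, float] | np.ndarray,
    grid: SamplingGrid,
    n_real: int,
    seed: int,
    events: list[Event] | None = None,
    max_total: int = 1_000_000,
    max_events: int = 10_000_000,
    on_failure: str = "raise",
) -> Trajectory:
    """Ensemble-mean stochastic trajectory (Gillespie direct method).

    ``max_total`` caps the total molecule count per realization (the
    pragmatic finite-state-space guard) and ``max_events`` the number of
    reaction firings; a realization exceeding either is aborted.  With
    ``on_failure="raise"`` any aborted realization raises
    :class:`SimulationError`; with ``"flag"`` the trajectory is returned
    flagged (mean over the successful realizations only).
    """
    cn = _compiled(net)
    if not cn.net.is_stochastic_compatible():
        raise UnsupportedRateLaw("network contains mm-cooperative rate laws")
    p = cn.param_vector(params) if isinstance(params, dict) else np.asarray(params, float)
    y0 = cn.net.initial_vector()
    if np.any(y0 < 0) or np.any(y0 != np.round(y0)):
        raise NetworkError("stochastic simulation needs non-negative integer initial counts")
    counts0 = y0.astype(np.int64)
    sidx = cn.net.species_index()
    evs = [_event_parts(e) for e in sorted(events or [], key=lambda e: e[0])]
    ev_t = np.array([e[0] for e in evs], dtype=float)
    ev_sp = np.array([sidx[e[1]] for e in evs], dtype=np.int64)
    ev_amt = np.array([int(e[2]) for e in evs], dtype=np.int64)
    ev_set = np.array([e[3] == "set" for e in evs], dtype=np.bool_)

    seeds = realization_seeds(seed, n_real)
    sum_out = np.zeros((cn.n_species, len(grid)))
    stoich_int = cn.stoich.astype(np.int64)
    n_failed = _kernels.ssa_ensemble(
        counts0, grid.t_start, grid.times, p,
        cn.in_ptr, cn.in_sp, cn.in_st, stoich_int, cn.k_idx,
        ev_t, ev_sp, ev_amt, ev_set, seeds, max_total, max_events, sum_out,
    )
    n_ok = n_real - n_failed
    if n_failed and on_failure == "raise":
        raise SimulationError(
            f"{n_failed}/{n_real} realizations aborted (state cap or event budget)"
        )
    values = sum_out / n_ok if n_ok else np.full_like(sum_out, np.nan)
    return Trajectory(
        grid, list(cn.net.species), values,
        kind="ensemble-mean", n_realizations=n_real,
        ok=(n_failed == 0), n_failed=n_failed,
    )
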