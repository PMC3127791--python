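"""Stochastic (Gillespie) and deterministic (ODE) trajectory simulation.

Both simulators handle the piecewise-constant stress input by splitting
the run at every stress toggle: the SSA resamples its exponential
waiting time at each boundary (exact, by memorylessness, because the
propensities change discontinuously there), and the ODE integrator is
restarted per segment so the solver never steps across a discontinuity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import odeint

from .model import (
    PLACES,
    PspParameters,
    StressSchedule,
    stress_at,
)

__all__ = [
    "Trajectory",
    "SimOptions",
    "simulate_ssa",
    "simulate_ode",
    "endpoint_states",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
]


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course over the eight Psp state variables.

    ``states`` has one row per entry of ``times`` and one column per
    place in canonical order.  Stochastic trajectories are step
    functions (right-continuous): row i holds on ``[times[i],
    times[i+1])``.
    """

    times: np.ndarray
    states: np.ndarray
    framework: str  # "stochastic" | "deterministic"
    seed: int | None = None
    truncated: bool = False

    def species(self, name: str) -> np.ndarray:
        return self.states[:, PLACES.index(name)]


@dataclass(frozen=True)
class SimOptions:
    max_events: int = 1_000_000
    ode_rel_tol: float = 1e-8
    ode_abs_tol: float = 1e-10
    output_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.max_events < 1:
            raise ValueError("max_events must be >= 1")
        if self.ode_rel_tol <= 0 or self.ode_abs_tol <= 0:
            raise ValueError("tolerances must be positive")


#: width (percent membrane) of the linear ramp replacing the sharp
#: dm>0 indicator in the ODE right-hand side; keeps the vector field
#: continuous at the dm=0 sliding mode without visibly moving solutions
_GATE_WIDTH = 1e-6


def _gate(x: float) -> float:
    """Continuous stand-in for the indicator 1{x>0}: a ramp on [0, _GATE_WIDTH]."""
    if x >= _GATE_WIDTH:
        return 1.0
    if x <= 0.0:
        return 0.0
    return x / _GATE_WIDTH


# state-change vectors as (place index, delta) lists, one per transition
_DELTAS = (
    ((1, +1), (2, -1)),            # tr1  im → dm
    ((1, -1), (2, +1)),            # tr2  dm → im
    ((4, +10), (3, +1)),           # tr3  ∅ → 10 hBCA + olg
    ((4, -1), (7, -1), (6, +1)),   # tr4  hBCA + TF → hBCAF
    ((6, -1), (5, +1), (7, +1)),   # tr5  hBCAF → hBcCcAc + TF
    ((5, -1), (4, +1)),            # tr6  hBcCcAc → hBCA
    ((4, -1), (5, +1)),            # tr7  hBCA → hBcCcAc
    ((4, -1),),                    # tr8  hBCA → ∅
    ((5, -1),),                    # tr9  hBcCcAc → ∅
    ((3, -1),),                    # tr10 olg → ∅
)


def simulate_ssa(
    params: PspParameters,
    m0,
    schedule: StressSchedule,
    options: SimOptions | None = None,
    seed: int = 0,
    tr1_law: str = "mass_action_im",
) -> Trajectory:
    """Exact stochastic simulation (direct method) under the schedule.

    One event record per reaction, plus one record at t=0 and at every
    stress toggle.  If ``options.max_events`` is reached the trajectory
    is returned with ``truncated=True`` and ends at the last event.

    The propensity expressions here are the scalar mirror of
    :func:`pspabc.model.propensities` (kept inline for speed; the test
    suite asserts the two agree).
    """
    opts = options or SimOptions()
    if tr1_law not in ("mass_action_im", "zeroth_order"):
        raise ValueError(f"unknown tr1_law {tr1_law!r}")
    law_im = tr1_law == "mass_action_im"
    rng = np.random.default_rng(seed)
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10 = params.as_array()

    state = [int(v) for v in m0]
    if len(state) != 8 or min(state) < 0:
        raise ValueError("m0 must be 8 non-negative integer counts")
    times: list[float] = []
    records: list[list[int]] = []
    events = 0
    truncated = False
    exponential = rng.exponential
    uniform = rng.random

    for seg_start, seg_end, s in schedule.segments():
        state[0] = s
        times.append(seg_start)
        records.append(state.copy())
        t = seg_start
        while True:
            dm = state[1]
            im = state[2]
            olg = state[3]
            hbca = state[4]
            hbcc = state[5]
            hbcaf = state[6]
            tf = state[7]
            if law_im:
                a1 = k1 * s * im
            else:
                a1 = k1 * s if im > 0 else 0.0
            a2 = k2 * olg if dm > 0 else 0.0
            a3 = k3 * tf
            a4 = k4 * hbca * tf
            a5 = k5 * hbcaf * dm
            a6 = k6 * hbcc * im
            a7 = k7 * hbca * dm
            a8 = k8 * hbca
            a9 = k9 * hbcc
            a10 = k10 * olg
            a0 = a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9 + a10
            if a0 <= 0.0:
                break
            if events >= opts.max_events:
                truncated = True
                break
            dt = exponential() / a0
            if t + dt >= seg_end:
                break  # waiting time resampled after the stress toggle
            t += dt
            r = uniform() * a0
            if r < a1:
                j = 0
            elif r < a1 + a2:
                j = 1
            elif r < a1 + a2 + a3:
                j = 2
            elif r < a1 + a2 + a3 + a4:
                j = 3
            elif r < a1 + a2 + a3 + a4 + a5:
                j = 4
            elif r < a1 + a2 + a3 + a4 + a5 + a6:
                j = 5
            elif r < a1 + a2 + a3 + a4 + a5 + a6 + a7:
                j = 6
            elif r < a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8:
                j = 7
            elif r < a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9:
                j = 8
            else:
                j = 9
            for idx, d in _DELTAS[j]:
                state[idx] += d
            events += 1
            times.append(t)
            records.append(state.copy())
        if truncated:
            break
    if not truncated:
        # the final row keeps the last segment's stress: no toggle event
        # occurs at t_end itself
        times.append(schedule.t_end)
        records.append(state.copy())
    return Trajectory(
        times=np.array(times),
        states=np.array(records, dtype=np.int64),
        framework="stochastic",
        seed=seed,
        truncated=truncated,
    )


def simulate_ode(
    params: PspParameters,
    y0,
    schedule: StressSchedule,
    options: SimOptions | None = None,
    tr1_law: str = "mass_action_im",
) -> Trajectory:
    """Integrate the mass-action ODE piecewise over the stress segments.

    Output is reported on ``options.output_grid`` (default: 401 evenly
    spaced points) merged with the segment boundaries, so the endpoint
    times t1, t2, t3 are always solver output, never interpolation.
    """
    opts = options or SimOptions()
    if tr1_law not in ("mass_action_im", "zeroth_order"):
        raise ValueError(f"unknown tr1_law {tr1_law!r}")
    law_im = tr1_law == "mass_action_im"
    k1, k2, k3, k4, k5, k6, k7, k8, k9, k10 = params.as_array()

    def rhs(t, y):
        # scalar mirror of model.ode_rhs with stress frozen at y[0];
        # the dm>0 repair gate is ramped linearly over [0, _GATE_WIDTH]
        # so the vector field is continuous and the solver does not
        # chatter on the sliding mode at dm = 0
        s, dm, im, olg, hbca, hbcc, hbcaf, tf = y
        if law_im:
            damage = k1 * s * im
        else:
            damage = k1 * s * _gate(100.0 - dm)
        ddm = damage - k2 * olg * _gate(dm)
        bind = k4 * hbca * tf
        breakup = k5 * hbcaf * dm
        relax = k6 * hbcc * im
        conf = k7 * hbca * dm
        return (
            0.0,
            ddm,
            -ddm,
            k3 * tf - k10 * olg,
            10.0 * k3 * tf - bind + relax - conf - k8 * hbca,
            conf + breakup - relax - k9 * hbcc,
            bind - breakup,
            breakup - bind,
        )

    grid = opts.output_grid
    if grid is None:
        grid = np.linspace(0.0, schedule.t_end, 401)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > schedule.t_end):
        raise ValueError("output_grid outside [0, t_end]")

    y = np.asarray(y0, dtype=float).copy()
    if y.shape != (8,) or np.any(y < 0):
        raise ValueError("y0 must be 8 non-negative values")
    out_t: list[float] = []
    out_y: list[np.ndarray] = []
    segments = schedule.segments()
    for si, (a, b, s) in enumerate(segments):
        y[0] = float(s)
        inner = grid[(grid > a) & (grid < b)]
        ts = np.concatenate([[a], inner, [b]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # failures are raised below
            sol, info = odeint(
                rhs,
                y,
                ts,
                rtol=opts.ode_rel_tol,
                atol=opts.ode_abs_tol,
                tfirst=True,
                full_output=True,
                mxstep=100_000,
            )
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"ODE integration failed on segment [{a},{b}): {info['message']}"
            )
        out_t.extend(ts[:-1])
        out_y.extend(sol[:-1])
        y = sol[-1].copy()
        if si == len(segments) - 1:
            out_t.append(ts[-1])
            out_y.append(sol[-1])
    states = np.array(out_y)
    times = np.array(out_t)
    # stress column: the value driving the dynamics at each output time
    # (the final row keeps the last segment's value)
    states[:-1, 0] = [stress_at(schedule, t) for t in times[:-1]]
    return Trajectory(times=times, states=states, framework="deterministic")


def endpoint_states(
    traj: Trajectory, schedule: StressSchedule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """States at the observation times t1, t2, t3.

    Stochastic trajectories use the step-function value in effect at
    each endpoint (state after the last event at or before it);
    deterministic trajectories use solver output (the grid always
    contains the segment boundaries, hence the endpoints).
    """
    if traj.times[-1] < schedule.t3:
        raise ValueError("trajectory does not cover [0, t3]")
    out = []
    for t in (schedule.t1, schedule.t2, schedule.t3):
        if traj.framework == "stochastic":
            i = int(np.searchsorted(traj.times, t, side="right")) - 1
            out.append(traj.states[i].astype(float))
        else:
            i = int(np.searchsorted(traj.times, t))
            if traj.times[i] == t:
                out.append(traj.states[i])
            else:  # fallback for user-supplied grids; linear interpolation
                lo, hi = traj.states[i - 1], traj.states[i]
                w = (t - traj.times[i - 1]) / (traj.times[i] - traj.times[i - 1])
                out.append(lo + w * (hi - lo))
    return tuple(out)  # type: ignore[return-value]


def write_trajectory_tsv(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# framework={traj.framework} seed={traj.seed} truncated={traj.truncated}\n")
        fh.write("time\t" + "\t".join(PLACES) + "\n")
        for t, row in zip(traj.times, traj.states):
            fh.write(f"{t:.10g}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_trajectory_tsv(path) -> Trajectory:
    with open(path) as fh:
        meta = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=", 1) for item in meta)
        fh.readline()  # header
        rows = [[float(x) for x in line.split("\t")] for line in fh if line.strip()]
    arr = np.array(rows)
    seed = None if kv.get("seed") == "None" else int(kv["seed"])
    return Trajectory(
        times=arr[:, 0],
        states=arr[:, 1:],
        framework=kv["framework"],
        seed=seed,
        truncated=kv.get("truncated") == "True",
    )
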