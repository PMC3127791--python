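"""Qualitative end-point data, summary statistics and distances.

No time-resolved measurements of the Psp response exist; what is known
is qualitative and tied to the stress schedule: by the end of the first
stress period (t1) a fraction ``a`` of the membrane is damaged and all
hBCAF complexes have broken up; by the end of the recovery period (t2)
the membrane is repaired and every PspF is back in a complex (no free
TF); renewed stress damages the membrane to the same level by t3.
These five constraints are encoded as a five-component summary/distance
pair with per-component tolerances (see the ABC machinery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .dynamics import SimOptions, Trajectory, endpoint_states, simulate_ode, simulate_ssa
from .model import (
    PspParameters,
    StressSchedule,
    default_schedule,
    initial_marking,
)

__all__ = [
    "EndpointData",
    "make_endpoint_data",
    "summaries",
    "distance",
    "generate_pseudo_data",
    "oscillation_score",
    "noise_profile",
]

#: PspF monomers per hexamer-grouped complex token
MONOMERS_PER_HEXAMER = 6


@dataclass(frozen=True)
class EndpointData:
    """The qualitative endpoint targets for one stress schedule.

    The targets are dm(t1)=a, dm(t2)=0, hBCAF(t1)=0, TF(t2)=0 and
    dm(t3)=a, with ``a`` the percent membrane damage reached by the end
    of the first stress period.  ``true_params`` is set only on
    synthetic (pseudo-) data generated from a known parameter vector,
    for recovery scoring.
    """

    a: float
    schedule: StressSchedule
    true_params: PspParameters | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.a <= 100.0):
            raise ValueError(f"a must be in (0, 100], got {self.a}")


def make_endpoint_data(a: float, schedule: StressSchedule | None = None) -> EndpointData:
    """Endpoint dataset for damage level ``a`` (default schedule if omitted)."""
    return EndpointData(a=float(a), schedule=schedule or default_schedule())


def summaries(traj: Trajectory, data: EndpointData) -> np.ndarray:
    """The five summary statistics of a trajectory.

    S = (dm(t1), dm(t2), 6·hBCAF(t1), 6·TF(t2), dm(t3)): membrane
    damage at the three endpoints plus the complex and free-PspF levels
    counted in PspF-monomer units (six per hexamer token), so that the
    complex components share the 0–120 scale of the tolerance schedule.
    The summaries never depend on ``a`` itself.
    """
    s1, s2, s3 = endpoint_states(traj, data.schedule)
    dm1, dm2, dm3 = s1[1], s2[1], s3[1]
    hbcaf1 = s1[6]
    tf2 = s2[7]
    return np.array(
        [dm1, dm2, MONOMERS_PER_HEXAMER * hbcaf1, MONOMERS_PER_HEXAMER * tf2, dm3]
    )


def distance(s: np.ndarray, data: EndpointData) -> np.ndarray:
    """Five-component distance to the endpoint targets.

    d = (|S1−a|, S2, S3, S4, |S5−a|/a): absolute damage error at t1,
    residual damage at t2, residual complex monomers at t1, residual
    free-PspF monomers at t2, and the *relative* damage error at t3
    (dimensionless, matching the magnitude of its tolerance entries).
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (5,):
        raise ValueError("expected 5 summary statistics")
    if data.a == 0:
        raise ZeroDivisionError("a must be positive for the relative component")
    return np.array(
        [
            abs(s[0] - data.a),
            abs(s[1]),
            s[2],
            s[3],
            abs(s[4] - data.a) / data.a,
        ]
    )


def generate_pseudo_data(
    true_params: PspParameters,
    schedule: StressSchedule | None = None,
    framework: str = "deterministic",
    seed: int = 0,
    tr1_law: str = "mass_action_im",
    options: SimOptions | None = None,
) -> EndpointData:
    """Synthetic endpoint dataset simulated from a known parameter vector.

    Simulates with ``true_params``, sets the damage target ``a`` to the
    simulated dm(t1) rounded to integer percent, and records the truth
    on the returned dataset so recovery experiments can score coverage.
    Raises if the implied ``a`` is zero (no damage, no usable data).
    """
    schedule = schedule or default_schedule()
    if framework == "deterministic":
        traj = simulate_ode(true_params, initial_marking().astype(float), schedule,
                            options, tr1_law=tr1_law)
    elif framework == "stochastic":
        traj = simulate_ssa(true_params, initial_marking(), schedule,
                            options, seed=seed, tr1_law=tr1_law)
    else:
        raise ValueError(f"unknown framework {framework!r}")
    (s1, _, _) = endpoint_states(traj, schedule)
    a = float(round(s1[1]))
    return EndpointData(a=a, schedule=schedule, true_params=true_params)


def oscillation_score(
    traj: Trajectory, species: str, min_prominence: float = 0.05
) -> int:
    """Count prominent local maxima of one species' time course.

    A maximum counts when its prominence exceeds ``min_prominence``
    times the series range; a score of 2 or more flags the trajectory
    as oscillatory for that species.  Flat series score 0.
    """
    y = np.asarray(traj.species(species), dtype=float)
    rng = float(y.max() - y.min())
    if rng == 0.0:
        return 0
    peaks, _ = find_peaks(y, prominence=min_prominence * rng)
    return int(len(peaks))


def noise_profile(
    trajs: list[Trajectory], window: tuple[float, float]
) -> dict[str, float]:
    """Across-replicate coefficient of variation per species.

    For each stochastic replicate the species is time-averaged over
    ``window`` (step-function weighting); the CV (std/mean, ddof=1) is
    taken across replicates.  Species with zero mean are reported as
    NaN and should be excluded from any ranking.
    """
    if len(trajs) < 2:
        raise ValueError("need at least two replicate trajectories")
    lo, hi = window
    if not hi > lo:
        raise ValueError("empty window")
    from .model import PLACES

    means = np.empty((len(trajs), len(PLACES)))
    for i, traj in enumerate(trajs):
        t = traj.times
        x = traj.states.astype(float)
        # step-function time average over [lo, hi]
        edges = np.concatenate([[lo], t[(t > lo) & (t < hi)], [hi]])
        idx = np.searchsorted(t, edges[:-1], side="right") - 1
        widths = np.diff(edges)
        means[i] = (x[idx] * widths[:, None]).sum(axis=0) / (hi - lo)
    mu = means.mean(axis=0)
    sd = means.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mu > 0, sd / mu, np.nan)
    return dict(zip(PLACES, cv))
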