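"""Configuration handling and end-to-end run functions.

Everything the command line (and the analysis drivers) can do is a thin
function here: structural invariant reports, single-trajectory
simulation, the ABC SMC fit, and the synthetic-data parameter-recovery
experiment.  All outputs are plain text (TSV/CSV/JSON) and every run is
reproducible from its config and seed, both of which are recorded in
the manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import invariants as inv
from .dynamics import SimOptions, simulate_ode, simulate_ssa, write_trajectory_tsv
from .model import (
    PspParameters,
    StressSchedule,
    build_simplified_net,
    default_schedule,
    initial_marking,
)
from .qualdata import EndpointData, distance, generate_pseudo_data, make_endpoint_data, summaries
from .smc import (
    PARAM_NAMES,
    Population,
    Prior,
    ToleranceSchedule,
    abc_smc,
    default_prior,
    default_tolerances,
    write_populations_csv,
)

__all__ = [
    "RunConfig",
    "make_distance_fn",
    "run_invariants",
    "run_simulate",
    "run_fit",
    "run_recover",
]


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: model options, schedule, data, prior, ABC settings."""

    schedule: StressSchedule = field(default_factory=default_schedule)
    a: float = 60.0
    tr1_law: str = "mass_action_im"
    unit_mode: str = "counts"
    prior: Prior = field(default_factory=default_prior)
    tolerances: ToleranceSchedule = field(default_factory=default_tolerances)
    n_particles: int = 100
    framework: str = "deterministic"
    seed: int = 0
    params: PspParameters | None = None       # for simulate
    true_params: PspParameters | None = None  # for recover

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "schedule" in raw:
            s = raw["schedule"]
            kwargs["schedule"] = StressSchedule(
                tuple(tuple(iv) for iv in s["on_intervals"]),
                t_end=float(s["t_end"]),
                t1=float(s["t1"]),
                t2=float(s["t2"]),
            )
        if "endpoint" in raw and "a" in raw["endpoint"]:
            kwargs["a"] = float(raw["endpoint"]["a"])
        for key in ("tr1_law", "unit_mode", "framework"):
            if key in raw:
                kwargs[key] = raw[key]
        if "prior" in raw:
            kwargs["prior"] = Prior(
                np.asarray(raw["prior"]["lower"], dtype=float),
                np.asarray(raw["prior"]["upper"], dtype=float),
            )
        if "tolerances" in raw:
            kwargs["tolerances"] = ToleranceSchedule(np.asarray(raw["tolerances"], dtype=float))
        if "n_particles" in raw:
            kwargs["n_particles"] = int(raw["n_particles"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        for key in ("params", "true_params"):
            if key in raw and raw[key] is not None:
                kwargs[key] = PspParameters.from_array(
                    [float(raw[key][name]) for name in PARAM_NAMES],
                    unit_mode=raw.get("unit_mode", "counts"),
                )
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "schedule": {
                "on_intervals": [list(iv) for iv in self.schedule.on_intervals],
                "t_end": self.schedule.t_end,
                "t1": self.schedule.t1,
                "t2": self.schedule.t2,
            },
            "endpoint": {"a": self.a},
            "tr1_law": self.tr1_law,
            "unit_mode": self.unit_mode,
            "framework": self.framework,
            "prior": {"lower": self.prior.lower.tolist(), "upper": self.prior.upper.tolist()},
            "tolerances": self.tolerances.epsilons.tolist(),
            "n_particles": self.n_particles,
            "seed": self.seed,
        }
        for key, p in (("params", self.params), ("true_params", self.true_params)):
            if p is not None:
                out[key] = dict(zip(PARAM_NAMES, p.as_array().tolist()))
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def endpoint_data(self) -> EndpointData:
        return make_endpoint_data(self.a, self.schedule)


#: sparse output grid for fitting runs — the distance needs only the
#: endpoint times, which the piecewise integrator always emits
_FIT_OPTIONS = SimOptions(output_grid=np.empty(0), max_events=200_000)


def make_distance_fn(
    data: EndpointData,
    framework: str = "deterministic",
    tr1_law: str = "mass_action_im",
    options: SimOptions | None = None,
):
    """Build the per-proposal simulate-and-measure callable for ABC.

    Each call runs one fresh simulation at ``theta`` and returns the
    five-component distance to ``data``.  The stochastic framework
    draws its trajectory from the per-particle RNG stream supplied by
    the sampler.
    """
    if framework not in ("deterministic", "stochastic"):
        raise ValueError(f"unknown framework {framework!r}")
    opts = options or _FIT_OPTIONS
    m0 = initial_marking()
    y0 = m0.astype(float)

    def distance_fn(theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        params = PspParameters.from_array(theta)
        if framework == "deterministic":
            try:
                traj = simulate_ode(params, y0, data.schedule, opts, tr1_law=tr1_law)
            except RuntimeError:
                # rare pathological fast oscillators the integrator cannot
                # resolve within its step budget: treat as a rejection
                return np.full(5, np.inf)
        else:
            traj = simulate_ssa(
                params, m0, data.schedule, opts,
                seed=int(rng.integers(2**31)), tr1_law=tr1_law,
            )
            if traj.truncated:
                return np.full(5, np.inf)
        return distance(summaries(traj, data), data)

    return distance_fn


def run_invariants(outdir, seed: int = 0) -> dict:
    """Structural validation: invariant tables, coverage, liveness probe."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net = build_simplified_net()
    p_invs = inv.minimal_p_invariants(net)
    t_invs = inv.minimal_t_invariants(net)
    inv.write_invariants_tsv(p_invs, outdir / "p_invariants.tsv")
    inv.write_invariants_tsv(t_invs, outdir / "t_invariants.tsv")
    covered, uncovered = inv.p_coverage(net, p_invs)
    fired, unfired = inv.l1_liveness_probe(net, initial_marking(), seed=seed)
    summary = {
        "n_p_invariants": len(p_invs),
        "n_t_invariants": len(t_invs),
        "covered_places": sorted(covered),
        "unbounded_places": sorted(uncovered),
        "l1_fired": sorted(fired),
        "l1_unfired": sorted(unfired),
    }
    with open(outdir / "structure_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def run_simulate(config: RunConfig, outdir) -> Path:
    """Simulate one trajectory at ``config.params`` and write it as TSV."""
    if config.params is None:
        raise ValueError("config.params required for simulation")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.framework == "deterministic":
        traj = simulate_ode(
            config.params, initial_marking().astype(float), config.schedule,
            tr1_law=config.tr1_law,
        )
    else:
        traj = simulate_ssa(
            config.params, initial_marking(), config.schedule,
            seed=config.seed, tr1_law=config.tr1_law,
        )
    path = outdir / f"trajectory_{config.framework}.tsv"
    write_trajectory_tsv(traj, path)
    return path


def run_fit(config: RunConfig, outdir) -> list[Population]:
    """ABC SMC fit to the configured endpoint data; writes posteriors,
    a per-particle distance audit table, and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = config.endpoint_data()
    distance_fn = make_distance_fn(data, config.framework, config.tr1_law)
    tic = time.perf_counter()
    populations = abc_smc(
        distance_fn,
        config.prior,
        config.tolerances,
        n_particles=config.n_particles,
        seed=config.seed,
    )
    wall = time.perf_counter() - tic
    write_populations_csv(populations, outdir)
    from .smc import populations_frame

    populations_frame(populations).to_csv(
        outdir / "distance_audit.tsv", sep="\t", index=False
    )
    manifest = {
        "config": config.to_dict(),
        "acceptance_rates": [p.acceptance_rate for p in populations],
        "n_proposals": [p.n_proposals for p in populations],
        "wall_clock_s": wall,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return populations


def run_recover(config: RunConfig, outdir) -> dict:
    """Parameter-recovery experiment on synthetic endpoint data.

    Generates pseudo-data from ``config.true_params``, fits it with the
    configured ABC settings, and reports each parameter's weighted
    5–95% posterior interval together with whether the truth lies
    inside.
    """
    if config.true_params is None:
        raise ValueError("config.true_params required for recovery")
    if not config.prior.contains(config.true_params.as_array()):
        raise ValueError("true parameters lie outside the prior support")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = generate_pseudo_data(
        config.true_params, config.schedule, config.framework,
        seed=config.seed, tr1_law=config.tr1_law,
    )
    fit_config = RunConfig(
        schedule=config.schedule,
        a=data.a,
        tr1_law=config.tr1_law,
        prior=config.prior,
        tolerances=config.tolerances,
        n_particles=config.n_particles,
        framework=config.framework,
        seed=config.seed,
    )
    populations = run_fit(fit_config, outdir)
    final = populations[-1]
    truth = config.true_params.as_array()
    report: dict = {"a": data.a, "parameters": {}}
    for i, name in enumerate(PARAM_NAMES):
        lo, hi = final.weighted_quantile([0.05, 0.95], i)
        report["parameters"][name] = {
            "truth": float(truth[i]),
            "q05": float(lo),
            "q95": float(hi),
            "inside": bool(lo <= truth[i] <= hi),
        }
    with open(outdir / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
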