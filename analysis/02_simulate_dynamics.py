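"""Example stochastic and deterministic trajectories.

Simulates the simplified Psp model under the default stress schedule
(stress on over [0,10) and [30,40)) at an illustrative parameter set
that reproduces the qualitative endpoint behaviour, in both frameworks,
and writes the trajectories as TSV under results/trajectories/.
"""

from dataclasses import replace
from pathlib import Path

from pspabc.model import PspParameters
from pspabc.workflows import RunConfig, run_simulate

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "trajectories"

#: a parameter set satisfying the a=69 endpoint data (strong damage and
#: repair, slow transcription, fast complex turnover)
EXAMPLE_PARAMS = PspParameters.from_array(
    [0.7, 90.0, 0.02, 0.2, 0.012, 0.002, 0.01, 1.0, 0.9, 1.4]
)


def main() -> None:
    config = RunConfig(params=EXAMPLE_PARAMS, seed=11)
    for framework in ("deterministic", "stochastic"):
        path = run_simulate(replace(config, framework=framework), OUTDIR)
        print(f"wrote {path}")


if __name__ == "__main__":
    main()
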