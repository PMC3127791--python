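"""The simplified Psp stress-response model.

The phage shock protein (Psp) response lets *E. coli* react to inner-
membrane damage (phage infection, proton ionophores, heat): damage
dissipates the proton motive force, the PspB–PspC–PspA–PspF complex
breaks up, freed PspF hexamers act as a σ54 transcription factor, and
newly made PspA 36-mer oligomers repair the membrane — a negative
feedback on the stress signal.

The model tracks eight state variables::

    stress   external stress condition, 0/1 (never consumed: test arc)
    dm, im   percent damaged / intact membrane, dm + im = 100
    olg      PspA 36-mer oligomers (membrane-repair effector)
    hBCA     PspB-PspC-PspA complexes, grouped in hexamer units
    hBcCcAc  the same complexes in the stress-induced conformation
    hBCAF    hexamer complexes bound to PspF
    TF       free PspF hexamers (transcription factor)

and ten transitions tr1..tr10 with mass-action, marking-dependent
rates k1..k10::

    tr1   im → dm            [test: stress]   membrane damage
    tr2   dm → im            [test: olg]      oligomer-driven repair
    tr3   ∅ → 10·hBCA + olg  [test: TF]       transcription + translation
    tr4   hBCA + TF → hBCAF                   PspF sequestration
    tr5   hBCAF → hBcCcAc + TF  [test: dm]    complex break-up under damage
    tr6   hBcCcAc → hBCA     [test: im]       conformational relaxation
    tr7   hBCA → hBcCcAc     [test: dm]       conformational change
    tr8   hBCA → ∅                            degradation
    tr9   hBcCcAc → ∅                         degradation
    tr10  olg → ∅                             degradation

tr3 produces ten hexamer-grouped BCA complexes and one oligomer per
firing, reflecting the measured 100:60:40 PspA:PspB:PspC production
ratio with complexes grouped in sixes (60 BCA = 10 hexamer units; the
remaining ~40 PspA ≈ one 36-mer oligomer).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .petri import PetriNet

__all__ = [
    "PLACES",
    "TRANSITIONS",
    "PspParameters",
    "StressSchedule",
    "UnitContext",
    "build_simplified_net",
    "initial_marking",
    "propensities",
    "ode_rhs",
    "stress_at",
    "det_to_stoch_rate",
    "molecules_to_concentration",
    "concentration_to_molecules",
    "default_schedule",
    "alternative_schedule",
]

PLACES = ("stress", "dm", "im", "olg", "hBCA", "hBcCcAc", "hBCAF", "TF")
TRANSITIONS = tuple(f"tr{i}" for i in range(1, 11))

#: total membrane percentage and total PspF hexamers at the start
MEMBRANE_TOTAL = 100
PSPF_TOTAL = 20


@dataclass(frozen=True)
class PspParameters:
    """Rate constants k1..k10 (per arbitrary time unit).

    ``k4`` is additionally per count (counts mode) or per molar (molar
    mode); all other reactions are effectively first order in a single
    species (possibly modulated by a read-only marking factor).
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    unit_mode: str = "counts"

    def __post_init__(self) -> None:
        if self.unit_mode not in ("counts", "molar"):
            raise ValueError(f"unknown unit_mode {self.unit_mode!r}")
        for i, k in enumerate(self.as_array(), start=1):
            if k < 0:
                raise ValueError(f"k{i} must be non-negative, got {k}")

    @classmethod
    def from_array(cls, ks: Sequence[float], unit_mode: str = "counts") -> "PspParameters":
        ks = list(map(float, ks))
        if len(ks) != 10:
            raise ValueError("expected 10 rate constants")
        return cls(*ks, unit_mode=unit_mode)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k2, self.k3, self.k4, self.k5,
             self.k6, self.k7, self.k8, self.k9, self.k10]
        )

    @classmethod
    def zeros(cls) -> "PspParameters":
        return cls.from_array([0.0] * 10)


@dataclass(frozen=True)
class StressSchedule:
    """Piecewise-constant stress input and the endpoint observation times.

    ``on_intervals`` are disjoint, ordered, half-open ``[start, end)``
    windows inside ``[0, t_end)`` during which stress is applied.  ``t1``
    is the end of the first stress period, ``t2`` the end of the
    recovery period, ``t3 = t_end`` the end of the run.
    """

    on_intervals: tuple[tuple[float, float], ...]
    t_end: float
    t1: float
    t2: float

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b)) for a, b in self.on_intervals)
        object.__setattr__(self, "on_intervals", ivs)
        last = 0.0
        for a, b in ivs:
            if not (0.0 <= a < b <= self.t_end):
                raise ValueError(f"interval [{a},{b}) outside [0,{self.t_end})")
            if a < last:
                raise ValueError("stress intervals must be ordered and disjoint")
            last = b
        if not (0 < self.t1 < self.t2 <= self.t_end):
            raise ValueError("need 0 < t1 < t2 <= t3 = t_end")

    @property
    def t3(self) -> float:
        return self.t_end

    def boundaries(self) -> list[float]:
        """Sorted toggle times, including 0 and t_end."""
        pts = {0.0, self.t_end}
        for a, b in self.on_intervals:
            pts.add(a)
            if b < self.t_end:
                pts.add(b)
        return sorted(pts)

    def segments(self) -> list[tuple[float, float, int]]:
        """Constant-stress segments ``(start, end, stress)`` covering [0, t_end]."""
        pts = self.boundaries()
        return [
            (a, b, stress_at(self, a)) for a, b in zip(pts[:-1], pts[1:])
        ]


def default_schedule() -> StressSchedule:
    """Stress on over [0,10) and [30,40), off over [10,30)."""
    return StressSchedule(((0.0, 10.0), (30.0, 40.0)), t_end=40.0, t1=10.0, t2=30.0)


def alternative_schedule() -> StressSchedule:
    """Stress on over [0,20) and [30,50), off over [20,30)."""
    return StressSchedule(((0.0, 20.0), (30.0, 50.0)), t_end=50.0, t1=20.0, t2=30.0)


def stress_at(schedule: StressSchedule, t: float) -> int:
    """Stress indicator at time ``t`` (half-open interval convention)."""
    if not (0.0 <= t <= schedule.t_end):
        raise ValueError(f"t={t} outside [0, {schedule.t_end}]")
    for a, b in schedule.on_intervals:
        if a <= t < b:
            return 1
    return 0


@dataclass(frozen=True)
class UnitContext:
    """Molecule-count ↔ molar-concentration conversion context.

    With an *E. coli* volume of 1 μm³ = 1e-15 l, a concentration ``y``
    (M) corresponds to ``n_A · y · V`` molecules.  In counts mode the
    scale factor is 1 and stochastic and deterministic rate constants
    coincide for every reaction order.
    """

    volume: float = 1e-15
    avogadro: float = 6.02e23
    mode: str = "counts"

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.mode not in ("counts", "molar"):
            raise ValueError(f"unknown unit mode {self.mode!r}")

    @property
    def nav(self) -> float:
        """n_A·V, molecules per molar unit (1 in counts mode)."""
        return 1.0 if self.mode == "counts" else self.avogadro * self.volume


def det_to_stoch_rate(k: float, order: int, ctx: UnitContext = UnitContext()) -> float:
    """Convert a deterministic rate constant to a stochastic one.

    First order: c = k.  Second order (X+Y→Z): c = k/(n_A·V).  Zeroth
    order (∅→X): c = k·n_A·V.  In counts mode all three coincide.
    """
    if k < 0:
        raise ValueError("rate must be non-negative")
    if order == 1:
        return k
    if order == 2:
        return k / ctx.nav
    if order == 0:
        return k * ctx.nav
    raise ValueError(f"unsupported reaction order {order}")


def molecules_to_concentration(m: float, ctx: UnitContext = UnitContext(mode="molar")) -> float:
    """Concentration y = m/(n_A·V) for a molecule count m."""
    if m < 0:
        raise ValueError("molecule count must be non-negative")
    return m / ctx.nav


def concentration_to_molecules(y: float, ctx: UnitContext = UnitContext(mode="molar")) -> float:
    """Molecule count m = n_A·y·V for a concentration y."""
    return y * ctx.nav


# place indices, used throughout the hot paths
_STRESS, _DM, _IM, _OLG, _HBCA, _HBCACC, _HBCAF, _TF = range(8)


def build_simplified_net() -> PetriNet:
    """Construct the simplified Psp Petri net (8 places, 10 transitions)."""
    m = len(TRANSITIONS)
    n = len(PLACES)
    pre = np.zeros((m, n), dtype=np.int64)
    post = np.zeros((m, n), dtype=np.int64)
    test = np.zeros((m, n), dtype=np.int64)

    def t(name: str) -> int:
        return TRANSITIONS.index(name)

    pre[t("tr1"), _IM] = 1
    post[t("tr1"), _DM] = 1
    test[t("tr1"), _STRESS] = 1

    pre[t("tr2"), _DM] = 1
    post[t("tr2"), _IM] = 1
    test[t("tr2"), _OLG] = 1

    post[t("tr3"), _HBCA] = 10
    post[t("tr3"), _OLG] = 1
    test[t("tr3"), _TF] = 1

    pre[t("tr4"), _HBCA] = 1
    pre[t("tr4"), _TF] = 1
    post[t("tr4"), _HBCAF] = 1

    pre[t("tr5"), _HBCAF] = 1
    post[t("tr5"), _HBCACC] = 1
    post[t("tr5"), _TF] = 1
    test[t("tr5"), _DM] = 1

    pre[t("tr6"), _HBCACC] = 1
    post[t("tr6"), _HBCA] = 1
    test[t("tr6"), _IM] = 1

    pre[t("tr7"), _HBCA] = 1
    post[t("tr7"), _HBCACC] = 1
    test[t("tr7"), _DM] = 1

    pre[t("tr8"), _HBCA] = 1
    pre[t("tr9"), _HBCACC] = 1
    pre[t("tr10"), _OLG] = 1

    return PetriNet(PLACES, TRANSITIONS, pre, post, test)


def initial_marking() -> np.ndarray:
    """M0 = (stress, dm, im, olg, hBCA, hBcCcAc, hBCAF, TF) = (1,0,100,0,0,0,20,0).

    Stress on, membrane intact, all PspF bound in hBCAF complexes.
    This marking makes every transition L1-fireable.
    """
    return np.array([1, 0, MEMBRANE_TOTAL, 0, 0, 0, PSPF_TOTAL, 0], dtype=np.int64)


def propensities(
    state: Sequence[float],
    params: PspParameters,
    tr1_law: str = "mass_action_im",
) -> np.ndarray:
    """Marking-dependent transition rates a(tr1)..a(tr10) at ``state``.

    Damage-driven steps (tr5, tr7) scale with the damaged fraction dm;
    repair (tr2) scales with the oligomer count and is gated at dm = 0;
    relaxation (tr6) scales with the intact fraction im.  With the
    default ``tr1_law`` the damage rate is first order in the intact
    membrane, ``k1·stress·im``; the ``"zeroth_order"`` variant uses a
    constant ``k1·stress`` while any membrane remains intact.
    """
    y = np.asarray(state, dtype=float)
    if np.any(y < 0):
        raise ValueError("negative state component")
    s, dm, im, olg, hbca, hbcc, hbcaf, tf = y
    if tr1_law == "mass_action_im":
        a1 = params.k1 * s * im
    elif tr1_law == "zeroth_order":
        a1 = params.k1 * s * (1.0 if im > 0 else 0.0)
    else:
        raise ValueError(f"unknown tr1_law {tr1_law!r}")
    return np.array(
        [
            a1,
            params.k2 * olg if dm > 0 else 0.0,
            params.k3 * tf,
            params.k4 * hbca * tf,
            params.k5 * hbcaf * dm,
            params.k6 * hbcc * im,
            params.k7 * hbca * dm,
            params.k8 * hbca,
            params.k9 * hbcc,
            params.k10 * olg,
        ]
    )


def ode_rhs(
    t: float,
    y: Sequence[float],
    params: PspParameters,
    schedule: StressSchedule | None = None,
    tr1_law: str = "mass_action_im",
) -> np.ndarray:
    """Mass-action ODE right-hand side (mean field of the stochastic net).

    The stress input is read from ``schedule`` when given, otherwise
    from ``y[0]`` (the piecewise integrator sets y[0] per segment and
    passes ``schedule=None`` so segment-boundary evaluations stay
    consistent).  dstress/dt is always 0: stress only changes through
    the external schedule.  dm+im and hBCAF+TF are conserved exactly.
    """
    from .dynamics import _gate  # shared indicator regularization

    s_, dm, im, olg, hbca, hbcc, hbcaf, tf = (float(v) for v in y)
    s = float(stress_at(schedule, t)) if schedule is not None else s_
    if tr1_law == "mass_action_im":
        damage = params.k1 * s * im
    elif tr1_law == "zeroth_order":
        damage = params.k1 * s * _gate(MEMBRANE_TOTAL - dm)
    else:
        raise ValueError(f"unknown tr1_law {tr1_law!r}")
    repair = params.k2 * olg * _gate(dm)
    ddm = damage - repair
    bind = params.k4 * hbca * tf
    breakup = params.k5 * hbcaf * dm
    relax = params.k6 * hbcc * im
    conf = params.k7 * hbca * dm
    return np.array(
        [
            0.0,
            ddm,
            -ddm,
            params.k3 * tf - params.k10 * olg,
            10.0 * params.k3 * tf - bind + relax - conf - params.k8 * hbca,
            conf + breakup - relax - params.k9 * hbcc,
            bind - breakup,
            breakup - bind,
        ]
    )
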