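"""Minimal P- and T-invariants and structural diagnostics.

A P-invariant is a non-zero, non-negative integer vector ``y`` over the
places with ``A y = 0`` (``A`` the incidence matrix, transitions ×
places): the weighted token sum ``y·M`` is conserved along every firing
sequence.  A T-invariant is a non-negative ``x`` over the transitions
with ``Aᵀ x = 0``: firing each transition ``x_t`` times returns the net
to its starting marking.  The *minimal* (support-minimal, gcd-reduced)
semi-positive invariants generate all others and are computed here with
the classical positive-combination elimination scheme of Martinez and
Silva, in exact integer arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .petri import PetriNet, enabled, fire, incidence

__all__ = [
    "InvariantSet",
    "minimal_p_invariants",
    "minimal_t_invariants",
    "minimal_semiflows",
    "p_coverage",
    "l1_liveness_probe",
    "write_invariants_tsv",
    "read_invariants_tsv",
]


@dataclass(frozen=True)
class InvariantSet:
    """A set of minimal semi-positive invariants.

    ``kind`` is ``"P"`` (vectors over places) or ``"T"`` (over
    transitions); ``names`` gives the column labels; ``vectors`` is an
    integer array with one invariant per row, canonically ordered.
    """

    kind: str
    names: tuple[str, ...]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "vectors", np.asarray(self.vectors, dtype=np.int64))

    def __len__(self) -> int:
        return len(self.vectors)

    def supports(self) -> list[tuple[str, ...]]:
        """The support (names with non-zero weight) of each invariant."""
        return [
            tuple(n for n, v in zip(self.names, vec) if v)
            for vec in self.vectors
        ]

    def find_support(self, names: Sequence[str]) -> np.ndarray:
        """Return the unique invariant whose support is exactly ``names``."""
        want = set(names)
        for vec in self.vectors:
            if {n for n, v in zip(self.names, vec) if v} == want:
                return vec
        raise KeyError(f"no invariant with support {sorted(want)}")


def _gcd_reduce(v: np.ndarray) -> np.ndarray:
    g = math.gcd(*(int(x) for x in v)) if np.any(v) else 1
    return v // max(g, 1)


def _prune(rows: list[np.ndarray], start: int) -> list[np.ndarray]:
    """Drop exact duplicates and rows whose candidate support (columns
    from ``start`` on) strictly contains another row's support.

    Deleting strict-superset supports at intermediate steps is the
    classical Martinez–Silva refinement: no minimal semiflow is ever a
    positive combination involving such a row.
    """
    supports = [frozenset(np.flatnonzero(r[start:])) for r in rows]
    keep: list[np.ndarray] = []
    for i, s in enumerate(supports):
        minimal = True
        for j, t in enumerate(supports):
            if i == j:
                continue
            if t < s:
                minimal = False
                break
            if t == s and j < i and np.array_equal(rows[i], rows[j]):
                minimal = False
                break
        if minimal:
            keep.append(rows[i])
    return keep


def minimal_semiflows(matrix: np.ndarray) -> np.ndarray:
    """Minimal semi-positive integer solutions of ``matrix · v = 0``.

    ``matrix`` has one row per constraint and one column per component of
    ``v``.  Constraints are eliminated one at a time by forming all
    positive combinations of candidate rows with opposite residual signs
    (Farkas / Martinez–Silva); candidates whose support strictly contains
    another's are pruned after every elimination.  Arithmetic is exact
    (int64 with gcd reduction after every combination).
    """
    m = np.asarray(matrix, dtype=np.int64)
    n_constraints, n = m.shape
    # tableau row j = [residual matrix·e_j | e_j]: candidate v in the
    # right block, its constraint residual in the left block
    eye = np.eye(n, dtype=np.int64)
    rows = [np.concatenate([m[:, j], eye[j]]) for j in range(n)]
    for c in range(n_constraints):
        pos = [r for r in rows if r[c] > 0]
        neg = [r for r in rows if r[c] < 0]
        zero = [r for r in rows if r[c] == 0]
        new = []
        for rp in pos:
            for rn in neg:
                comb = _gcd_reduce((-rn[c]) * rp + rp[c] * rn)
                new.append(comb)
        rows = _prune(zero + new, start=n_constraints)
    out = [_gcd_reduce(r[n_constraints:]) for r in rows]
    out = [r for r in out if np.any(r)]
    out = _prune(out, start=0)
    # canonical order: lexicographic by support indices, then by weights
    out.sort(key=lambda r: (tuple(np.flatnonzero(r)), tuple(r)))
    return np.array(out, dtype=np.int64) if out else np.empty((0, n), dtype=np.int64)


def minimal_p_invariants(net: PetriNet) -> InvariantSet:
    """Minimal conservation laws: semi-positive ``y`` with ``A y = 0``."""
    a = incidence(net)  # rows: transitions (constraints), cols: places
    return InvariantSet("P", net.places, minimal_semiflows(a))


def minimal_t_invariants(net: PetriNet) -> InvariantSet:
    """Minimal reproduction cycles: semi-positive ``x`` with ``Aᵀ x = 0``."""
    a = incidence(net)
    return InvariantSet("T", net.transitions, minimal_semiflows(a.T))


def p_coverage(net: PetriNet, invs: InvariantSet) -> tuple[set[str], set[str]]:
    """Split places into (covered, uncovered) by the P-invariant supports.

    A place outside every P-invariant support has no conservation law
    bounding it: the net is structurally unbounded there.
    """
    if invs.kind != "P":
        raise ValueError(f"expected P-invariants, got kind {invs.kind!r}")
    covered = {n for sup in invs.supports() for n in sup}
    return covered, set(net.places) - covered


def l1_liveness_probe(
    net: PetriNet,
    m0: Sequence[int],
    max_events: int = 1000,
    n_trials: int = 20,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """Randomized probe for L1-liveness (every transition fireable once).

    Runs ``n_trials`` firing sequences of at most ``max_events`` events,
    choosing uniformly among enabled transitions.  A transition in the
    returned ``fired`` set is proven L1-fireable from ``m0``; membership
    in ``unfired`` is evidence of deadness, not proof.
    """
    if max_events < 1 or n_trials < 1:
        raise ValueError("max_events and n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    fired: set[str] = set()
    for _ in range(n_trials):
        m = np.asarray(m0, dtype=np.int64)
        for _ in range(max_events):
            en = sorted(enabled(net, m))
            if not en:
                break
            tr = en[rng.integers(len(en))]
            m = fire(net, m, tr)
            fired.add(tr)
        if len(fired) == net.n_transitions:
            break
    return fired, set(net.transitions) - fired


def write_invariants_tsv(invs: InvariantSet, path) -> None:
    """One row per invariant, columns = place/transition names (table layout)."""
    with open(path, "w") as fh:
        fh.write("\t".join(invs.names) + "\n")
        for vec in invs.vectors:
            fh.write("\t".join(str(int(v)) for v in vec) + "\n")


def read_invariants_tsv(path, kind: str) -> InvariantSet:
    with open(path) as fh:
        names = tuple(fh.readline().rstrip("\n").split("\t"))
        vectors = [
            [int(x) for x in line.rstrip("\n").split("\t")]
            for line in fh
            if line.strip()
        ]
    arr = np.array(vectors, dtype=np.int64) if vectors else np.empty((0, len(names)), dtype=np.int64)
    return InvariantSet(kind, names, arr)
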