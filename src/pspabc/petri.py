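"""Place/transition Petri nets with test (read) arcs.

A Petri net is a bipartite graph of places (molecular species or
conditions, holding integer tokens) and transitions (reactions).  Arc
weights are collected in two non-negative integer matrices ``pre``
(consumption) and ``post`` (production), one row per transition and one
column per place.  Test arcs — read-only dependencies that condition a
transition's enabling and rate on a place without moving its tokens —
live in a third matrix ``test`` so that they never contribute to the
incidence matrix and therefore never distort conservation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PetriNet",
    "incidence",
    "enabled",
    "fire",
    "validate",
    "write_pnml",
    "read_pnml",
]


@dataclass(frozen=True)
class PetriNet:
    """An ordinary Petri net extended with test arcs.

    Parameters
    ----------
    places, transitions
        Unique names, in canonical order.  Matrix columns follow
        ``places``; matrix rows follow ``transitions``.
    pre, post, test
        Integer weight matrices of shape ``(len(transitions), len(places))``.
        ``test`` defaults to all zeros.
    """

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    pre: np.ndarray
    post: np.ndarray
    test: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "places", tuple(self.places))
        object.__setattr__(self, "transitions", tuple(self.transitions))
        object.__setattr__(self, "pre", np.asarray(self.pre, dtype=np.int64))
        object.__setattr__(self, "post", np.asarray(self.post, dtype=np.int64))
        test = self.test
        if test is None:
            test = np.zeros_like(self.pre)
        object.__setattr__(self, "test", np.asarray(test, dtype=np.int64))

    @property
    def n_places(self) -> int:
        return len(self.places)

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def place_index(self, name: str) -> int:
        return self.places.index(name)

    def transition_index(self, name: str) -> int:
        return self.transitions.index(name)

    # convenience method mirrors of the module-level operations
    def incidence(self) -> np.ndarray:
        return incidence(self)

    def enabled(self, marking: Sequence[int]) -> set[str]:
        return enabled(self, marking)

    def fire(self, marking: Sequence[int], transition: str) -> np.ndarray:
        return fire(self, marking, transition)

    def validate(self) -> list[str]:
        return validate(self)


def _as_marking(net: PetriNet, marking: Sequence[int]) -> np.ndarray:
    m = np.asarray(marking, dtype=np.int64)
    if m.shape != (net.n_places,):
        raise ValueError(
            f"marking has shape {m.shape}, expected ({net.n_places},)"
        )
    return m


def incidence(net: PetriNet) -> np.ndarray:
    """Incidence matrix A = post − pre (transitions × places).

    Test arcs contribute nothing: a read dependency moves no tokens, so
    it must not appear in the net's conservation structure.
    """
    return net.post - net.pre


def enabled(net: PetriNet, marking: Sequence[int]) -> set[str]:
    """Names of transitions enabled at ``marking``.

    A transition is enabled iff the marking dominates both its ``pre``
    row (tokens to consume) and its ``test`` row (tokens to read),
    component-wise.
    """
    m = _as_marking(net, marking)
    ok = np.all(m >= net.pre, axis=1) & np.all(m >= net.test, axis=1)
    return {net.transitions[i] for i in np.flatnonzero(ok)}


def fire(net: PetriNet, marking: Sequence[int], transition: str) -> np.ndarray:
    """Fire ``transition`` at ``marking`` and return the new marking.

    Raises ``RuntimeError`` if the transition is not enabled.  Places
    touched only by test arcs are left unchanged.
    """
    m = _as_marking(net, marking)
    i = net.transition_index(transition)
    if np.any(m < net.pre[i]) or np.any(m < net.test[i]):
        raise RuntimeError(f"transition {transition!r} is not enabled")
    return m - net.pre[i] + net.post[i]


def validate(net: PetriNet) -> list[str]:
    """Structural well-formedness check; returns a list of violations."""
    violations: list[str] = []
    if len(set(net.places)) != len(net.places):
        violations.append("duplicate place names")
    if len(set(net.transitions)) != len(net.transitions):
        violations.append("duplicate transition names")
    shape = (net.n_transitions, net.n_places)
    for name, mat in (("pre", net.pre), ("post", net.post), ("test", net.test)):
        if mat.shape != shape:
            violations.append(f"{name} has shape {mat.shape}, expected {shape}")
            continue
        if not np.issubdtype(mat.dtype, np.integer):
            violations.append(f"{name} is not integer-valued")
        bad = np.argwhere(mat < 0)
        for row, col in bad:
            violations.append(f"{name}[{row},{col}] is negative")
    return violations


# --------------------------------------------------------------------------
# PNML serialization.  Ordinary arcs follow the PNML core model; test arcs
# are written as arcs carrying a <toolspecific tool="pspabc"> element with
# <arctype>read</arctype>, so standard tools see them as plain arcs while
# this package round-trips them exactly.
# --------------------------------------------------------------------------

import xml.etree.ElementTree as _ET

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


def write_pnml(net: PetriNet, path, marking: Sequence[int] | None = None) -> None:
    """Write the net (and optionally an initial marking) as PNML."""
    root = _ET.Element("pnml", xmlns=_PNML_NS)
    netel = _ET.SubElement(root, "net", id="net0", type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = _ET.SubElement(netel, "page", id="page0")
    m = None if marking is None else _as_marking(net, marking)
    for j, p in enumerate(net.places):
        pel = _ET.SubElement(page, "place", id=p)
        name = _ET.SubElement(pel, "name")
        _ET.SubElement(name, "text").text = p
        if m is not None and m[j] > 0:
            im = _ET.SubElement(pel, "initialMarking")
            _ET.SubElement(im, "text").text = str(int(m[j]))
    for t in net.transitions:
        tel = _ET.SubElement(page, "transition", id=t)
        name = _ET.SubElement(tel, "name")
        _ET.SubElement(name, "text").text = t
    arc_id = 0

    def _arc(src: str, dst: str, w: int, read: bool = False) -> None:
        nonlocal arc_id
        ael = _ET.SubElement(page, "arc", id=f"a{arc_id}", source=src, target=dst)
        arc_id += 1
        if w != 1:
            ins = _ET.SubElement(ael, "inscription")
            _ET.SubElement(ins, "text").text = str(int(w))
        if read:
            ts = _ET.SubElement(ael, "toolspecific", tool="pspabc", version="1")
            _ET.SubElement(ts, "arctype").text = "read"

    for i, t in enumerate(net.transitions):
        for j, p in enumerate(net.places):
            if net.pre[i, j]:
                _arc(p, t, net.pre[i, j])
            if net.post[i, j]:
                _arc(t, p, net.post[i, j])
            if net.test[i, j]:
                _arc(p, t, net.test[i, j], read=True)
    _ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def read_pnml(path) -> tuple[PetriNet, np.ndarray]:
    """Read a PNML file written by :func:`write_pnml`.

    Returns the net and the initial marking (zeros where absent).
    """
    tree = _ET.parse(path)
    ns = {"p": _PNML_NS}

    def findall(tag: str):
        out = tree.getroot().findall(f".//p:{tag}", ns)
        return out if out else tree.getroot().findall(f".//{tag}")

    places = [el.get("id") for el in findall("place")]
    transitions = [el.get("id") for el in findall("transition")]
    pidx = {p: j for j, p in enumerate(places)}
    tidx = {t: i for i, t in enumerate(transitions)}
    pre = np.zeros((len(transitions), len(places)), dtype=np.int64)
    post = np.zeros_like(pre)
    test = np.zeros_like(pre)
    marking = np.zeros(len(places), dtype=np.int64)
    for el in findall("place"):
        im = el.find("p:initialMarking/p:text", ns)
        if im is None:
            im = el.find("initialMarking/text")
        if im is not None:
            marking[pidx[el.get("id")]] = int(im.text)
    for el in findall("arc"):
        src, dst = el.get("source"), el.get("target")
        ins = el.find("p:inscription/p:text", ns)
        if ins is None:
            ins = el.find("inscription/text")
        w = int(ins.text) if ins is not None else 1
        ts = el.find("p:toolspecific", ns)
        if ts is None:
            ts = el.find("toolspecific")
        is_read = False
        if ts is not None and ts.get("tool") == "pspabc":
            at = ts.find("p:arctype", ns)
            if at is None:
                at = ts.find("arctype")
            is_read = at is not None and at.text == "read"
        if src in pidx:  # place → transition
            if is_read:
                test[tidx[dst], pidx[src]] = w
            else:
                pre[tidx[dst], pidx[src]] = w
        else:  # transition → place
            post[tidx[src], pidx[dst]] = w
    return PetriNet(tuple(places), tuple(transitions), pre, post, test), marking
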