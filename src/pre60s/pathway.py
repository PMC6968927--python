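"""Qualitative dependency model of cytoplasmic pre-60S maturation.

The pathway is encoded as a directed acyclic graph of discrete events —
``release(factor)``, ``recruit(factor)`` and ``load(r-protein)`` — where an
event can fire only after all of its prerequisite events have fired.
Dominant-negative perturbations (an ATPase- or GTPase-dead enzyme) disable
specific blockable events; the composition of the trapped particle is then
predicted by a reachability closure:

* a factor **accumulates** if it is pre-loaded (or its recruitment is
  reachable) but its release is unreachable;
* a factor is **not recruited** if its recruitment (or loading) event is
  unreachable.

There are no rates and no stochastic timing — the model is purely
qualitative, mirroring how such pathways are drawn. The default graph is
shipped as an editable YAML file (``pre60s/data/pathway.yaml``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
import yaml


@dataclass(frozen=True)
class Event:
    name: str
    factor: str
    kind: str  # "release" | "recruit" | "load"
    requires: tuple[str, ...] = ()
    blockable: str | None = None
    inferred: bool = False


@dataclass(frozen=True)
class MaturationGraph:
    """Event-dependency graph with pre-loaded factors and block handles."""

    events: dict[str, Event]
    preloaded: frozenset[str]
    core_factors: frozenset[str]
    perturbations: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ev in self.events.values():
            for req in ev.requires:
                if req not in self.events:
                    raise ValueError(
                        f"event {ev.name!r} requires unknown event {req!r}"
                    )
            if ev.kind not in ("release", "recruit", "load"):
                raise ValueError(f"unknown event kind {ev.kind!r}")
        for factor in self.factors:
            for kind in ("release", "recruit"):
                n = sum(
                    1
                    for ev in self.events.values()
                    if ev.factor == factor and ev.kind == kind
                )
                if n > 1:
                    raise ValueError(
                        f"factor {factor!r} has {n} {kind} events; at most one allowed"
                    )
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("dependency graph contains a cycle")

    # -- structure ---------------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        """Edges point prerequisite -> dependent event."""
        g = nx.DiGraph()
        g.add_nodes_from(self.events)
        for ev in self.events.values():
            for req in ev.requires:
                g.add_edge(req, ev.name)
        return g

    @property
    def factors(self) -> frozenset[str]:
        return frozenset(ev.factor for ev in self.events.values()) | self.preloaded

    @property
    def blockable(self) -> frozenset[str]:
        return frozenset(
            ev.name for ev in self.events.values() if ev.blockable is not None
        )

    def event_of(self, factor: str, kind: str) -> Event | None:
        for ev in self.events.values():
            if ev.factor == factor and ev.kind == kind:
                return ev
        return None

    def resolve_blocks(self, blocked: set[str] | str) -> frozenset[str]:
        """Map event names and/or perturbation labels to blocked events."""
        if isinstance(blocked, str):
            blocked = {blocked}
        out: set[str] = set()
        for label in blocked:
            if label in self.perturbations:
                out.update(self.perturbations[label])
            elif label in self.events:
                if label not in self.blockable:
                    raise ValueError(f"event {label!r} is not blockable")
                out.add(label)
            else:
                raise ValueError(f"unknown block label {label!r}")
        return frozenset(out)

    # -- reachability ------------------------------------------------------

    def reachable(self, blocked: frozenset[str]) -> frozenset[str]:
        """Events that can still fire with ``blocked`` disabled.

        An event is reachable iff it is not blocked and all of its
        prerequisites are reachable (evaluated in topological order).
        """
        order = nx.topological_sort(self.to_networkx())
        ok: set[str] = set()
        for name in order:
            ev = self.events[name]
            if name in blocked:
                continue
            if all(req in ok for req in ev.requires):
                ok.add(name)
        return frozenset(ok)


@dataclass(frozen=True)
class TrapPrediction:
    """Predicted trapped-particle composition under a set of blocks.

    ``accumulated`` and ``not_recruited`` are disjoint by construction.
    """

    blocked: frozenset[str]
    accumulated: frozenset[str]
    not_recruited: frozenset[str]

    def restricted(self, factors: frozenset[str]) -> "TrapPrediction":
        return TrapPrediction(
            blocked=self.blocked,
            accumulated=self.accumulated & factors,
            not_recruited=self.not_recruited & factors,
        )


def load_graph(path) -> MaturationGraph:
    """Load a maturation graph from a structured YAML file."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    events = {}
    for e in spec.get("events", []):
        ev = Event(
            name=e["name"],
            factor=e["factor"],
            kind=e["kind"],
            requires=tuple(e.get("requires", ())),
            blockable=e.get("blockable"),
            inferred=bool(e.get("inferred", False)),
        )
        if ev.name in events:
            raise ValueError(f"duplicate event {ev.name!r}")
        events[ev.name] = ev
    return MaturationGraph(
        events=events,
        preloaded=frozenset(spec.get("preloaded", ())),
        core_factors=frozenset(spec.get("core_factors", ())),
        perturbations={
            k: tuple(v) for k, v in (spec.get("perturbations") or {}).items()
        },
    )


def build_default_graph() -> MaturationGraph:
    """The shipped cytoplasmic pre-60S maturation pathway."""
    ref = importlib.resources.files("pre60s") / "data" / "pathway.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_graph(path)


def predict_accumulation(
    g: MaturationGraph, blocked: set[str] | str | frozenset[str]
) -> TrapPrediction:
    """Predict which factors accumulate or fail recruitment under blocks.

    ``blocked`` may contain blockable event names (e.g.
    ``"release(Rlp24)"``) and/or perturbation labels (e.g. ``"Drg1DN"``).
    """
    blocked_events = g.resolve_blocks(set(blocked) if not isinstance(blocked, str) else blocked)
    ok = g.reachable(blocked_events)

    accumulated: set[str] = set()
    not_recruited: set[str] = set()
    for factor in g.factors:
        recruit = g.event_of(factor, "recruit") or g.event_of(factor, "load")
        release = g.event_of(factor, "release")
        on_particle = factor in g.preloaded or (
            recruit is not None and recruit.name in ok
        )
        if recruit is not None and recruit.name not in ok and factor not in g.preloaded:
            not_recruited.add(factor)
        elif on_particle and release is not None and release.name not in ok:
            accumulated.add(factor)
    return TrapPrediction(
        blocked=blocked_events,
        accumulated=frozenset(accumulated),
        not_recruited=frozenset(not_recruited),
    )


@dataclass
class ConsistencyReport:
    """Per-factor agreement between pathway prediction and observed
    accumulation classes, with precision/recall of the predicted
    accumulated set against the observed one."""

    table: pd.DataFrame
    precision: float
    recall: float
    n_testable: int
    n_untestable: int


def consistency_check(
    pred: TrapPrediction,
    classes: pd.DataFrame,
    factors: frozenset[str] | None = None,
) -> ConsistencyReport:
    """Compare a trap prediction with enrichment-derived classes.

    ``classes`` is the output of
    :func:`pre60s.profiles.accumulation_classes` (indexed by protein
    group with a ``cls`` column). Factors absent from ``classes`` are
    listed as ``untestable``. ``factors`` restricts the comparison (e.g.
    to a graph's core factors); by default every factor mentioned by the
    prediction is compared.
    """
    universe = (
        set(factors)
        if factors is not None
        else set(pred.accumulated) | set(pred.not_recruited)
    )
    rows = []
    tp = fp = fn = 0
    for factor in sorted(universe):
        predicted = (
            "accumulated"
            if factor in pred.accumulated
            else "not_recruited"
            if factor in pred.not_recruited
            else "released"
        )
        if factor not in classes.index:
            rows.append((factor, predicted, "untestable", None))
            continue
        observed = str(classes.loc[factor, "cls"])
        agree = (predicted == "accumulated") == (observed == "accumulated")
        rows.append((factor, predicted, observed, agree))
        if predicted == "accumulated" and observed == "accumulated":
            tp += 1
        elif predicted == "accumulated":
            fp += 1
        elif observed == "accumulated":
            fn += 1
    table = pd.DataFrame(
        rows, columns=["factor", "predicted", "observed", "agree"]
    ).set_index("factor")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    n_untestable = int((table["observed"] == "untestable").sum())
    return ConsistencyReport(
        table=table,
        precision=precision,
        recall=recall,
        n_testable=len(table) - n_untestable,
        n_untestable=n_untestable,
    )
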