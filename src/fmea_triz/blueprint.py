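"""Service-blueprint data model with validation and export.

A service blueprint is a laned process diagram: customer actions sit above
the line of interaction, front-stage staff actions between the lines of
interaction and visibility, back-stage staff actions below the line of
visibility, and support processes beneath those.  Failure-point
annotations tie blueprint actions to failure-mode ids from the FMEA
register.

The model stores structure only: scenario (e.g. patient acuity) is a tag,
never inferred, and figures are exported as JSON (lossless round-trip) or
Graphviz DOT (one cluster per occupied lane, failure points marked).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx


class Lane(str, Enum):
    CUSTOMER = "customer"
    FRONT_STAGE = "front_stage"
    BACK_STAGE = "back_stage"
    SUPPORT = "support"


#: Lane order used for rendering, top to bottom.
LANE_ORDER = (Lane.CUSTOMER, Lane.FRONT_STAGE, Lane.BACK_STAGE, Lane.SUPPORT)

_PROVIDER_LANES = {Lane.FRONT_STAGE, Lane.BACK_STAGE, Lane.SUPPORT}


@dataclass(frozen=True)
class BlueprintAction:
    id: str
    lane: Lane
    label: str
    successors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lane", Lane(self.lane))
        object.__setattr__(self, "successors", tuple(self.successors))


@dataclass(frozen=True)
class FailurePointAnnotation:
    failure_id: str
    action_id: str
    note: str = ""


@dataclass(frozen=True)
class ServiceBlueprint:
    title: str
    scenario: str
    actions: tuple[BlueprintAction, ...]
    annotations: tuple[FailurePointAnnotation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "actions", tuple(self.actions))
        object.__setattr__(self, "annotations", tuple(self.annotations))

    def action(self, action_id: str) -> BlueprintAction:
        for a in self.actions:
            if a.id == action_id:
                return a
        raise KeyError(action_id)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "scenario": self.scenario,
            "actions": [
                {"id": a.id, "lane": a.lane.value, "label": a.label,
                 "successors": list(a.successors)}
                for a in self.actions
            ],
            "failure_points": [
                {"failure_id": an.failure_id, "action_id": an.action_id, "note": an.note}
                for an in self.annotations
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ServiceBlueprint":
        return cls(
            title=str(data["title"]),
            scenario=str(data.get("scenario", "")),
            actions=tuple(
                BlueprintAction(str(a["id"]), Lane(a["lane"]), str(a["label"]),
                                tuple(a.get("successors", ())))
                for a in data.get("actions", ())
            ),
            annotations=tuple(
                FailurePointAnnotation(str(an["failure_id"]), str(an["action_id"]),
                                       str(an.get("note", "")))
                for an in data.get("failure_points", ())
            ),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ServiceBlueprint":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


@dataclass(frozen=True)
class BlueprintValidationReport:
    violations: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_blueprint(bp: ServiceBlueprint) -> BlueprintValidationReport:
    """Check referential integrity, acyclicity and the line-of-interaction rule.

    The line-of-interaction rule: any edge with exactly one endpoint in
    the customer lane must link that customer action to a front-stage
    action -- customers never interact directly with back-stage or
    support actions.
    """
    violations: list[str] = []
    warnings: list[str] = []

    ids = [a.id for a in bp.actions]
    if not ids:
        warnings.append("no actions")
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        violations.append(f"duplicate action ids: {dupes}")
    known = set(ids)
    lane_of = {a.id: a.lane for a in bp.actions}

    for a in bp.actions:
        for succ in a.successors:
            if succ not in known:
                violations.append(f"action {a.id}: successor {succ!r} does not exist")
                continue
            lanes = {lane_of[a.id], lane_of[succ]}
            if Lane.CUSTOMER in lanes and lanes & _PROVIDER_LANES:
                if lanes != {Lane.CUSTOMER, Lane.FRONT_STAGE}:
                    violations.append(
                        f"edge {a.id} -> {succ} crosses the line of interaction "
                        f"between {lane_of[a.id].value} and {lane_of[succ].value}; "
                        "customer actions may only link to front-stage actions"
                    )

    for an in bp.annotations:
        if an.action_id not in known:
            violations.append(
                f"failure point {an.failure_id}: action {an.action_id!r} does not exist"
            )

    graph = nx.DiGraph()
    graph.add_nodes_from(known)
    graph.add_edges_from(
        (a.id, s) for a in bp.actions for s in a.successors if s in known
    )
    if known and not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        violations.append(f"blueprint contains a cycle: {cycle}")

    return BlueprintValidationReport(tuple(violations), tuple(warnings))


def list_failure_points(
    blueprints: ServiceBlueprint | Sequence[ServiceBlueprint],
) -> list[tuple[str, str]]:
    """(failure_id, action_id) pairs across scenarios, de-duplicated by failure id.

    Blueprints are validated first; any violation raises.  When the same
    failure is annotated in several scenarios, the first occurrence (in
    blueprint order) is kept.  Output is ordered by failure id.
    """
    if isinstance(blueprints, ServiceBlueprint):
        blueprints = [blueprints]
    for bp in blueprints:
        report = validate_blueprint(bp)
        if not report.ok:
            raise ValueError(
                f"blueprint {bp.title!r} fails validation: {'; '.join(report.violations)}"
            )
    seen: dict[str, str] = {}
    for bp in blueprints:
        for an in bp.annotations:
            seen.setdefault(an.failure_id, an.action_id)
    return [(fid, seen[fid]) for fid in sorted(seen)]


def export_blueprint(bp: ServiceBlueprint, format: str = "json") -> str:
    """Serialize a validated blueprint to ``json`` or Graphviz ``dot``."""
    report = validate_blueprint(bp)
    if not report.ok:
        raise ValueError(f"cannot export invalid blueprint: {'; '.join(report.violations)}")
    if format == "json":
        return json.dumps(bp.to_dict(), indent=2)
    if format == "dot":
        return _to_dot(bp)
    raise ValueError(f"unknown export format: {format!r} (expected 'json' or 'dot')")


def _to_dot(bp: ServiceBlueprint) -> str:
    failure_actions: dict[str, list[str]] = {}
    for an in bp.annotations:
        failure_actions.setdefault(an.action_id, []).append(an.failure_id)
    lines = [f'digraph "{bp.title}" {{', "  rankdir=LR;", "  node [shape=box];"]
    for i, lane in enumerate(LANE_ORDER):
        members = [a for a in bp.actions if a.lane is lane]
        if not members:
            continue
        lines.append(f"  subgraph cluster_{lane.value} {{")
        lines.append(f'    label="{lane.value}";')
        for a in members:
            label = a.label
            attrs = ""
            if a.id in failure_actions:
                flags = ", ".join(sorted(failure_actions[a.id]))
                label = f"{label}\\n[failure: {flags}]"
                attrs = ' style=filled fillcolor="lightpink"'
            lines.append(f'    "{a.id}" [label="{label}"{attrs}];')
        lines.append("  }")
    for a in bp.actions:
        for succ in a.successors:
            lines.append(f'  "{a.id}" -> "{succ}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
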