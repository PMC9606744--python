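"""TRIZ registries, contradiction-matrix lookup and principle suggestion.

TRIZ (the theory of inventive problem solving) catalogues 39 engineering
parameters and 40 inventive principles.  A technical contradiction is a
pair (improving parameter, worsening parameter); the contradiction matrix
maps each pair to an ordered shortlist of candidate principles.

In the service-risk pipeline, each cause of a high-priority failure mode
is tagged with a service-quality determinant; a determinant map translates
determinants to improving parameters; every (improving x worsening) cell
is looked up; the union of suggested principles is then screened by an
expert roster.  Screening is always an explicit roster input, never an
automated relevance score.

The bundled matrix asset is sparse: it carries exactly the cells used by
the bundled elderly-care case study, which are authoritative for this
package.  A user-supplied (e.g. full classical) matrix in the same format
can be passed anywhere a matrix is accepted; absent cells yield an empty
suggestion with a logged notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .fmea import Cause, FailureMode

logger = logging.getLogger(__name__)

N_PARAMETERS = 39
N_PRINCIPLES = 40

#: Cells of the bundled case study (improving, worsening) -> principles.
#: These are authoritative: asset validation enforces them verbatim.
CASE_STUDY_CELLS: dict[tuple[int, int], tuple[int, ...]] = {
    (9, 22): (20, 14, 19, 35),
    (9, 36): (10, 28, 4, 34),
    (17, 22): (21, 17, 35, 38),
    (17, 36): (2, 17, 16),
    (26, 22): (25, 7, 8),
    (26, 36): (3, 13, 10, 27),
    (35, 22): (18, 15, 1),
    (35, 36): (15, 29, 28, 37),
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fmea_triz").joinpath("data", name)))


# ---------------------------------------------------------------------------
# registries


def load_parameters(path: str | Path | None = None) -> dict[int, str]:
    """Index -> name registry of the 39 engineering parameters."""
    path = Path(path) if path else _data_path("triz_parameters.json")
    data = json.loads(path.read_text(encoding="utf-8"))
    return {int(k): str(v) for k, v in data.items()}


def load_principles(path: str | Path | None = None) -> dict[int, str]:
    """Index -> name registry of the 40 inventive principles."""
    path = Path(path) if path else _data_path("inventive_principles.json")
    data = json.loads(path.read_text(encoding="utf-8"))
    return {int(k): str(v) for k, v in data.items()}


# ---------------------------------------------------------------------------
# contradiction matrix


@dataclass(frozen=True)
class ContradictionMatrix:
    """Sparse map (improving, worsening) -> ordered principle indices."""

    cells: Mapping[tuple[int, int], tuple[int, ...]]

    def __post_init__(self) -> None:
        cells: dict[tuple[int, int], tuple[int, ...]] = {}
        for (imp, wor), principles in dict(self.cells).items():
            imp, wor = int(imp), int(wor)
            if imp == wor:
                raise ValueError(f"diagonal cell ({imp}, {wor}): self-contradiction undefined")
            if not (1 <= imp <= N_PARAMETERS and 1 <= wor <= N_PARAMETERS):
                raise ValueError(f"cell ({imp}, {wor}): parameter index outside 1..39")
            principles = tuple(int(p) for p in principles)
            if any(not 1 <= p <= N_PRINCIPLES for p in principles):
                raise ValueError(f"cell ({imp}, {wor}): principle index outside 1..40")
            cells[(imp, wor)] = principles
        object.__setattr__(self, "cells", cells)

    def to_records(self) -> list[dict]:
        return [
            {"improving": imp, "worsening": wor, "principles": list(ps)}
            for (imp, wor), ps in sorted(self.cells.items())
        ]

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "ContradictionMatrix":
        return cls({
            (int(r["improving"]), int(r["worsening"])): tuple(r["principles"])
            for r in records
        })

    @classmethod
    def from_file(cls, path: str | Path) -> "ContradictionMatrix":
        path = Path(path)
        if path.suffix == ".csv":
            import pandas as pd

            df = pd.read_csv(path)
            records = [
                {"improving": row.improving, "worsening": row.worsening,
                 "principles": [int(p) for p in str(row.principles).split()]}
                for row in df.itertuples(index=False)
            ]
            return cls.from_records(records)
        data = json.loads(path.read_text(encoding="utf-8"))
        return cls.from_records(data["cells"])

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"cells": self.to_records()}, indent=2), encoding="utf-8"
        )


def load_matrix(path: str | Path | None = None) -> ContradictionMatrix:
    return ContradictionMatrix.from_file(path or _data_path("contradiction_matrix.json"))


def lookup_matrix(improving: int, worsening: int,
                  matrix: ContradictionMatrix) -> tuple[int, ...]:
    """Principles of one matrix cell, in stored order; () if absent."""
    if improving == worsening:
        raise ValueError(
            f"self-contradiction undefined: improving == worsening == {improving}"
        )
    for idx, role in ((improving, "improving"), (worsening, "worsening")):
        if not 1 <= idx <= N_PARAMETERS:
            raise ValueError(f"{role} parameter index {idx} outside 1..39")
    cell = matrix.cells.get((improving, worsening))
    if cell is None:
        logger.info("contradiction matrix has no cell (%d, %d); "
                    "no principles suggested for this pair", improving, worsening)
        return ()
    return cell


# ---------------------------------------------------------------------------
# determinant map


@dataclass(frozen=True)
class DeterminantMap:
    """Service-quality determinant id -> improving TRIZ parameter index."""

    entries: Mapping[int, int]
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        entries = {int(k): int(v) for k, v in dict(self.entries).items()}
        if any(not 1 <= v <= N_PARAMETERS for v in entries.values()):
            raise ValueError("determinant map targets must be parameter indices 1..39")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "names", {int(k): str(v) for k, v in dict(self.names).items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "DeterminantMap":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        dets = data.get("determinants", data)
        entries = {int(k): int(v["parameter"] if isinstance(v, Mapping) else v)
                   for k, v in dets.items()}
        names = {int(k): str(v.get("name", "")) for k, v in dets.items()
                 if isinstance(v, Mapping)}
        return cls(entries, names)


def load_determinant_map(path: str | Path | None = None) -> DeterminantMap:
    return DeterminantMap.from_file(path or _data_path("determinant_map.yaml"))


def load_case_defaults(path: str | Path | None = None) -> dict:
    """Worsening set and screening roster bundled with the determinant map."""
    data = yaml.safe_load(Path(path or _data_path("determinant_map.yaml"))
                          .read_text(encoding="utf-8"))
    return {
        "worsening": tuple(int(w) for w in data.get("worsening", ())),
        "roster": tuple(int(r) for r in data.get("roster", ())),
    }


def map_causes_to_parameters(failure: FailureMode, dmap: DeterminantMap) -> list[int]:
    """De-duplicated, order-preserving improving parameters for one failure."""
    out: list[int] = []
    for cause in failure.causes:
        if not cause.determinants:
            raise ValueError(
                f"failure {failure.id}: cause {cause.text!r} carries no "
                "determinant tag; tag it or subset the register"
            )
        for det in cause.determinants:
            if det not in dmap.entries:
                raise ValueError(
                    f"failure {failure.id}: cause {cause.text!r} tagged with "
                    f"determinant {det} which is not in the determinant map"
                )
            param = dmap.entries[det]
            if param not in out:
                out.append(param)
    return out


# ---------------------------------------------------------------------------
# suggestion


@dataclass(frozen=True)
class FailureProvenance:
    failure_id: str
    chains: tuple[tuple[str, int, int], ...]  # (cause text, determinant, parameter)


@dataclass(frozen=True)
class SuggestionReport:
    """Outcome of the contradiction-matrix stage for a set of failures."""

    provenance: tuple[FailureProvenance, ...]
    improving: tuple[int, ...]
    worsening: tuple[int, ...]
    cells_consulted: tuple[tuple[tuple[int, int], tuple[int, ...]], ...]
    raw_union: tuple[int, ...]
    screened: tuple[int, ...]
    roster: tuple[int, ...] | None

    def to_dict(self) -> dict:
        return {
            "provenance": [
                {"failure_id": p.failure_id,
                 "chains": [{"cause": c, "determinant": d, "parameter": m}
                            for c, d, m in p.chains]}
                for p in self.provenance
            ],
            "improving": list(self.improving),
            "worsening": list(self.worsening),
            "cells_consulted": [
                {"improving": imp, "worsening": wor, "principles": list(ps)}
                for (imp, wor), ps in self.cells_consulted
            ],
            "raw_union": list(self.raw_union),
            "screened": list(self.screened),
            "roster": list(self.roster) if self.roster is not None else None,
        }


def suggest_principles(
    failures: Sequence[FailureMode],
    dmap: DeterminantMap,
    worsening: Sequence[int],
    matrix: ContradictionMatrix,
    roster: Sequence[int] | None = None,
    pooled: bool = True,
) -> SuggestionReport:
    """Suggest inventive principles for ranked failures.

    Every improving parameter mapped from the failures' causes is crossed
    with every worsening parameter; the raw union is the ordered
    de-duplicated union of the consulted cells.  When a screening roster
    is supplied the screened list is ``raw_union & roster`` (in raw-union
    order); otherwise it equals the raw union.

    With ``pooled=True`` (default) improving parameters are pooled across
    failures before querying, mirroring a joint treatment of the top
    failures; ``pooled=False`` records cells per failure (the raw union is
    identical, but per-failure cell provenance is kept separate).
    """
    worsening = tuple(int(w) for w in worsening)
    if not worsening:
        raise ValueError("worsening parameter set must be non-empty")
    if not failures:
        return SuggestionReport((), (), worsening, (), (), (),
                                tuple(roster) if roster is not None else None)

    provenance: list[FailureProvenance] = []
    improving: list[int] = []
    per_failure_params: list[list[int]] = []
    for failure in failures:
        chains: list[tuple[str, int, int]] = []
        params: list[int] = []
        for cause in failure.causes:
            if not cause.determinants:
                raise ValueError(
                    f"failure {failure.id}: cause {cause.text!r} carries no determinant tag"
                )
            for det in cause.determinants:
                if det not in dmap.entries:
                    raise ValueError(
                        f"failure {failure.id}: cause {cause.text!r} tagged with "
                        f"unmapped determinant {det}"
                    )
                param = dmap.entries[det]
                chains.append((cause.text, det, param))
                if param not in params:
                    params.append(param)
                if param not in improving:
                    improving.append(param)
        provenance.append(FailureProvenance(failure.id, tuple(chains)))
        per_failure_params.append(params)

    cells: list[tuple[tuple[int, int], tuple[int, ...]]] = []
    raw_union: list[int] = []
    query_sets = [improving] if pooled else per_failure_params
    seen_cells: set[tuple[int, int]] = set()
    for params in query_sets:
        for imp in params:
            for wor in worsening:
                if (imp, wor) in seen_cells:
                    continue
                seen_cells.add((imp, wor))
                principles = lookup_matrix(imp, wor, matrix)
                cells.append(((imp, wor), principles))
                for p in principles:
                    if p not in raw_union:
                        raw_union.append(p)

    if roster is not None:
        roster_t = tuple(int(r) for r in roster)
        screened = tuple(p for p in raw_union if p in roster_t)
    else:
        roster_t = None
        screened = tuple(raw_union)

    return SuggestionReport(
        provenance=tuple(provenance),
        improving=tuple(improving),
        worsening=worsening,
        cells_consulted=tuple(cells),
        raw_union=tuple(raw_union),
        screened=screened,
        roster=roster_t,
    )


# ---------------------------------------------------------------------------
# asset validation


@dataclass(frozen=True)
class AssetValidationReport:
    deviations: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.deviations


def validate_matrix_assets(
    matrix: ContradictionMatrix,
    parameters: Mapping[int, str],
    principles: Mapping[int, str],
) -> AssetValidationReport:
    """Check registry sizes (39/40) and the authoritative case cells verbatim."""
    deviations: list[str] = []
    if len(parameters) != N_PARAMETERS:
        deviations.append(f"parameter registry has {len(parameters)} entries, expected 39")
    if sorted(parameters) != list(range(1, N_PARAMETERS + 1)) and len(parameters) == N_PARAMETERS:
        deviations.append("parameter registry indices are not exactly 1..39")
    if len(principles) != N_PRINCIPLES:
        deviations.append(f"principle registry has {len(principles)} entries, expected 40")
    if sorted(principles) != list(range(1, N_PRINCIPLES + 1)) and len(principles) == N_PRINCIPLES:
        deviations.append("principle registry indices are not exactly 1..40")
    for cell, expected in CASE_STUDY_CELLS.items():
        actual = matrix.cells.get(cell)
        if actual != expected:
            deviations.append(
                f"cell {cell}: expected {list(expected)}, found "
                f"{list(actual) if actual is not None else 'absent'}"
            )
    return AssetValidationReport(tuple(deviations))
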