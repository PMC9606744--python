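"""The bundled CMEC (combined medical and elderly care) case study.

Loaders for the worked example shipped with the package: a six-entry
failure register, two service-blueprint scenarios (mild and severe
illness), printed per-cell fuzzy rating means from a 35-member expert
panel, a 13-expert endorsement tally, and the TRIZ configuration
(determinant map, worsening parameters, screening roster, matrix cells).

The raw 35 questionnaires behind the printed means are not available, so
``case_panel()`` reconstructs a SYNTHETIC panel by reverse-fitting integer
score counts to each printed mean triple.  The reconstruction is
mean-faithful (component means match the printed values to within 0.0005)
but the individual ratings are not the study's; see docs/methods.md.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .blueprint import ServiceBlueprint
from .fmea import Cause, Factor, FailureMode, RatingPanel, VoteTally
from .fuzzy import LinguisticScale, TriangularFuzzyNumber, default_scale
from .panel_sim import CountVector, fit_counts_to_fuzzy_mean, panel_from_counts

N_PANEL_RATERS = 35
N_EXPERTS = 13
TOP_K = 3  # failures taken forward to the contradiction-matrix stage


def _data_path(name: str) -> Path:
    return Path(str(resources.files("fmea_triz").joinpath("data", name)))


def failure_register() -> list[FailureMode]:
    data = json.loads(_data_path("failure_register.json").read_text(encoding="utf-8"))
    return [
        FailureMode(
            id=item["id"],
            point=item["point"],
            situation=item["situation"],
            causes=tuple(Cause(c["text"], tuple(c.get("determinants", ())))
                         for c in item["causes"]),
            effects=tuple(item.get("effects", ())),
        )
        for item in data
    ]


def fuzzy_means() -> dict[tuple[str, Factor], TriangularFuzzyNumber]:
    """Printed per-cell (failure, factor) fuzzy means of the 35-rater panel."""
    data = json.loads(_data_path("case_fuzzy_means.json").read_text(encoding="utf-8"))
    out: dict[tuple[str, Factor], TriangularFuzzyNumber] = {}
    for fac, per_failure in data["means"].items():
        for fid, (q, o, p) in per_failure.items():
            out[(fid, Factor(fac))] = TriangularFuzzyNumber(q, o, p)
    return out


def case_counts(scale: LinguisticScale | None = None
                ) -> dict[tuple[str, Factor], CountVector]:
    """Reverse-fitted per-cell score counts reproducing the printed means."""
    scale = scale or default_scale()
    counts: dict[tuple[str, Factor], CountVector] = {}
    for cell, target in fuzzy_means().items():
        cv = fit_counts_to_fuzzy_mean(target, N_PANEL_RATERS, scale)
        if cv is None:  # pragma: no cover - bundled means are known-feasible
            raise RuntimeError(f"no count vector reproduces printed means for {cell}")
        counts[cell] = cv
    return counts


def case_panel(scale: LinguisticScale | None = None) -> RatingPanel:
    """Synthetic 35-rater panel whose cell means reproduce the printed tables."""
    return panel_from_counts(case_counts(scale))


def expert_votes() -> VoteTally:
    data = json.loads(_data_path("expert_votes.json").read_text(encoding="utf-8"))
    counts = {opt: 0 for opt in data["options"]}
    for choice in data["votes"].values():
        counts[choice] += 1
    return VoteTally(counts)


def blueprints() -> list[ServiceBlueprint]:
    return [
        ServiceBlueprint.from_file(_data_path("blueprint_mild.json")),
        ServiceBlueprint.from_file(_data_path("blueprint_severe.json")),
    ]


def solutions() -> dict[int, str]:
    """Principle index -> service optimization solution headline."""
    data = json.loads(_data_path("case_solutions.json").read_text(encoding="utf-8"))
    return {int(k): v for k, v in data.items()}
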