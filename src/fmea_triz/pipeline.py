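"""The three-phase pipeline: blueprint validation -> Fuzzy-FMEA -> TRIZ.

Phase I validates the service blueprints and collects the annotated
failure points; phase II scores the rating panel, defuzzifies and ranks
the failure modes by FRPN; phase III maps the top-ranked failures' causes
through the contradiction matrix and screens the suggested inventive
principles against an expert roster.  Any stage's validation error aborts
with a stage-tagged message.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import case_study
from .blueprint import (
    BlueprintValidationReport,
    ServiceBlueprint,
    list_failure_points,
    validate_blueprint,
)
from .fmea import FailureMode, RatingPanel, RiskScore, rank_failures, score_panel
from .fuzzy import DefuzzMethod, EQ4_NOTICE, LinguisticScale, default_scale
from .io import (
    RunConfig,
    read_failure_register,
    read_ratings,
    write_risk_report,
    write_suggestion_report,
)
from .triz import (
    SuggestionReport,
    load_case_defaults,
    load_determinant_map,
    load_matrix,
    load_parameters,
    load_principles,
    suggest_principles,
    validate_matrix_assets,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Hard error in one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class PipelineResult:
    blueprint_reports: tuple[tuple[str, BlueprintValidationReport], ...]
    failure_points: tuple[tuple[str, str], ...]
    ranked_scores: tuple[RiskScore, ...]
    suggestion: SuggestionReport
    outputs: tuple[Path, ...]


def run_phase_pipeline(config: RunConfig) -> PipelineResult:
    """Run all three phases and write the artifact bundle to ``config.outdir``."""
    # ---- load inputs (bundled case assets when a path is omitted) ----
    try:
        scale = (LinguisticScale.from_file(config.scale) if config.scale
                 else default_scale())
        register = (read_failure_register(config.register) if config.register
                    else case_study.failure_register())
        panel = (read_ratings(config.ratings) if config.ratings
                 else case_study.case_panel(scale))
        bps = ([ServiceBlueprint.from_file(p) for p in config.blueprints]
               if config.blueprints else case_study.blueprints())
        dmap = load_determinant_map(config.determinant_map)
        matrix = load_matrix(config.matrix)
        parameters = load_parameters(config.parameters)
        principles = load_principles(config.principles)
        defaults = load_case_defaults(config.determinant_map)
        worsening = config.worsening if config.worsening is not None else defaults["worsening"]
        roster = config.roster if config.roster is not None else (defaults["roster"] or None)
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError("inputs", str(exc)) from exc

    if config.strict and config.defuzz_method is DefuzzMethod.TRAPEZOIDAL_EQ4:
        raise PipelineError("inputs", "strict mode: " + EQ4_NOTICE)

    asset_report = validate_matrix_assets(matrix, parameters, principles)
    if not asset_report.ok:
        raise PipelineError("triz-assets", "; ".join(asset_report.deviations))

    # ---- phase I: blueprint validation -------------------------------
    bp_reports = []
    for bp in bps:
        report = validate_blueprint(bp)
        bp_reports.append((bp.title, report))
        if not report.ok:
            raise PipelineError(
                "blueprint", f"{bp.title!r}: {'; '.join(report.violations)}"
            )
    try:
        failure_points = tuple(list_failure_points(bps))
    except ValueError as exc:
        raise PipelineError("blueprint", str(exc)) from exc

    # ---- phase II: Fuzzy-FMEA scoring and ranking ---------------------
    try:
        scores = score_panel(panel, scale, config.defuzz_method, failures=register)
        ranked = rank_failures(scores, key="frpn")
    except ValueError as exc:
        raise PipelineError("fmea", str(exc)) from exc

    # ---- phase III: TRIZ suggestion -----------------------------------
    by_id = {f.id: f for f in register}
    top = [by_id[s.failure_id] for s in ranked[: config.top_k] if s.failure_id in by_id]
    try:
        suggestion = suggest_principles(top, dmap, worsening, matrix, roster=roster)
    except ValueError as exc:
        raise PipelineError("triz", str(exc)) from exc

    # ---- write the artifact bundle ------------------------------------
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = (f"generated {datetime.datetime.now().isoformat(timespec='seconds')}"
             if config.timestamp else None)
    outputs = []
    try:
        risk_csv = outdir / "risk_report.csv"
        write_risk_report(ranked, risk_csv, "csv", register, header_comment=stamp)
        risk_md = outdir / "risk_report.md"
        write_risk_report(ranked, risk_md, "md", register, header_comment=stamp)
        sugg_json = outdir / "suggestions.json"
        write_suggestion_report(suggestion, sugg_json, "json", header_comment=stamp)
        sugg_md = outdir / "suggestions.md"
        write_suggestion_report(
            suggestion, sugg_md, "md", principle_names=principles,
            solutions=case_study.solutions() if not config.matrix else None,
            header_comment=stamp,
        )
        outputs = [risk_csv, risk_md, sugg_json, sugg_md]
    except OSError as exc:
        raise PipelineError("report", str(exc)) from exc

    logger.info("pipeline complete: %d failures ranked, %d principles screened",
                len(ranked), len(suggestion.screened))
    return PipelineResult(
        blueprint_reports=tuple(bp_reports),
        failure_points=failure_points,
        ranked_scores=tuple(ranked),
        suggestion=suggestion,
        outputs=tuple(outputs),
    )
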