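"""Readers, writers and run configuration.

File dialects:

* ratings CSV (long format): header ``rater_id,failure_id,factor,score``,
  UTF-8, one record per (rater, failure, factor);
* failure register: JSON (list of objects) or CSV with columns
  ``id,point,situation,causes,effects`` where causes are ``;``-separated
  and may carry determinant tags in trailing brackets, e.g.
  ``Inadequate healthcare workers [13]``; effects are ``;``-separated;
* risk report: CSV or Markdown mirroring the worksheet layout
  (id, situation, causes, S, O, D, FRPN, rank); risk values are printed
  half-up at 3 decimals, percentages at 2.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .fmea import (
    Cause,
    Factor,
    FailureMode,
    RatingPanel,
    RatingRecord,
    RiskScore,
)
from .fuzzy import DefuzzMethod, round_half_up

_RATING_COLUMNS = ["rater_id", "failure_id", "factor", "score"]
_FACTOR_VALUES = {f.value for f in Factor}


def read_ratings(path: str | Path) -> RatingPanel:
    """Read a long-format ratings CSV; errors name the offending line."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _RATING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        factor = str(row.factor).strip()
        if factor not in _FACTOR_VALUES:
            raise ValueError(f"{path} line {line}: unknown factor label {factor!r}")
        try:
            score = int(str(row.score).strip())
        except ValueError:
            raise ValueError(f"{path} line {line}: malformed score {row.score!r}") from None
        try:
            records.append(RatingRecord(str(row.rater_id), str(row.failure_id),
                                        Factor(factor), score))
        except ValueError as exc:
            raise ValueError(f"{path} line {line}: {exc}") from None
    return RatingPanel(records)


def write_ratings(panel: RatingPanel, path: str | Path) -> None:
    panel.to_dataframe().to_csv(path, index=False)


_CAUSE_TAG = re.compile(r"^(?P<text>.*?)\s*\[(?P<tags>[\d,\s]+)\]$")


def _parse_cause(segment: str) -> Cause:
    segment = segment.strip()
    m = _CAUSE_TAG.match(segment)
    if m:
        tags = tuple(int(t) for t in m.group("tags").split(",") if t.strip())
        return Cause(m.group("text").strip(), tags)
    return Cause(segment)


def read_failure_register(path: str | Path) -> list[FailureMode]:
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return [
            FailureMode(
                id=item["id"], point=item.get("point", ""),
                situation=item.get("situation", ""),
                causes=tuple(Cause(c["text"], tuple(c.get("determinants", ())))
                             for c in item["causes"]),
                effects=tuple(item.get("effects", ())),
            )
            for item in data
        ]
    df = pd.read_csv(path, dtype=str).fillna("")
    failures = []
    for row in df.itertuples(index=False):
        causes = tuple(_parse_cause(seg) for seg in str(row.causes).split(";") if seg.strip())
        effects = tuple(seg.strip() for seg in str(row.effects).split(";") if seg.strip())
        failures.append(FailureMode(str(row.id), str(row.point), str(row.situation),
                                    causes, effects))
    return failures


def _fmt_rank(rank: int | None, flag_top: int = 3) -> str:
    if rank is None:
        return ""
    return f"{rank}*" if rank <= flag_top else str(rank)


def risk_report_frame(
    scores: Sequence[RiskScore],
    register: Sequence[FailureMode] | None = None,
) -> pd.DataFrame:
    """Risk worksheet as a DataFrame, values rounded at the reporting layer."""
    info = {f.id: f for f in register} if register else {}
    rows = []
    for s in sorted(scores, key=lambda s: (s.rank if s.rank is not None else 0, s.failure_id)):
        f = info.get(s.failure_id)
        rows.append({
            "id": s.failure_id,
            "situation": f.situation if f else "",
            "causes": "; ".join(c.text for c in f.causes) if f else "",
            "S": round_half_up(s.s_defuzz, 3),
            "O": round_half_up(s.o_defuzz, 3),
            "D": round_half_up(s.d_defuzz, 3),
            "FRPN": round_half_up(s.frpn, 3),
            "traditional_RPN": (round_half_up(s.traditional_rpn, 3)
                                if s.traditional_rpn is not None else None),
            "rank": s.rank,
            "prioritization": _fmt_rank(s.rank),
        })
    return pd.DataFrame(rows)


def write_risk_report(
    scores: Sequence[RiskScore],
    path: str | Path,
    format: str = "csv",
    register: Sequence[FailureMode] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write the risk worksheet as ``csv`` or ``md`` (Markdown table)."""
    path = Path(path)
    df = risk_report_frame(scores, register)
    if format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
        return
    if format == "md":
        cols = ["id", "situation", "causes", "S", "O", "D", "FRPN", "prioritization"]
        lines = []
        if header_comment:
            lines.append(f"<!-- {header_comment} -->")
        lines.append("| " + " | ".join(cols) + " |")
        lines.append("|" + "|".join("---" for _ in cols) + "|")
        for _, row in df.iterrows():
            cells = [f"{row[c]:.3f}" if c in ("S", "O", "D", "FRPN") else str(row[c])
                     for c in cols]
            lines.append("| " + " | ".join(cells) + " |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown risk report format: {format!r} (expected 'csv' or 'md')")


def write_suggestion_report(
    report,
    path: str | Path,
    format: str = "json",
    principle_names: Mapping[int, str] | None = None,
    solutions: Mapping[int, str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a SuggestionReport as JSON or a principle -> solution Markdown table."""
    path = Path(path)
    if format == "json":
        doc = report.to_dict()
        if header_comment:
            doc = {"comment": header_comment, **doc}
        path.write_text(json.dumps(doc, indent=2), encoding="utf-8")
        return
    if format == "md":
        lines = []
        if header_comment:
            lines.append(f"<!-- {header_comment} -->")
        lines.append("| Inventive principle | Service optimization solution |")
        lines.append("|---|---|")
        for p in report.screened:
            name = principle_names.get(p, "") if principle_names else ""
            label = f"No. {p}" + (f": {name}" if name else "")
            sol = solutions.get(p, "") if solutions else ""
            lines.append(f"| {label} | {sol} |")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    raise ValueError(f"unknown suggestion report format: {format!r}")


@dataclass(frozen=True)
class RunConfig:
    """Paths and options driving the three-phase pipeline.

    ``None`` paths fall back to the bundled case-study assets.  The
    ``timestamp`` flag controls whether reports carry a generation-time
    header (off by default so identical inputs give byte-identical
    outputs).
    """

    ratings: Path | None = None
    register: Path | None = None
    blueprints: tuple[Path, ...] = ()
    scale: Path | None = None
    determinant_map: Path | None = None
    matrix: Path | None = None
    parameters: Path | None = None
    principles: Path | None = None
    defuzz_method: DefuzzMethod = DefuzzMethod.CENTROID
    worsening: tuple[int, ...] | None = None
    roster: tuple[int, ...] | None = None
    top_k: int = 3
    outdir: Path = Path("fmea_triz_out")
    seed: int = 0
    strict: bool = False
    timestamp: bool = False


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; relative paths resolve next to the file."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    base = path.parent

    def _resolve(key: str) -> Path | None:
        value = data.get(key)
        if value is None:
            return None
        p = Path(value)
        p = p if p.is_absolute() else base / p
        if not p.exists():
            raise FileNotFoundError(f"run config {key!r}: path does not exist: {p}")
        return p

    blueprints = tuple(
        (Path(v) if Path(v).is_absolute() else base / v)
        for v in data.get("blueprints", ())
    )
    for p in blueprints:
        if not p.exists():
            raise FileNotFoundError(f"run config 'blueprints': path does not exist: {p}")
    outdir = Path(data.get("outdir", "fmea_triz_out"))
    return RunConfig(
        ratings=_resolve("ratings"),
        register=_resolve("register"),
        blueprints=blueprints,
        scale=_resolve("scale"),
        determinant_map=_resolve("determinant_map"),
        matrix=_resolve("matrix"),
        parameters=_resolve("parameters"),
        principles=_resolve("principles"),
        defuzz_method=DefuzzMethod(data.get("defuzz_method", "centroid")),
        worsening=tuple(data["worsening"]) if "worsening" in data else None,
        roster=tuple(data["roster"]) if "roster" in data else None,
        top_k=int(data.get("top_k", 3)),
        outdir=outdir if outdir.is_absolute() else base / outdir,
        seed=int(data.get("seed", 0)),
        strict=bool(data.get("strict", False)),
        timestamp=bool(data.get("timestamp", False)),
    )
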