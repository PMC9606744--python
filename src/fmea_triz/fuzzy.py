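"""Triangular fuzzy numbers and the five-level linguistic rating scale.

Multi-rater Likert scores (1-5) are mapped to triangular fuzzy numbers
(TFNs), aggregated component-wise across raters, and collapsed back to a
crisp value.  A TFN ``(q, o, p)`` has membership rising linearly from the
lower bound ``q`` to the mode ``o`` and falling back to the upper bound
``p``; all three components live on ``[0, 1]``.

Two defuzzification rules are provided:

* ``centroid`` -- ``(q + o + p) / 3``, the centre of gravity of the
  triangular membership function.  This is the package default: it is the
  rule that reproduces the defuzzified factor tables of the combined
  medical and elderly care (CMEC) case study bundled with the package.
* ``trapezoidal_eq4`` -- ``(q + 2o + p) / 4``, the trapezoidal-equivalence
  rule (a triangle read as the degenerate trapezoid ``(q, o, o, p)``).
  On asymmetric inputs it deviates slightly from the centroid (e.g. 0.671
  vs 0.669 on the case study's first severity row); a notice is logged
  when it is selected so the choice is always explicit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

_EPS = 1e-12

EQ4_NOTICE = (
    "trapezoidal_eq4 defuzzification (q + 2o + p)/4 selected: on asymmetric "
    "fuzzy numbers it deviates from the centroid (q + o + p)/3 that the "
    "bundled case-study tables were produced with."
)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round ``x`` half-up to ``ndigits`` decimals (reporting convention).

    Internal computation is always full precision; tables round 3 dp for
    risk values and 2 dp for percentages, with halves away from zero.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TriangularFuzzyNumber:
    """Ordered triple ``0 <= q <= o <= p <= 1`` on the unit interval."""

    q: float
    o: float
    p: float

    def __post_init__(self) -> None:
        q, o, p = float(self.q), float(self.o), float(self.p)
        if not (-_EPS <= q <= o + _EPS and o <= p + _EPS and p <= 1.0 + _EPS):
            raise ValueError(
                f"invalid triangular fuzzy number ({q}, {o}, {p}): "
                "components must satisfy 0 <= q <= o <= p <= 1"
            )
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "o", o)
        object.__setattr__(self, "p", p)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q, self.o, self.p)

    @property
    def is_symmetric(self) -> bool:
        return abs((self.p - self.o) - (self.o - self.q)) <= 1e-9


TFN = TriangularFuzzyNumber


class DefuzzMethod(str, Enum):
    """The two supported defuzzification rules."""

    CENTROID = "centroid"
    TRAPEZOIDAL_EQ4 = "trapezoidal_eq4"


@dataclass(frozen=True)
class ScaleLevel:
    label: str
    score: int
    tfn: TriangularFuzzyNumber


@dataclass(frozen=True)
class LinguisticScale:
    """Five-level linguistic scale mapping Likert scores 1-5 to TFNs.

    Scores must be a permutation of 1..5 and level TFNs must be
    non-decreasing in every component as the score increases.
    """

    levels: tuple[ScaleLevel, ...]

    def __post_init__(self) -> None:
        levels = tuple(sorted(self.levels, key=lambda lv: lv.score))
        if len(levels) != 5 or sorted(lv.score for lv in levels) != [1, 2, 3, 4, 5]:
            raise ValueError("linguistic scale needs exactly five levels with scores 1..5")
        for lo, hi in zip(levels, levels[1:]):
            if (hi.tfn.q < lo.tfn.q - _EPS or hi.tfn.o < lo.tfn.o - _EPS
                    or hi.tfn.p < lo.tfn.p - _EPS):
                raise ValueError(
                    f"scale TFNs must be non-decreasing with score: "
                    f"{lo.score} -> {hi.score} decreases a component"
                )
        object.__setattr__(self, "levels", levels)

    @property
    def scores(self) -> tuple[int, ...]:
        return tuple(lv.score for lv in self.levels)

    def tfn_for(self, score: int) -> TriangularFuzzyNumber:
        for lv in self.levels:
            if lv.score == score:
                return lv.tfn
        raise ValueError(f"score out of scale: {score!r} (valid scores: 1..5)")

    def label_for(self, score: int) -> str:
        for lv in self.levels:
            if lv.score == score:
                return lv.label
        raise ValueError(f"score out of scale: {score!r}")

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "levels": [
                {"label": lv.label, "score": lv.score,
                 "q": lv.tfn.q, "o": lv.tfn.o, "p": lv.tfn.p}
                for lv in self.levels
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinguisticScale":
        try:
            levels = tuple(
                ScaleLevel(
                    label=str(item["label"]),
                    score=int(item["score"]),
                    tfn=TriangularFuzzyNumber(item["q"], item["o"], item["p"]),
                )
                for item in data["levels"]
            )
        except KeyError as exc:
            raise ValueError(f"scale document missing field: {exc}") from exc
        return cls(levels)

    @classmethod
    def from_file(cls, path: str | Path) -> "LinguisticScale":
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False),
                            encoding="utf-8")


def default_scale() -> LinguisticScale:
    """The bundled five-level scale (NI, LI, I, VI, EI).

    Scores 1..5 map to {(0,0,0.25), (0,0.25,0.5), (0.25,0.5,0.75),
    (0.5,0.75,1), (0.75,1,1)} -- the standard normalized importance scale
    used by the bundled case study.
    """
    return LinguisticScale(
        levels=(
            ScaleLevel("NI (Not Important)", 1, TFN(0.00, 0.00, 0.25)),
            ScaleLevel("LI (A Little Important)", 2, TFN(0.00, 0.25, 0.50)),
            ScaleLevel("I (Important)", 3, TFN(0.25, 0.50, 0.75)),
            ScaleLevel("VI (Very Important)", 4, TFN(0.50, 0.75, 1.00)),
            ScaleLevel("EI (Extremely Important)", 5, TFN(0.75, 1.00, 1.00)),
        )
    )


DEFAULT_SCALE = default_scale()


def fuzzify(score: int, scale: LinguisticScale | None = None) -> TriangularFuzzyNumber:
    """Map a Likert score to its scale TFN (unmodified)."""
    scale = scale or DEFAULT_SCALE
    if not isinstance(score, (int,)) or isinstance(score, bool):
        raise ValueError(f"score out of scale: {score!r} (must be an integer 1..5)")
    return scale.tfn_for(score)


def aggregate_mean(tfns: Sequence[TriangularFuzzyNumber] | Iterable[TriangularFuzzyNumber]
                   ) -> TriangularFuzzyNumber:
    """Component-wise arithmetic mean of a non-empty list of TFNs.

    This is the panel aggregation step: the lower bounds, modes and upper
    bounds of the raters' fuzzy ratings are each averaged, which again
    yields a valid TFN.
    """
    tfns = list(tfns)
    if not tfns:
        raise ValueError("no ratings to aggregate")
    n = len(tfns)
    return TriangularFuzzyNumber(
        sum(t.q for t in tfns) / n,
        sum(t.o for t in tfns) / n,
        sum(t.p for t in tfns) / n,
    )


def defuzzify(tfn: TriangularFuzzyNumber,
              method: DefuzzMethod | str = DefuzzMethod.CENTROID) -> float:
    """Collapse a TFN to a crisp value in ``[q, p]``.

    ``centroid`` returns ``(q + o + p)/3``; ``trapezoidal_eq4`` returns
    ``(q + 2o + p)/4`` and logs a notice (see module docstring).  Both
    coincide exactly on symmetric TFNs.
    """
    method = DefuzzMethod(method)
    if method is DefuzzMethod.TRAPEZOIDAL_EQ4:
        logger.warning(EQ4_NOTICE)
        return (tfn.q + 2.0 * tfn.o + tfn.p) / 4.0
    return (tfn.q + tfn.o + tfn.p) / 3.0
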