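"""FMEA worksheet model and risk prioritization.

A failure-mode register (what can go wrong, why, with what effect) is
scored by a panel of raters on three factors -- severity (S), occurrence
(O) and detectability (D) -- on a 1-5 Likert scale.  Two risk keys are
computed per failure mode:

* the fuzzy risk priority number (FRPN): the product of the three
  defuzzified panel-mean fuzzy ratings, a value in [0, 1];
* the traditional RPN: the product of the three per-factor arithmetic
  means of the raw scores, a value in [1, 125].

Failures are ranked descending by either key (rank 1 = riskiest), rankings
are compared by rank correlation, and expert endorsements of the two
schemes are summarized as percentages.

Note on D orientation: a higher detectability score means the failure is
detected only after it has occurred, i.e. worse; no re-orientation is
applied anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .fuzzy import (
    DefuzzMethod,
    LinguisticScale,
    TriangularFuzzyNumber,
    aggregate_mean,
    defuzzify,
    fuzzify,
)


class Factor(str, Enum):
    S = "S"
    O = "O"
    D = "D"


FACTORS = (Factor.S, Factor.O, Factor.D)


@dataclass(frozen=True)
class Cause:
    text: str
    determinants: tuple[int, ...] = ()


@dataclass(frozen=True)
class FailureMode:
    """One entry of the failure register."""

    id: str
    point: str
    situation: str
    causes: tuple[Cause, ...]
    effects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.causes:
            raise ValueError(f"failure mode {self.id}: at least one cause is required")
        object.__setattr__(self, "causes", tuple(self.causes))
        object.__setattr__(self, "effects", tuple(self.effects))


@dataclass(frozen=True)
class RatingRecord:
    """One rater's score for one (failure, factor) cell."""

    rater_id: str
    failure_id: str
    factor: Factor
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "factor", Factor(self.factor))
        score = self.score
        if not isinstance(score, int) or isinstance(score, bool) or not 1 <= score <= 5:
            raise ValueError(
                f"rating for ({self.rater_id}, {self.failure_id}, "
                f"{self.factor.value}) has score out of scale: {score!r}"
            )


class RatingPanel:
    """Immutable collection of rating records, one per (rater, failure, factor)."""

    def __init__(self, records: Iterable[RatingRecord]):
        records = tuple(records)
        seen: set[tuple[str, str, Factor]] = set()
        for rec in records:
            key = (rec.rater_id, rec.failure_id, rec.factor)
            if key in seen:
                raise ValueError(f"duplicate rating record for {key}")
            seen.add(key)
        self._records = records
        cells: dict[tuple[str, Factor], list[int]] = {}
        for rec in records:
            cells.setdefault((rec.failure_id, rec.factor), []).append(rec.score)
        self._cells = {k: tuple(v) for k, v in cells.items()}

    @property
    def records(self) -> tuple[RatingRecord, ...]:
        return self._records

    @property
    def failure_ids(self) -> tuple[str, ...]:
        return tuple(sorted({rec.failure_id for rec in self._records}))

    def cell_scores(self, failure_id: str, factor: Factor | str) -> tuple[int, ...]:
        return self._cells.get((failure_id, Factor(factor)), ())

    def n_raters(self, failure_id: str, factor: Factor | str) -> int:
        return len(self.cell_scores(failure_id, factor))

    def cells(self) -> dict[tuple[str, Factor], tuple[int, ...]]:
        return dict(self._cells)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RatingPanel) and set(self._records) == set(other._records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rater_id, r.failure_id, r.factor.value, r.score) for r in self._records],
            columns=["rater_id", "failure_id", "factor", "score"],
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingPanel":
        return cls(
            RatingRecord(str(row.rater_id), str(row.failure_id),
                         Factor(str(row.factor)), int(row.score))
            for row in df.itertuples(index=False)
        )


@dataclass(frozen=True)
class RiskScore:
    """Per-failure crisp factor values and risk keys."""

    failure_id: str
    s_defuzz: float
    o_defuzz: float
    d_defuzz: float
    frpn: float
    traditional_rpn: float | None = None
    rank: int | None = None


@dataclass(frozen=True)
class RankComparison:
    kendall_tau: float
    spearman_rho: float
    disagreements: tuple[str, ...]


@dataclass(frozen=True)
class VoteTally:
    """Expert endorsements, one vote per expert, over named options."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        if any(c < 0 for c in counts.values()):
            raise ValueError("vote counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _required_cells(panel: RatingPanel,
                    failures: Sequence[FailureMode] | None) -> list[tuple[str, Factor]]:
    if failures is not None:
        wanted = [(f.id, fac) for f in failures for fac in FACTORS]
    else:
        wanted = sorted(panel.cells(), key=lambda c: (c[0], c[1].value))
    missing = [cell for cell in wanted if not panel.cell_scores(*cell)]
    if missing:
        pretty = ", ".join(f"({fid}, {fac.value})" for fid, fac in missing)
        raise ValueError(f"panel has no ratings for cells: {pretty}")
    return wanted


def compute_fuzzy_factor_means(
    panel: RatingPanel,
    scale: LinguisticScale | None = None,
    failures: Sequence[FailureMode] | None = None,
) -> dict[tuple[str, Factor], TriangularFuzzyNumber]:
    """Per-cell component-wise mean of the raters' fuzzified scores."""
    cells = _required_cells(panel, failures)
    return {
        cell: aggregate_mean([fuzzify(s, scale) for s in panel.cell_scores(*cell)])
        for cell in cells
    }


def compute_frpn(s: float, o: float, d: float) -> float:
    """Fuzzy risk priority number: the product of three crisp factor values."""
    for name, v in (("s", s), ("o", o), ("d", d)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"defuzzified factor {name}={v!r} outside [0, 1]")
    return s * o * d


def compute_traditional_rpn(
    panel: RatingPanel,
    failures: Sequence[FailureMode] | None = None,
) -> dict[str, float]:
    """Product of the per-factor arithmetic means of the raw 1-5 scores."""
    fids = ([f.id for f in failures] if failures is not None
            else list(panel.failure_ids))
    missing = [(fid, fac) for fid in fids for fac in FACTORS
               if not panel.cell_scores(fid, fac)]
    if missing:
        pretty = ", ".join(f"({fid}, {fac.value})" for fid, fac in missing)
        raise ValueError(f"panel has no ratings for cells: {pretty}")
    fids = sorted(fids)
    out: dict[str, float] = {}
    for fid in fids:
        means = []
        for fac in FACTORS:
            scores = panel.cell_scores(fid, fac)
            means.append(sum(scores) / len(scores))
        out[fid] = means[0] * means[1] * means[2]
    return out


def score_panel(
    panel: RatingPanel,
    scale: LinguisticScale | None = None,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID,
    failures: Sequence[FailureMode] | None = None,
) -> list[RiskScore]:
    """Defuzzified S/O/D, FRPN and traditional RPN for every failure."""
    fuzzy_means = compute_fuzzy_factor_means(panel, scale, failures)
    traditional = compute_traditional_rpn(panel, failures)
    fids = sorted({fid for fid, _ in fuzzy_means})
    scores = []
    for fid in fids:
        s = defuzzify(fuzzy_means[(fid, Factor.S)], method)
        o = defuzzify(fuzzy_means[(fid, Factor.O)], method)
        d = defuzzify(fuzzy_means[(fid, Factor.D)], method)
        scores.append(RiskScore(fid, s, o, d, compute_frpn(s, o, d), traditional[fid]))
    return scores


def rank_failures(scores: Sequence[RiskScore], key: str = "frpn") -> list[RiskScore]:
    """Assign ranks 1..N descending by the chosen key.

    ``key`` is ``"frpn"`` or ``"traditional"``.  Ties break by ascending
    failure id, so the output ranks always form a permutation of 1..N.
    """
    if key not in ("frpn", "traditional"):
        raise ValueError(f"unknown ranking key: {key!r}")
    ids = [s.failure_id for s in scores]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate failure ids in scores: {dupes}")

    def keyval(s: RiskScore) -> float:
        if key == "frpn":
            return s.frpn
        if s.traditional_rpn is None:
            raise ValueError(f"no traditional RPN available for {s.failure_id}")
        return s.traditional_rpn

    ordered = sorted(scores, key=lambda s: (-keyval(s), s.failure_id))
    return [dataclasses.replace(s, rank=i + 1) for i, s in enumerate(ordered)]


def compare_rankings(a: Mapping[str, int], b: Mapping[str, int]) -> RankComparison:
    """Kendall tau, Spearman rho and the ids whose ranks differ."""
    if set(a) != set(b):
        raise ValueError(
            f"rankings cover different failure sets: {sorted(set(a) ^ set(b))}"
        )
    ids = sorted(a)
    ra = [a[i] for i in ids]
    rb = [b[i] for i in ids]
    if len(ids) < 2:
        tau = rho = 1.0
    else:
        tau = float(stats.kendalltau(ra, rb).statistic)
        rho = float(stats.spearmanr(ra, rb).statistic)
    disagree = tuple(i for i in ids if a[i] != b[i])
    return RankComparison(tau, rho, disagree)


def expert_vote_summary(tally: VoteTally) -> dict[str, float]:
    """Percentage of experts endorsing each option, totalling exactly 100.

    Each percentage is floored at two decimals; the rounding residue (the
    hundredths of a percent needed to reach 100) is credited to options in
    descending vote count (ties by insertion order).  With 10 of 13 votes
    this yields 76.93 / 23.07.
    """
    total = tally.total
    if total < 1:
        raise ValueError("cannot summarize a tally with zero experts")
    options = list(tally.counts)
    base = {opt: int(Fraction(10000 * tally.counts[opt], total)) for opt in options}
    residue = 10000 - sum(base.values())
    for opt in sorted(options, key=lambda o: -tally.counts[o]):
        if residue <= 0:
            break
        base[opt] += 1
        residue -= 1
    return {opt: base[opt] / 100.0 for opt in options}
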