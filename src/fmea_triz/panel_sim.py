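"""Synthetic rater panels: simulation, reverse-fitting and rank stability.

The study data this package ships as its worked example consists of
printed per-cell fuzzy means, not raw questionnaires.  This module makes
every downstream stage testable anyway:

* ``simulate_panel`` draws a full multi-rater panel from per-cell
  categorical score distributions (seeded, bit-reproducible);
* ``fit_counts_to_fuzzy_mean`` reverse-fits an integer score-count vector
  whose fuzzified component means reproduce a printed mean triple, by
  exhaustive search over all compositions of n raters into the five scale
  levels (82,251 compositions at n=35 -- enumerated exactly);
* ``rank_stability`` resamples panels and tallies how often each failure
  lands on each rank, quantifying agreement between the fuzzy and
  traditional rankings under sampling noise.

Many count vectors can share the same 3-dp-rounded means, so fitted panels
claim mean-fidelity only: the fit is deterministic (first hit in
lexicographic order of the count vector) but not unique.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .fmea import (
    Factor,
    RatingPanel,
    RatingRecord,
    compare_rankings,
    rank_failures,
    score_panel,
)
from .fuzzy import DefuzzMethod, LinguisticScale, TriangularFuzzyNumber, default_scale

#: Per-component tolerance for fitting printed (3-dp rounded) means.
FIT_TOLERANCE = 5e-4

_DIST_TOL = 1e-9


@dataclass(frozen=True)
class PanelConfig:
    """Categorical score distributions per (failure, factor) cell.

    ``cells`` maps ``(failure_id, factor)`` to a length-5 probability
    vector over scores 1..5 (must sum to 1 within 1e-9).
    """

    n_raters: int
    cells: Mapping[tuple[str, Factor], tuple[float, ...]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        cells: dict[tuple[str, Factor], tuple[float, ...]] = {}
        for (fid, fac), probs in dict(self.cells).items():
            probs = tuple(float(p) for p in probs)
            if len(probs) != 5 or any(p < 0 for p in probs):
                raise ValueError(
                    f"cell ({fid}, {fac}): distribution must be 5 non-negative probabilities"
                )
            if abs(sum(probs) - 1.0) > _DIST_TOL:
                raise ValueError(
                    f"cell ({fid}, {fac}): distribution sums to {sum(probs)!r}, not 1"
                )
            cells[(str(fid), Factor(fac))] = probs
        object.__setattr__(self, "cells", cells)

    @classmethod
    def from_file(cls, path: str | Path) -> "PanelConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        cells = {
            (str(c["failure_id"]), Factor(c["factor"])): tuple(c["probs"])
            for c in data["cells"]
        }
        return cls(n_raters=int(data["n_raters"]), cells=cells,
                   seed=int(data.get("seed", 0)))


@dataclass(frozen=True)
class CountVector:
    """Score counts over the five scale levels for one cell."""

    counts: tuple[int, int, int, int, int]

    def __post_init__(self) -> None:
        counts = tuple(int(c) for c in self.counts)
        if len(counts) != 5 or any(c < 0 for c in counts):
            raise ValueError("count vector needs 5 non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return sum(self.counts)

    def scores(self) -> list[int]:
        """Expand to a sorted list of raw scores (score s repeated counts[s-1] times)."""
        return [s for s in range(1, 6) for _ in range(self.counts[s - 1])]


def simulate_panel(config: PanelConfig) -> RatingPanel:
    """Draw one record per rater per configured cell; identical seed, identical panel."""
    rng = np.random.default_rng(config.seed)
    records: list[RatingRecord] = []
    width = len(str(config.n_raters))
    for (fid, fac) in sorted(config.cells, key=lambda k: (k[0], k[1].value)):
        probs = config.cells[(fid, fac)]
        scores = rng.choice(np.arange(1, 6), size=config.n_raters, p=probs)
        for t, score in enumerate(scores, start=1):
            records.append(RatingRecord(f"r{t:0{width}d}", fid, fac, int(score)))
    return RatingPanel(records)


@functools.lru_cache(maxsize=8)
def _compositions(n: int) -> np.ndarray:
    """All compositions of n into 5 non-negative parts, in lexicographic order."""
    rows = [
        (n1, n2, n3, n4, n - n1 - n2 - n3 - n4)
        for n1 in range(n + 1)
        for n2 in range(n + 1 - n1)
        for n3 in range(n + 1 - n1 - n2)
        for n4 in range(n + 1 - n1 - n2 - n3)
    ]
    return np.array(rows, dtype=np.int64)


def fit_counts_to_fuzzy_mean(
    target: TriangularFuzzyNumber | Sequence[float],
    n: int,
    scale: LinguisticScale | None = None,
    tolerance: float = FIT_TOLERANCE,
) -> CountVector | None:
    """Find a count vector whose fuzzified means match ``target``; None if infeasible.

    The target may be a TFN or a raw (q, o, p) triple; triples violating
    the TFN ordering (or any composition search coming up empty) yield
    ``None`` rather than an exception.  The search is exhaustive over all
    compositions of ``n`` into five parts and returns the first hit in
    lexicographic order of the count vector, so results are deterministic.
    """
    if isinstance(target, TriangularFuzzyNumber):
        q, o, p = target.as_tuple()
    else:
        q, o, p = (float(x) for x in target)
        if any(not 0.0 <= x <= 1.0 for x in (q, o, p)):
            raise ValueError(f"target components must lie in [0, 1]: {(q, o, p)}")
        if not q <= o <= p:
            return None  # infeasible: violates TFN ordering
    scale = scale or default_scale()
    levels = np.array([lv.tfn.as_tuple() for lv in scale.levels])  # 5 x 3, score order
    comps = _compositions(int(n))
    means = comps @ levels / float(n)
    ok = np.all(np.abs(means - np.array([q, o, p])) <= tolerance, axis=1)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return None
    return CountVector(tuple(int(c) for c in comps[hits[0]]))


def panel_from_counts(
    counts: Mapping[tuple[str, Factor], CountVector],
) -> RatingPanel:
    """Assemble a RatingPanel from per-cell count vectors (synthetic raters)."""
    ns = {cv.n for cv in counts.values()}
    if len(ns) > 1:
        raise ValueError(f"cells have inconsistent rater counts: {sorted(ns)}")
    n = ns.pop() if ns else 0
    width = len(str(n))
    records: list[RatingRecord] = []
    for (fid, fac) in sorted(counts, key=lambda k: (k[0], k[1].value)):
        for t, score in enumerate(counts[(fid, fac)].scores(), start=1):
            records.append(RatingRecord(f"r{t:0{width}d}", fid, fac, score))
    return RatingPanel(records)


@dataclass(frozen=True)
class RankStabilityResult:
    """Rank frequencies per failure (fuzzy ranking) and fuzzy-vs-traditional taus."""

    rank_frequency: dict[str, dict[int, float]]
    taus: tuple[float, ...]

    @property
    def mean_tau(self) -> float:
        return float(np.mean(self.taus))


def rank_stability(
    config: PanelConfig,
    replicates: int,
    scale: LinguisticScale | None = None,
    method: DefuzzMethod | str = DefuzzMethod.CENTROID,
) -> RankStabilityResult:
    """Resample panels; tally fuzzy rank frequencies and fuzzy-vs-traditional tau."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    # independent child seeds below 2**31, derived deterministically
    seed_rng = np.random.default_rng(config.seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=replicates)
    fids = sorted({fid for fid, _ in config.cells})
    tallies: dict[str, dict[int, int]] = {fid: {} for fid in fids}
    taus: list[float] = []
    for rep_seed in child_seeds:
        rep_config = PanelConfig(config.n_raters, config.cells, seed=int(rep_seed))
        panel = simulate_panel(rep_config)
        scores = score_panel(panel, scale, method)
        fuzzy = {s.failure_id: s.rank for s in rank_failures(scores, "frpn")}
        trad = {s.failure_id: s.rank for s in rank_failures(scores, "traditional")}
        for fid, rank in fuzzy.items():
            tallies[fid][rank] = tallies[fid].get(rank, 0) + 1
        taus.append(compare_rankings(fuzzy, trad).kendall_tau)
    freq = {
        fid: {rank: count / replicates for rank, count in sorted(ranks.items())}
        for fid, ranks in tallies.items()
    }
    return RankStabilityResult(freq, tuple(taus))
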