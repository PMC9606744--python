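# fmea-triz

Fuzzy failure mode and effects analysis (Fuzzy-FMEA) with TRIZ-based
solution suggestion, for service-process risk engineering.

## The problem

Service managers — the bundled case study concerns combined medical and
elderly care (CMEC) institutions — need to decide which failure points in a
service process to fix first, and what kind of intervention to try. Crisp
FMEA asks a rater panel to score each failure mode's severity (S),
occurrence (O) and detectability (D) on a 1–5 Likert scale and ranks
failures by the risk priority number RPN = S × O × D. Likert judgments are
ambiguous, so this package implements the fuzzy variant: each score *s* is
mapped to a triangular fuzzy number (TFN) on [0, 1],

| score | level | TFN (q, o, p) |
|---|---|---|
| 1 | NI | (0, 0, 0.25) |
| 2 | LI | (0, 0.25, 0.5) |
| 3 | I | (0.25, 0.5, 0.75) |
| 4 | VI | (0.5, 0.75, 1) |
| 5 | EI | (0.75, 1, 1) |

the panel is aggregated component-wise, Q_ij = (1/n) Σ_t q_tij (likewise
O_ij, P_ij), each (Q, O, P) triple is defuzzified to a crisp X — by the
centroid X = (Q + O + P)/3 (default) or the trapezoidal-equivalence rule
X = (Q + 2O + P)/4 — and failures are ranked by the fuzzy risk priority
number

    FRPN_i = X_i(S) × X_i(O) × X_i(D)  ∈ [0, 1].

The top-ranked failures' causes are tagged with service-quality
determinants, translated to improving TRIZ engineering parameters, crossed
with the worsening parameters the organisation cares about (here: No. 22
loss of energy/costs, No. 36 system complexity), looked up in the TRIZ
contradiction matrix, and the suggested inventive principles are screened
by an expert roster. A service-blueprint model (customer / front-stage /
back-stage / support lanes with lines of interaction and visibility)
carries the upstream failure-point identification.

## Worked example

The bundled case study ships a six-entry failure register, two blueprint
scenarios, the published per-cell fuzzy rating means of a 35-member expert
panel (from which a mean-faithful synthetic panel is reconstructed), and
the TRIZ configuration. Run the full three-phase pipeline:

```sh
$ fmea-triz run --outdir out
1       F1      FRPN=0.293
2       F6      FRPN=0.234
3       F2      FRPN=0.228
4       F4      FRPN=0.207
5       F3      FRPN=0.188
6       F5      FRPN=0.173
screened principles: [25, 10, 27, 1, 28, 21, 4]
wrote out/risk_report.csv
wrote out/risk_report.md
wrote out/suggestions.json
wrote out/suggestions.md
```

Reading the output: F1 (human resource misallocation, defuzzified
S/O/D = 0.669/0.657/0.667) is the riskiest failure mode with
FRPN = 0.669 × 0.657 × 0.667 = 0.293; rehabilitation failures (F6) and
slow response (F2) follow. The top three failures' causes map to improving
parameters {26 amount of substance, 35 adaptability, 17 temperature,
9 speed}; crossed with worsening parameters {22, 36} and screened by the
case's expert roster, exactly seven inventive principles survive
(Self-Service, Preliminary Action, Cheap Short-Living Objects,
Segmentation, Replacement of Mechanical Systems, Rushing Through,
Asymmetry), each paired with one of the case's seven service-optimization
solutions in `out/suggestions.md`.

The same steps are available as a library:

```python
from fmea_triz import case_study, rank_failures, score_panel

panel = case_study.case_panel()          # synthetic, mean-faithful
register = case_study.failure_register()
ranked = rank_failures(score_panel(panel, failures=register))
print(ranked[0].failure_id, round(ranked[0].frpn, 3))  # F1 0.293
```

Other subcommands: `fmea-triz score`, `rank`, `triz suggest`,
`blueprint validate`, `blueprint export`, `simulate` (seeded panels from
per-cell score distributions), `fit-panel` (reverse-fit a panel to printed
fuzzy means) and `report`. See `fmea-triz --help`.

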