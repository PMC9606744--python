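# Methods

## Model and procedure

The package implements a three-phase service-risk procedure:

1. **Service process analysis.** The process is modelled as a service
   blueprint: actions in four lanes (customer, front-stage, back-stage,
   support), directed successor edges, and failure-point annotations tying
   actions to failure-mode ids. Validation enforces referential integrity,
   acyclicity within a scenario, and the line-of-interaction rule (an edge
   with exactly one endpoint in the customer lane must end in the
   front-stage lane — customers never interact directly with back-stage or
   support actions). Scenario (e.g. mild vs severe illness) is a stored
   tag, never inferred.

2. **Failure diagnosis (Fuzzy-FMEA).** Each rater scores each failure
   mode on severity, occurrence and detectability (1–5). Scores are mapped
   to triangular fuzzy numbers (TFNs) by the five-level linguistic scale,
   the panel is aggregated by the component-wise arithmetic mean, the mean
   TFN is defuzzified, and failures are ranked descending by
   FRPN = X(S)·X(O)·X(D). The detectability scale is oriented so that a
   higher score means detection only after the failure has occurred
   (worse); no re-orientation is applied.

3. **Solution suggestion (TRIZ).** Causes of the top-k failures (default
   k = 3) carry service-quality-determinant tags; a determinant map
   translates tags to improving engineering parameters; every
   (improving × worsening) pair is looked up in the contradiction matrix;
   the ordered union of suggested inventive principles is intersected with
   an expert screening roster. Screening is always an explicit roster —
   the package never scores principle relevance automatically.

## Defuzzification: centroid vs trapezoidal equivalence

Two rules are implemented for a TFN (q, o, p):

* **centroid** (default): X = (q + o + p)/3;
* **trapezoidal_eq4**: X = (q + 2o + p)/4, the triangle read as the
  degenerate trapezoid (q, o, o, p).

Both return o exactly on symmetric TFNs and always lie in [q, p]. They
differ on asymmetric inputs: on the case study's first severity row
(0.4286, 0.6786, 0.9000) the centroid gives 0.669 while the trapezoidal
rule gives 0.671. The case study's published crisp factor tables are
reproduced exactly (at 3 dp, all 18 cells) by the centroid and by no
setting of the trapezoidal rule, so the centroid is the default; selecting
`trapezoidal_eq4` logs a notice, and strict mode (`--strict`) turns that
notice into an error so regulated users must make the choice explicitly.

## Rounding and reporting conventions

Computation is full precision throughout; rounding happens only at the
reporting layer: half-up to 3 decimals for risk values, 2 decimals for
percentages. Expert-vote percentages are made to total exactly 100.00 by
flooring each percentage at 2 dp and crediting the leftover hundredths to
options in descending vote count — with 10 of 13 votes this yields
76.93 / 23.07 (plain half-up rounding would give 76.92 / 23.08).

Ranks are assigned descending by the chosen key with ties broken by
ascending failure id, so ranks are always a permutation of 1..N. The top
three ranks are flagged with an asterisk in reports (display only).

## Traditional vs fuzzy ranking

The traditional RPN is computed as the product of the three per-factor
arithmetic means of the raw scores (the standard crisp-panel reading);
other readings (mean of per-rater products) exist and are not provided.
The two keys need not order failures identically: each is a product of a
different increasing transform of the scores, and products do not preserve
order across non-comparable triples. On componentwise-dominated score
triples they provably agree (verified exhaustively in the test suite over
all ordered pairs of the 125 unanimous triples), but e.g. unanimous
(S,O,D) = (5,4,1) outranks (3,3,2) traditionally (20 > 18) while the fuzzy
key prefers (3,3,2) (0.0625 > 0.0573): the fuzzy scale compresses the top
of the range, down-weighting single extreme factors. This is a genuine
behavioural difference of the method, visible in the bundled case as a
rank swap between two failure modes, and is why `compare_rankings`
(Kendall tau, Spearman rho, disagreeing ids) is part of the surface.

## Synthetic panel reconstruction

The case study publishes per-cell fuzzy means, not raw questionnaires.
`fit_counts_to_fuzzy_mean` reverse-fits an integer count vector over the
five scale levels whose fuzzified component means match a target triple to
within 0.0005 per component (printed means are 3-dp rounded, so the true
per-component sums are recovered exactly: adjacent achievable means differ
by 0.25/35 ≈ 0.007 ≫ 0.001). The search enumerates all compositions of n
into five parts (82,251 at n = 35) and returns the first hit in
lexicographic order, making the fixture deterministic. Many compositions
share the same means, so the reconstruction claims **mean-fidelity only**:
aggregated means, defuzzified values, FRPNs and ranks are faithful;
individual ratings, rater covariance and any systematic bias of the real
panel are not represented. Passing tests therefore validate the
arithmetic pipeline, not distributional properties of the original data.
For the same reason the published traditional-RPN magnitudes are not
reproducible from printed data and are not asserted anywhere.

## Simulation and seeding

`simulate_panel` draws per-cell scores from categorical distributions with
`numpy.random.default_rng(seed)`; cells are visited in sorted order so
identical seeds give bit-identical panels. `rank_stability` derives one
child seed per replicate (below 2³¹) from the config seed, simulates,
ranks by both keys, and reports per-failure rank frequencies and the mean
Kendall tau between the fuzzy and traditional rankings. No global random
state is used anywhere.

## TRIZ assets

The parameter (39) and principle (40) registries ship complete. The
bundled contradiction matrix is deliberately sparse: it contains exactly
the eight cells used by the bundled case study, which are treated as
authoritative — `validate_matrix_assets` enforces registry sizes and those
cells verbatim, and the pipeline refuses to run on deviating assets. A
full user-supplied matrix in the same JSON/CSV cell format is accepted
everywhere; looking up an absent cell returns an empty suggestion with a
logged notice rather than an error. The determinant map ships only the
five case-study mappings (13→26, 5→35, 18→26, 7→17, 20→9) and is
user-extensible by config; no invented determinants are bundled. Whether
improving parameters are pooled across the top-k failures (default,
matching the case study) or queried per failure is a mode switch on
`suggest_principles`; both give the same raw union.

## Blueprint fixtures

The bundled mild- and severe-illness blueprints encode the case's lane and
failure-point structure (contact nursing staff; receive diagnostic,
therapeutic and rehabilitation services; front-stage request/arrive/
provide/rehabilitate; back-stage health assessment; severe-only referral
with ambulance coordination). F4 (testing equipment) is annotated only in
the mild scenario and F5 (referrals) only in the severe scenario; the
other four failure points appear in both and de-duplicate to six in total.
The exact arrow topology of the original diagrams is not fully recoverable
from text, so the fixtures claim structural fidelity at the
lane/failure-point level only.

## Degenerate inputs and error policy

Missing (failure, factor) cells are a hard error listing the missing
pairs — no imputation; partial panels must be subset explicitly. Untagged
causes and unmapped determinants fail naming the offending cause. Empty
rating lists, zero-expert tallies, empty worsening sets, diagonal matrix
queries and out-of-range scores/indices all raise with specific messages.
An empty blueprint validates with a warning. Infeasible reverse-fit
targets (including triples violating the TFN ordering) return an
infeasible result rather than raising.

## Problem sizes

The bundled case runs with 6 failure modes × 3 factors × 35 raters, a
13-expert tally, and 8 matrix cells; the reproduction script adds a
200-replicate rank-stability resampling. The whole pipeline is
milliseconds-scale; the reverse-fit enumeration is the dominant cost
(~1 s for all 18 cells, cached per panel size).

## Known limitations

* No rater weighting, factor weighting, fuzzy-rule-base (Mamdani) RPN, or
  TOPSIS/grey-relational ranking extensions.
* Only triangular fuzzy numbers; no trapezoidal-with-four-free-points or
  interval-valued hesitant variants.
* Solution narratives are human artifacts: the package maps principles to
  user-supplied solution text, it does not generate solutions.
* The synthetic panel reconstruction cannot recover rater-level structure
  (see above); conclusions about rater behaviour are out of scope.
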