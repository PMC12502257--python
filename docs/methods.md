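# Methods

This note documents the model implemented by `vmrasat`, the choices made
where the framework leaves the design open, and what the synthetic-data
machinery does and does not demonstrate.

## The assessment model

A catalog is a tree: functions → indicators → sub-indicators. Each
sub-indicator is pre-designated to one maturity tier and is the atomic unit
of both scoring and classification. Two profiles ship with the package:

| profile | functions | indicators | sub-indicators | tiers | scale |
|---|---|---|---|---|---|
| `vmra` | 8 | 13 | 235 (6/21/28/154/26 per tier) | Pre-bronze…Gold-plus | 1 / 0.5 / 0 |
| `who-gbt` | 9 | 13 | 268 | ML1…ML4 | 1 / 0.75 / 0.25 / 0 |

Each ladder also has a floor (`L0` / `ML0`) used only as a classification
result — it is never a designation tier. The veterinary scale deliberately
drops the Ongoing-implementation category and scores Partially implemented
at 0.5 rather than 0.75; requesting an out-of-scale rating is an error, not
a silent coercion.

Sub-indicator texts in the reference catalogs are structured placeholders.
The framework's published, testable content is structural — codes, tier
designations, counts, the rating scale and the threshold tables — and that
is what the reference catalogs reproduce exactly. The spread of the 268 WHO
sub-indicators across ML1–ML4 is not published; the skeleton uses a fixed
distribution (30/50/120/68) flagged non-normative in the catalog notes.
Likewise the critical and institution-mandatory sets are catalog data, not
engine constants: the reference catalog flags the six Pre-bronze items
(which are also institution-mandatory), the clinical-field-trials
requirement, and the first Gold item of each remaining function as a
placeholder critical set that users are expected to edit.

## Classification

For each designation tier the engine computes, over the *applicable*
(non-N/A) sub-indicators of the function, the implemented, in-process
(partial + ongoing) and not-implemented fractions, and tests them against
the active algorithm's threshold row (floor on implemented, caps on the
other two, lower tiers required at 100% unless the row pools its denominator
with the lower tiers, as the WHO ML2 rule does). The achieved tier is the
top of the maximal consecutive run of passing tiers starting at the bottom.

Numerical choices, all load-bearing:

- **Exact rationals.** Thresholds and observed fractions are
  `fractions.Fraction`; floats appear only at render time. 19/20 meets a
  95% floor exactly; 18/20 does not. Floors use ≥, caps use ≤.
- **Caps are independent.** The Gold row's 85% floor, 15% in-process cap
  and 5% not-implemented cap are separate constraints, not a partition
  (they sum to 105%); "up to" reads as a cap.
- **"N/A" table cells are zero caps** — Bronze and Silver admit no
  not-implemented items at all, Pre-bronze admits neither partials nor
  not-implemented.
- **Empty tiers pass vacuously** (0 applicable items ⇒ no constraint). A
  consequence, flagged by a runtime warning, is that an all-not-applicable
  assessment classifies to the top tier; real assessments always have
  applicable items.
- **Missing responses count as Not implemented** (with a warning):
  conservative, and immune to score inflation by omission.
- **Per-tier vs pooled denominators.** The veterinary rows each constrain
  their own tier's pool; the WHO ML2 row pools ML1+ML2. The WHO ML1
  flexible rule is not published separately and is taken as 100% of ML1
  (identical to strict). Whether veterinary Bronze should pool PB+B is
  moot: Pre-bronze must be fully implemented anyway, and then the pooled
  and per-tier readings coincide.
- **Restricted flexibility** = the flexible thresholds plus: every
  applicable critical sub-indicator designated at or below the candidate
  tier is Implemented. It therefore always lands between strict and
  flexible (a property the test suite checks on seeded random assessments).
- **Qualifiers.** Results are reported as e.g. `Silver (flexible)`; when
  the strict algorithm reaches the same tier the `strict` qualifier is
  preferred as the stronger statement. The floor tier is always qualified
  with the requested algorithm.
- **Institution level.** The institution tier is the minimum over function
  tiers, additionally capped at the highest tier whose
  institution-mandatory sub-indicators (at or below it) are all
  Implemented. The published description of institution-level mandatory
  items is a sketch; this cap rule is our interpretation, and the
  `mandatory_failures` list names the items that actively constrain.

## Development planning

`extract_gaps` lists every applicable sub-indicator below Implemented,
ordered tier-ascending, critical first, then by id — the framework does not
prescribe a prioritisation, so this ordering is our documented choice, and
the "suggested action" strings are templates, not domain guidance.
`upgrade_path` computes a smallest set of single-item rating upgrades that
lifts the institution to a target tier: upgrades forced by any feasible
plan (fully implementing tiers a higher row requires at 100%, critical
items under restricted flexibility, mandatory items) are applied first, and
each remaining threshold row is then solved exactly on its own pool by
enumerating move counts in increasing total. Because distinct rows
constrain disjoint pools (and the WHO ML2 overlap is neutralised by ML1's
own 100% row), the per-pool optima sum to a global optimum; the test suite
cross-checks this against an exhaustive subset search on small catalogs.

## Synthetic data and what the tests show

The generator produces one-function catalogs with requested per-tier counts
and assessments drawn from an explicit rating mix, all deterministic per
seed (`random.Random`). `gen_assessment_at_tier` constructs an assessment
hitting a target tier exactly: tiers below the target fully implemented,
the target tier filled to its exact implemented floor (critical/mandatory
items first, remainder in-process), every tier above rated Not implemented.
On multi-function catalogs the recovery guarantee is at institution level,
since functions with no items above the target pass the higher tiers
vacuously (in the reference catalog only VRS holds Pre-bronze items).
`oracle_classify` is an independent straight-line re-implementation used
purely as a cross-check.

The generator emulates rating patterns only as i.i.d. draws; it does not
model correlated capability across indicators, evidence quality, or
assessor behaviour. Passing tests therefore demonstrate the *arithmetic and
logic* of the scheme — threshold boundaries, algorithm ordering,
N/A-invariance, plan minimality — not anything about how real agencies
score.

Problem sizes used by the default suite and the acceptance script (chosen
as the smallest pools that exercise each boundary exactly): 20-item Bronze
and 30-item Silver pools, 100-item Gold/Gold-plus/ML3 pools, the pooled
40-item ML1+ML2 set; 200 seeded assessments per profile × algorithm for the
property suites; exhaustive upgrade-search comparisons on ≤8-item catalogs.

## Known limitations

- Sub-indicator texts and fact sheets are placeholders; the package is an
  engine, not a source of regulatory guidance.
- The critical and institution-mandatory reference sets are placeholders
  pending authoritative lists; results under restricted flexibility and the
  institution cap depend on catalog data the user supplies.
- Single-assessor, single-time-point model: no evidence management, no
  longitudinal tracking, no peer-review workflow.
- Scores weight all sub-indicators equally within a function; no published
  weighting exists, and none is implemented.
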