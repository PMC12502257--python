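# vmrasat

A maturity self-assessment and benchmarking engine for regulators of
veterinary medicines — and, more generally, for any tiered
capability-assessment framework built from functions, indicators and
sub-indicators.

National regulatory agencies (NRAs) for veterinary medicinal products vary
widely in capability, and unlike the human-medicines sector (covered by the
WHO Global Benchmarking Tool, GBT) the veterinary sector has lacked a common
self-assessment scheme. `vmrasat` implements such a scheme as a reusable
engine: a catalog describes the framework (8 regulatory functions, 13
indicators, 235 sub-indicators each pre-designated to a maturity tier —
Pre-bronze, Bronze, Silver, Gold, Gold-plus), an assessment records one
rating per sub-indicator, and the engine classifies each function and the
institution to a maturity tier, produces an Institutional Development Plan
(IDP) from the gaps, and renders reports. The WHO GBT profile (9 functions,
268 sub-indicators, ML1–ML4) is included as a second built-in configuration,
and custom catalogs can be supplied as YAML.

## The model

Each sub-indicator *s* is rated on a sliding scale and scored
`x_s ∈ {1, 0.5, 0}` for the veterinary profile (Implemented, Partially
implemented, Not implemented; Not applicable is excluded from all
arithmetic) or `x_s ∈ {1, 0.75, 0.25, 0}` for the WHO profile (which adds
Ongoing implementation). For a function *F* and designation tier *T*, let
`n_T` be the applicable sub-indicators of *F* designated to *T*, and
`i_T, p_T, u_T` the counts Implemented, in-process (partially/ongoing), and
Not implemented. Tier *T* is **met** under the *flexible* algorithm when

```
i_t = n_t            for every designation tier t < T     (lower tiers full)
i_T / n_T ≥ m_T      (implemented floor)
p_T / n_T ≤ c_T      (in-process cap)
u_T / n_T ≤ d_T      (not-implemented cap)
```

with per-tier parameters (veterinary profile): Pre-bronze `m=100%`;
Bronze `m=95%, c=5%, d=0`; Silver `m=90%, c=10%, d=0`;
Gold `m=85%, c=15%, d=5%`; Gold-plus `m=80%, c=20%, d=10%`.
The WHO profile uses ML2 `m=95%` over the *pooled* ML1+ML2 set,
ML3 `m=90%`, ML4 `m=80%`, all with `d=0` (the remainder must be in process
of implementation). The *strict* algorithm sets `m=100%, c=d=0` at every
tier; *restricted flexibility* (veterinary profile only) adds the condition
that every sub-indicator flagged **critical** at or below *T* is
Implemented. The achieved tier is the top of the maximal consecutive run of
met tiers from the bottom; the institution's tier is the minimum over
functions, further capped by institution-mandatory sub-indicators. All
comparisons use exact rational arithmetic, so 19 of 20 meets a 95% floor
exactly.

## Worked example

Simulate an assessment of the bundled reference catalog and classify it:

```
$ vmrasat simulate --seed 42 \
    --mix "IMPLEMENTED=0.7,PARTIALLY_IMPLEMENTED=0.2,NOT_IMPLEMENTED=0.1" \
    --out-catalog cat.yaml --out-responses resp.csv
$ vmrasat classify --responses resp.csv --algorithm flexible
VRS: Below Pre-bronze (flexible)
VMA: Bronze (strict)
VPV: Bronze (strict)
VMC: Pre-bronze (strict)
VLI: Bronze (strict)
VRI: Bronze (strict)
VLT: Silver (strict)
VBR: Bronze (strict)
institution: Below Pre-bronze (flexible)
```

Each line is one regulatory function and its achieved tier. The qualifier
names the algorithm that supports the tier; where the strict algorithm
reaches the same tier as the requested flexible one, the stronger strict
qualifier is shown. Here the Regulatory Systems function (VRS) fails
Pre-bronze — one of the six minimum-operating-capability items is not
implemented — which also drags the institution to the floor, because the
institution can never outrank its weakest function. The development plan
pinpoints the cheapest way up:

```
$ vmrasat idp --responses resp.csv --target BRONZE | sed -n '/Minimal/,$p'
## Minimal upgrade path to Bronze (3 upgrade(s))

VMC-B-02 -> IMPLEMENTED
VRS-B-01 -> IMPLEMENTED
VRS-PB-05 -> IMPLEMENTED
```

i.e. implementing the missing Pre-bronze item (published agency contacts)
plus one Bronze item each in VRS and VMC lifts the whole institution to
Bronze; everything else already satisfies the flexible thresholds.
`vmrasat report --format json|csv|markdown` renders the full report and
`vmrasat validate` checks a catalog file against the framework invariants.

The same operations are available as a library:

```python
import vmrasat as v

catalog = v.reference_catalog("vmra")          # 235 sub-indicators
assessment = v.read_responses_csv("resp.csv", catalog)
result = v.classify_institution(assessment, catalog, "flexible")
print(result.institution_tier)
```

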