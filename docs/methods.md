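# Methods

This note documents the models, numerical choices and design decisions
behind `gemaudit`, and what its synthetic fixtures do and do not
establish.

## Model representation and I/O

Models are held in plain dataclasses (`Metabolite`, `Reaction`, `Gene`,
`Model`): stoichiometry as metabolite → coefficient maps (negative =
substrate), flux bounds in mmol·gDW⁻¹·h⁻¹, annotations as namespace →
identifier-list maps, SBO terms as `SBO:0000NNN` strings. SBML reading
and writing is delegated to cobrapy (SBML L3 + fbc primary; legacy L2
documents with kinetic-law bound parameters are accepted; notes-encoded
bounds are not mapped). Missing bounds default to ±1000, the community
convention, and are flagged as warnings by the structural validator.
Structural validation itself works on the raw document with libsbml:
read/consistency errors plus explicit checks for duplicate ids, dangling
species references, undeclared compartments and missing fbc bounds.
Problems are returned as issues, never raised.

**Boundary detection** (first match wins): SBO term 627/628/632, then
the single-metabolite criterion, then the `EX_`/`DM_`/`SK_` id prefix.
**Biomass detection**: SBO 629, then "biomass" in id or name, then the
objective as fallback.

**Sorted YAML.** The canonical serialization sorts all element lists by
id and all mapping keys, renders integral floats as integers and other
floats with 10 significant digits, so semantically identical models are
byte-identical files; the model digest is the SHA-256 of that text.

## Stoichiometric consistency

Consistency is decided by the classic LP certificate: maximize `Σ yᵢ`
s.t. `Sᵀ_int·m = 0`, `yᵢ ≤ mᵢ`, `yᵢ ∈ [0,1]`, `mᵢ ∈ [0, M]`. The LP
relaxation (continuous `y`) is used instead of a MILP; on networks of
the size exercised here its optimum identifies the same unconserved set,
which an exhaustive subset-feasibility oracle verifies in the test
suite. **Internal columns exclude boundary reactions and the biomass
pseudo-reaction**: a biomass drain destroys mass by design, and
including it would mark essentially every growing model inconsistent.
The same exclusion applies to the mass/charge balance report.

Balance verdicts are three-valued: *balanced*, *unbalanced*,
*undetermined* (some participant lacks a usable formula or charge).
Undetermined reactions count against the balance metric — missing
formulas genuinely prevent a model from being shown mass-balanced — but
are listed separately.

## Energy-generating cycles

For each configured energy couple (NTP hydrolysis couples
`ntp + h2o → ndp + pi + h`; redox couples `reduced → oxidized + h`;
acetyl-CoA hydrolysis), all boundary reactions are closed, a temporary
dissipation reaction is added and maximized. Species are matched by
compartment-stripped base id (BiGG-style, alias table configurable),
preferring the cytosol when several compartments host the full couple.
A couple absent from the model leaves that test unscored. Which energy
metabolites to probe is a package decision (the area's convention names
ATP and redox cofactors but no exhaustive list); the dictionary is
configurable.

## Blocked reactions, orphans, dead ends

"Permanently blocked" is interpreted under the most permissive medium:
all boundary reactions opened to ±1000, then FVA (via cobrapy, one
process) with zero-flux tolerance `ε_flux`. Orphans and dead ends are
topological: a metabolite is an orphan (dead end) if no non-boundary
reaction can have it as net product (substrate) in an allowed direction.
Boundary pseudo-reactions deliberately do not count as producers or
consumers.

## Biomass battery

The weight check computes `Σ_substrates |S|·MW/1000 − Σ_products
|S|·MW/1000` in g·mmol⁻¹ from IUPAC conventional atomic weights
(vendored, 3 decimals) and accepts `|weight − 1| ≤ 10⁻³` (configurable).
Growth is the FBA optimum of the biomass reaction, in the default
(encoded) medium and in a complete medium with every exchange lower
bound opened to −1000; "different conditions" means exactly these two,
with further media supplied through the experimental module. Precursor
producibility adds a temporary demand per biomass substrate and
maximizes it. The growth-associated maintenance couple (ATP + H₂O) is
excluded from the precursor list: those moieties are conserved pools
with no de novo route, so an isolated demand can never carry flux even
in a perfectly healthy model. The "direct precursors" notion is not
operationally standardized; here it lists substrates with no internal,
non-transport producing reaction, and stays informational (unscored).

## Annotation battery

The identifier registry is a vendored subset of identifiers.org
patterns (8 metabolite, 7 reaction, 4 gene namespaces), applied with
full-match semantics and overridable per class from the configuration
file. All registry namespaces are scored equally within the annotation
section — the community does not rank them. Primary-namespace
consistency strips the trailing `_<compartment>` from metabolite ids
and reports the best-covering namespace. SBO expectations by role:
metabolite 247, gene 243, metabolic reaction 176, exchange 627, demand
628, sink 632, biomass 629.

## Experimental validation

Media tables (`exchange, lower, upper`), growth tables
(`medium, growth`) and essentiality tables (`gene, essential`) in
csv/tsv/xls/xlsx are named by a YAML manifest (schema in the module
docstring — it is this package's own contract). Media apply on a
closed-uptake baseline (all exchange lower bounds zeroed first) so each
medium is self-contained and portable across models. Growth predictions
are FBA optima compared against `ε_growth`; essentiality predictions
disable every reaction whose GPR evaluates false under the knockout
(grammar: `or` over `and` over parenthesized factors, case-insensitive)
and compare the optimum against the same threshold. Outcomes report the
confusion matrix, accuracy and Matthews correlation; unknown genes,
media or exchanges make individual records unevaluable rather than
failing the run.

## Scoring

Within a section: `score = Σ w_t·metric_t / Σ w_t × 100` over scored
tests; overall: `Σ w_s·section_s / Σ w_s`. Defaults — sections:
consistency 3, annotation/basic/biomass/experimental 1; tests:
stoichiometric consistency 3, SBO coverage 2, all else 1. These numbers
are this package's concretization of the qualitative rule that
consistency and SBO typing matter more than cross-reference
completeness; all of them are configurable, and unscored tests are
excluded and listed. An errored test is captured as unscored; the suite
never aborts on a loadable model.

## Numerical constants

| constant | default | meaning |
|---|---|---|
| `M` | 1000 | upper bound on conservation masses `m` |
| `ε_y` | 1e-6 | conservation-indicator threshold (unconserved iff `y ≤ ε_y`) |
| `ε_flux` | 1e-6 | zero-flux tolerance (blocked, EGC, precursors) |
| `ε_growth` | 1e-6 h⁻¹ | growth/no-growth threshold |
| biomass tolerance | 1e-3 g·mmol⁻¹ | weight-consistency band |
| open bound | 1000 | bound used when opening/closing exchanges |

All chosen to sit well above LP solver noise and below any meaningful
biological signal; all overridable via the YAML config.

## The synthetic fixtures, and what a green test establishes

`make_textbook_model` builds a deterministic ~20-metabolite aerobic toy
cell (glucose uptake → lumped glycolysis → respiration-driven ATP
synthesis → alanine synthesis → biomass). It is consistent, balanced,
fully annotated, GPR-complete, EGC-free and growth-positive *by
construction*, with real molecular formulas and charges so the balance
arithmetic is exact and the biomass coefficients solve
`Σ c·MW = 1000 g/mol` exactly. Ground truth in its manifest — FBA
optima, blocked set, unconserved set, orphans/dead ends, essential
genes — is computed by deliberately naive scipy-linprog oracles
(per-metabolite feasibility LPs, exhaustive two-LP FVA, exhaustive
single-knockout scan), not by the production code paths, so
manifest-vs-suite comparisons are genuine cross-checks. Thirteen
plantable defect kinds cover the four test areas; each planting records
exactly which tests must degrade and which element ids they must list.

Limits: the fixtures are desk-scale (tens of reactions, two
compartments, one objective). They do not emulate genome-scale size,
multi-compartment eukaryote structure, degenerate alternate optima at
scale, or the statistical texture of published model collections — a
green suite establishes the correctness of the algorithms and
bookkeeping, not performance or discrimination on 1000+-reaction
reconstructions. Gene ids are UniProt-shaped so the namespace-
consistency metric has a well-defined perfect answer; real models often
use locus tags that match no registry pattern, which this fixture does
not represent. The random networks used for oracle equivalence are
unannotated and exercise only the LP machinery.

## Known limitations

* The consistency LP identifies unconserved metabolites but not minimal
  correction sets; thermodynamic (loop-law) analysis is out of scope.
* SBML writing is provided only for the fixture generator's output;
  the tool does not edit models.
* Duplicate metabolite/reaction detection and reaction-directionality
  plausibility checks are not part of the battery.
* Essentiality uses a hard `ε_growth` threshold, not a
  fraction-of-wild-type criterion; both appear in the literature.
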