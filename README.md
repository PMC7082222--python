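# gemaudit

Quality control for genome-scale metabolic models (GEMs).

Constraint-based reconstructions are exchanged as SBML Level 3 files with
the flux-balance-constraints (fbc) package, but there has been no
standardized way to judge whether such a model is formally correct,
thermodynamically sane and well annotated before it is published or
reused. `gemaudit` reads an SBML3FBC (or legacy SBML) model, runs a
battery of consensus tests in four areas — **annotation**, **basic**,
**biomass** and **stoichiometric consistency** — optionally validates the
model against experimental growth and gene-essentiality data, condenses
the per-test metrics into a weighted overall score, and renders
snapshot / diff / history reports for peer review and iterative
reconstruction.

It is aimed at model builders who want a benchmark while curating, and at
reviewers and users who need a quick, reproducible quality summary of a
published model.

## The tests at the core

With `S` the stoichiometric matrix (rows = metabolites, columns =
reactions) and `v` the flux vector bounded by `lb ≤ v ≤ ub`:

* **Stoichiometric consistency.** A network is consistent iff there are
  strictly positive metabolite masses `m` with `Sᵀ_int·m = 0` over the
  internal (non-boundary, non-biomass) columns. The certificate LP
  maximizes `Σᵢ yᵢ` subject to `Sᵀ_int·m = 0`, `yᵢ ≤ mᵢ`, `yᵢ ∈ [0,1]`,
  `mᵢ ∈ [0,M]`; metabolites whose indicator stays at zero are
  *unconserved* — mass is created or destroyed through them.
* **Mass/charge balance.** Per internal reaction, the net elemental
  imbalance `Σᵢ Sᵢⱼ·countᵢ(e)` and net charge `Σᵢ Sᵢⱼ·zᵢ`; reactions with
  incomplete formula/charge data are *undetermined* and count against the
  metric.
* **Energy-generating cycles.** All boundary reactions closed, a
  dissipation reaction (e.g. `atp + h2o → adp + pi + h`) added and
  maximized; any positive optimum means ATP or a redox cofactor is
  produced from nothing.
* **Blocked reactions, orphans, dead ends.** Flux variability analysis
  under the fully open medium flags reactions that can never carry flux;
  topological scans flag metabolites never produced (orphans) or never
  consumed (dead ends) by any allowed reaction direction.
* **Biomass.** Biomass reaction detection, the `1 g·mmol⁻¹` weight
  convention (`Σ |Sᵢⱼ|·MWᵢ/1000`), FBA growth in default and complete
  media, and per-precursor producibility.
* **Annotation.** MIRIAM-style cross-references checked against a
  vendored identifiers.org pattern registry, primary-namespace
  consistency of native ids, and SBO-term coverage per component class.

Scores: each section is the weighted mean of its test metrics × 100; the
overall score is the weighted mean of sections. Consistency (weight 3)
and SBO coverage / stoichiometric consistency (per-test weights 2 / 3)
count more than plain cross-reference completeness; every weight is
configurable.

## Worked example

The package ships a deterministic fixture generator (a ~20-metabolite
aerobic toy cell) so everything can be tried without downloads:

```bash
gemaudit fixture --kind healthy --seed 0 --out healthy.xml
gemaudit fixture --kind strip_gpr --seed 0 --out nogpr.xml
gemaudit run healthy.xml --out healthy.json
gemaudit run nogpr.xml --out nogpr.json
```

prints

```
model textbook_0: overall score 100.0/100
  annotation      100.0  (weight 1)
  basic           100.0  (weight 1)
  biomass         100.0  (weight 1)
  consistency     100.0  (weight 3)
model textbook_0: overall score 99.4/100
  annotation      100.0  (weight 1)
  basic            96.4  (weight 1)
  biomass         100.0  (weight 1)
  consistency     100.0  (weight 3)
```

The healthy fixture is consistent, balanced, fully annotated and grows
(100/100 by construction); stripping GPR rules from three reactions
drops exactly the basic-section GPR metric (9 of 12 non-boundary
reactions still carry a rule → 96.4). Reports:

```bash
gemaudit snapshot healthy.json --html healthy.html
gemaudit diff healthy.json nogpr.json --html diff.html
gemaudit history nogpr.json healthy.json --ordered --html history.html
gemaudit validate healthy.xml
```

`gemaudit run MODEL.xml --yaml-out model.yml` additionally writes the
model in a canonical sorted-YAML form in which semantically identical
models are byte-identical — made for line-by-line version-control diffs.

Experimental data (growth media, growth outcomes, gene essentiality in
csv/tsv/xls/xlsx, listed in a YAML manifest) can be supplied with
`--experiments manifest.yml`; predictions are made by FBA and GPR-aware
single-gene knockouts and summarized as a confusion matrix with accuracy
and Matthews correlation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

rebuilds the textbook fixture from the seed, round-trips it through
SBML, runs the full battery on the healthy model and on all thirteen
planted-defect variants (checking each degrades exactly the tests its
manifest names), sweeps the consistency LP and the blocked-reaction FVA
against brute-force oracles on random networks, and writes the JSON
summary to `--out`. Progress is logged to stderr.
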