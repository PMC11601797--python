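# Methods

This note documents the models and procedures implemented in
`htscurate`, the assumptions behind them, the knobs that matter, and the
limits of what the synthetic test harness demonstrates.

## The curation model

A raw HTS deposit is modeled as a set of compound records (id, isomeric
SMILES, standard InChI, per-assay outcomes in {active, inactive,
inconclusive, untested}) plus a DAG of assays: primary screens at the
roots, confirmatory screens validating primary actives, counter screens
detecting off-target activity. The pipeline applies ten stages in a
fixed order — dedup, hierarchy, parse, inorganic, mixture, neutralize,
aromatize, PAINS, druglikeness, flag review — attributing every
exclusion to the first failing stage and conserving counts at each step
(`n_in = n_out + n_excluded`, checked at run time).

**Deduplication** groups records that collide on *any* of three keys —
compound id, RDKit-canonical isomeric SMILES, or standard InChI — via
union-find. Groups with identical outcome vectors keep the
lexicographically smallest id; groups with conflicting outcomes are
excluded entirely. Arbitrarily picking a winner among contradictory
measurements would inject label noise of exactly the kind the pipeline
exists to remove.

**Hierarchical labels.** A compound is finally *active* iff it is
active in a primary screen, active in a confirmatory screen downstream
of that primary, and not active in any downstream counter screen.
Primary-inactives are final inactives. Three dispositions drop a record
instead of labeling it: counter-screen actives (off-target activity is
not evidence of target inactivity), records with no primary result, and
— under the default `unconfirmed_policy="drop"` — primary actives that
were never confirmed. The primary threshold in real campaigns is set
loosely, so an unconfirmed primary active is ambiguous, not a negative;
`unconfirmed_policy="inactive"` implements the alternative reading. A
primary screen with no confirmatory screens beneath it confirms itself.

**Stage order and the inorganic stage.** At the whole-record level the
inorganic stage passes any multi-component record with at least one
organic component, because component-level salvage is the next stage's
job: a salt entry like `CCO.[Na+].[Cl-]` must reach mixture resolution,
which strips the counter-ions and keeps the ethanol. Applied to single
molecules, the rule is strict: at least one carbon, and no element
outside {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}. This is a
pragmatic approximation — CO2 and carbonates pass the carbon rule — and
is documented as such.

**Mixture resolution**, in order: identical components collapse to one;
if the closest pair of distinct components lies within
`mixture_mw_tolerance` (default 5 Da, average atomic masses) the record
is discarded as ambiguous, since the deposited measurements cannot be
assigned to a component with confidence; otherwise components are
filtered for organic character and druglikeness — a unique survivor is
kept, zero survivors drop the record, several survivors keep the
heaviest under an audit flag.

**Neutralization** uses the atom-local rule: any atom with formal
charge whose bonded neighbors carry no opposite charge is zeroed, with
hydrogen counts adjusted. Internally compensated groups (nitro,
N-oxides, betaines) are untouched because their charges have charged
neighbors. The result is revalidated; a failure keeps the original
structure under a flag rather than silently corrupting it.

**PAINS filtering** uses the three published catalog families shipped
with RDKit, exposed under the interference-layer names
`promiscuity` (family A), `optical_interference` (family B) and
`other_interference` (family C). This mapping is this package's own
reimplementation choice; the families are enabled individually so an
auditor can see which layer fired.

**Druglikeness** is Lipinski's Rule of Five over MW > 500 Da,
Crippen logP > 5, donors > 5, acceptors > 10. The default tolerates one
violation (Lipinski's original formulation); `ro5_max_violations=0`
gives the strict variant.

**Expert verification** is realized as an audit trail, not an
automated judge: suspect records (non-isomeric SMILES next to a stereo
InChI, nonstandard InChI prefixes, SMILES/InChI regeneration
mismatches, multi-survivor mixtures) carry flags through the pipeline
and are listed for human review; `strict=True` turns flags into
exclusions at the final stage.

## Early-recognition metrics

All four metrics consume only the ranking induced by the scores, so
they are invariant under strictly monotone score transformations.

**logAUC[0.001, 0.1].** The ROC curve is built with tie-grouped
thresholds (tied scores form one straight segment); TPR is linearly
interpolated at the window boundaries and each linear-in-FPR segment is
integrated against d(log10 FPR) in closed form, then normalized by
log10(0.1/0.001) = 2. Under the identity ROC the closed form gives
(0.1 − 0.001)/(2 ln 10) ≈ 0.0215, the floor a score-independent
classifier earns; a perfect ranking gives 1. The restricted window
concentrates the measure where a prospective campaign actually reads
the list.

**BEDROC** follows the Truchon–Bailey formulation with α = 20 by
default (≈80% of the weight in the top 1/α of the list); α is printed
in every report because BEDROC values are not comparable across α.

**EF_k** is the active fraction among the top k (default 100) divided
by the library's active fraction; **DCG_k** is binary-relevance
discounted cumulative gain, base-2 logarithm, rank 1 undiscounted.

Ties are broken by input order with a warning by default; an
`average_pessimistic` policy ranks actives last within each tie block
for conservative audits. Overall ROC-AUC is deliberately relegated to a
debug helper: it averages performance over the inactive bulk nobody
will ever test.

## Split schemes

**Adapted cross-validation** shuffles ids once (seeded) into k = 5
near-equal folds; tuple t uses fold t as test, fold (t − 1) mod k as
validation, and the rest as training. Every compound is tested exactly
once while only five models are trained — the compromise between a
single held-out split and full nested CV.

**Scaffold split** bins compounds by generic Bemis-Murcko framework
(ring systems plus linkers, atom/bond types retained; acyclic molecules
share the `""` bin). Bins above 10% of the library are forced into
training — a dominant scaffold in validation or test would make the
split trivially easy or trivially hard — and the remaining bins are
assigned greedily, in descending size with ties broken by scaffold
string, to whichever partition is furthest below its 3:1:1
train:validation:test target. The deterministic greedy order was chosen
over seeded shuffling of bins: it achieves the closest attainable
proportions and makes the split a pure function of the data, with the
seed recorded for provenance. The achievable proportions are quantized
by bin sizes; with a forced big bin the training fraction exceeds 60%
by construction.

## Graph featurization

Node features use a fixed 28-slot schema (element one-hot over 11
symbols including `other`, degree one-hot 0–5+, charge sign one-hot,
hybridization one-hot S/SP/SP2/SP3/other, aromaticity, attached-H
count, ring membership — see `representation.py`). The slot layout is
this package's own documented schema, versioned so downstream models
can detect changes. 2D graphs take covalent bonds as edges with
bond-type/ring edge features; 3D graphs connect all atom pairs within
6 Å (closed interval — the boundary is an edge), storing coordinates
verbatim under `pos`. Heavy atoms only by default. Conformer input is
pluggable (any V2000 SDF); no conformer generation or minimization is
performed here.

## The campaign simulator

`synthetic` emulates the data setting the pipeline is built for: n =
2000 compounds by default, a 0.5% true hit rate, a loose primary
threshold (30% false-positive rate on inactives, 1% false-negative rate
on actives), confirmatory screens run only on primary actives and
reporting ground truth, and a counter screen firing on 10% of confirmed
actives. Artifacts are planted at exact counts (20 duplicate CIDs, 20
ambiguous mixtures, 30 salt adducts, 30 charged species, 15 PAINS
matches, 15 Rule-of-Five violators by default), all on truly inactive
compounds, so structural exclusions never intersect the active set and
noiseless recovery is exact. Planted duplicates inherit their source
record's simulated outcomes — the same substance measured in the same
assay — which keeps duplicate groups outcome-consistent.

Molecules are assembled from a hand-curated vocabulary (~2,200 distinct
products of aromatic/aliphatic cores and small substituents, each
verified at build time to pass every structural filter; catechol
derivatives for the PAINS series; long alkanes for Ro5 violators;
alkyl carboxylates/ammoniums for charged species). This makes each
record's fate provable by construction, which is what the exact
per-stage oracle `expected_curation_counts` exploits: it replays each
record's fate from its planted tag and simulated outcomes alone, never
touching the pipeline's chemistry.

What the simulator does **not** model — and hence what passing tests do
not show about real deposits: realistic chemical diversity (the
scaffold distribution is narrow and benzene-heavy), dose-response
values, correlated assay noise, plate/batch effects, stereochemistry-
only duplicates, tautomers, or parsing pathologies beyond simple syntax
errors. Confirmatory noise is not parametrized (the screen reports
truth); counter-screen cross-reactivity is independent Bernoulli.

## Numerical choices

- Molecular weights use average atomic masses (RDKit `MolWt`).
- logAUC segment integration is closed-form per ROC segment; the test
  oracle integrates the step ROC independently and the two agree to
  1e-9.
- BEDROC is clamped to [0, 1] against floating-point overshoot at the
  extremes.
- Percent-active displays round to three decimals, matching the
  conventional reporting precision.
- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; identical seed + input implies byte-identical
  outputs (tables are written sorted by compound id).
- Degenerate inputs fail loudly: all-active or all-inactive label
  vectors, NaN scores, lists shorter than k, hierarchies with cycles or
  parentless confirmatory screens, outcome columns not declared in the
  hierarchy.

## Problem sizes used in the validation suite

The shipped tests and `scripts/acceptance.py` run campaigns of 400–2,000
compounds, Monte-Carlo metric calibration with 200 replicates of
n = 100,000 rankings at 1% actives, exhaustive metric-monotonicity
checks for all label placements at n ≤ 8, 1,000 randomized
metric-oracle instances at n ≤ 500, and 200–1,000 random point clouds
(n ≤ 50) for the distance-graph oracle. These sizes were chosen as the
smallest that make the statistical checks sharp (binomial error well
below the asserted tolerances) while keeping the suite quick to run.

## Known limitations

- The inorganic rule is a carbon-presence heuristic; CO2-like inorganic
  carbon compounds pass it.
- The PAINS layer↔family mapping is a labeling convention, not a claim
  about the original three-layer taxonomy.
- SMILES/InChI consistency checking compares RDKit-regenerated InChI
  strings; divergent but chemically equivalent representations
  (e.g. differing tautomer conventions) are flagged for a human, not
  auto-resolved.
- The 28-slot feature schema is one defensible choice among many;
  models trained on it are not comparable to models trained on other
  featurizations.
- No live retrieval from compound databases: the record schema mirrors
  a PubChem-style deposit, but network access is explicitly out of
  scope.
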