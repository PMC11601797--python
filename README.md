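# htscurate

Hierarchical curation of high-throughput-screening (HTS) data and
early-recognition evaluation for virtual screening.

## The problem

Raw HTS deposits are noisy in ways that quietly poison machine-learning
benchmarks: the primary screen's activity threshold is set loosely (to
avoid false negatives), so most called actives are false positives;
compound tables contain duplicate entries under different ids,
unresolved mixtures and salts, charged species, pan-assay interference
compounds (PAINS), and molecules nobody would ever advance. And once a
model is trained, the usual ROC-AUC rewards ranking quality among the
inactive bulk that no prospective campaign will ever test.

`htscurate` addresses both ends for people who build or consume
screening benchmarks:

- **Curation** — a ten-stage pipeline (duplicate removal → hierarchical
  primary/confirmatory/counter label assignment → parser → inorganic →
  mixture resolution → charge neutralization → aromatization → PAINS →
  Lipinski Rule-of-Five → flag review) with a per-record audit ledger:
  every exclusion names its stage and reason, and counts are conserved
  at every step. A compound is finally *active* only if a confirmatory
  screen validated it and no counter screen flagged off-target
  activity.
- **Evaluation** — the four early-recognition metrics:
  logAUC[0.001,0.1] (ROC area on a logarithmic FPR axis, normalized so
  a perfect ranking scores 1 and a score-independent one
  0.099/(2 ln 10) ≈ 0.0215), BEDROC(α = 20), EF₁₀₀ and DCG₁₀₀.
- **Splits** — adapted 5-fold cross-validation (every compound tested
  exactly once, validation fold cyclically preceding the test fold,
  only five models trained) and Bemis-Murcko scaffold splits
  (scaffold-disjoint 3:1:1 partitions, bins above 10% of the library
  forced into training).
- **Featurization** — 2D bond graphs and 3D distance-cutoff graphs
  (6 Å) with a documented 28-slot atom feature schema.
- **Simulation** — a screening-campaign generator with exact ground
  truth and planted artifacts, so the whole pipeline is testable
  without downloading anything.

See `docs/methods.md` for the models, assumptions, and limitations.

## Worked example

Simulate a 1,000-compound campaign (0.5% true hit rate, 30% primary
false-positive rate, planted artifacts), curate it, and summarize:

```python
from htscurate.synthetic import CampaignSpec, generate_library, simulate_screens
from htscurate.curation import run_curation_pipeline
from htscurate.io import dataset_stats
from htscurate.splits import murcko_scaffold

spec = CampaignSpec(n_compounds=1000, seed=7)
campaign = simulate_screens(generate_library(spec))
dataset = run_curation_pipeline(campaign.records, campaign.hierarchy)
for stage, (n_in, n_out, n_exc) in dataset.report.stage_counts.items():
    print(f"{stage:<12} in={n_in:<5} out={n_out:<5} excluded={n_exc}")
stats = dataset_stats(dataset.records, murcko_scaffold)
print(stats.n_compounds, stats.n_actives, stats.percent_active_display)
```

prints

```
dedup        in=1000  out=980   excluded=20
hierarchy    in=980   out=701   excluded=279
parse        in=701   out=701   excluded=0
inorganic    in=701   out=701   excluded=0
mixture      in=701   out=686   excluded=15
neutralize   in=686   out=686   excluded=0
aromatize    in=686   out=686   excluded=0
pains        in=686   out=678   excluded=8
druglikeness in=678   out=668   excluded=10
flags        in=668   out=668   excluded=0
668 5 0.749%
```

The 20 planted duplicate CIDs fall at dedup; the 279 hierarchy
exclusions are overwhelmingly primary-screen false positives that the
confirmatory screen refused to confirm (the loose primary threshold at
work); ambiguous mixtures, PAINS matches and Rule-of-Five violators
fall at their own stages; salts and charged species are *repaired*
(counter-ions stripped, charges neutralized), not excluded. The five
curated actives are exactly the campaign's true actives.

Scoring a ranking (here: a noisy synthetic score that places actives
high) with the early-recognition suite:

```python
import numpy as np
from htscurate.metrics import evaluate_all

rng = np.random.default_rng(0)
labels = np.array([1] * 50 + [0] * 4950)
scores = labels * 2.0 + rng.normal(size=5000)
print(evaluate_all(labels, scores).as_dict())
```

```
{'logauc': 0.4469, 'bedroc': 0.6192, 'ef_k': 23.0, 'dcg_k': 7.0074}
```

logAUC 0.447 sits between the random floor (0.0215) and the perfect 1.0;
EF₁₀₀ = 23 means the top-100 selection is 23× richer in actives than the
library at large.

The same workflows are available from the shell:

```
htscurate simulate --n 2000 --seed 7 --out campaign/
htscurate curate --input campaign/compounds.csv --hierarchy campaign/hierarchy.yaml --out curated/
htscurate split --input campaign/compounds.csv --hierarchy campaign/hierarchy.yaml --scheme scaffold --out folds/
htscurate evaluate --scores scores.csv --labels labels.csv
```

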