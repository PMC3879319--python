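# luminet

Neural-network-driven biomarker discovery and cohort statistics for
luminal breast cancer studies — and, more generally, for any
binary-phenotype transcriptomic dataset paired with a clinical cohort.

## The problem

Oestrogen-receptor (ER) positive ("luminal") tumours are the largest
breast-cancer group, yet clinically heterogeneous: distinguishing
good-prognosis (Luminal A) from poor-prognosis (Luminal B) patients needs
additional biomarkers. One discovery strategy is to (1) rank every
microarray probe by how well it alone predicts ER status, (2) infer a
signed interaction network among the top-ranked probes, (3) read candidate
markers off the network's hubs and focal interactomes, and (4) validate a
candidate against clinicopathological variables and survival in an
independent patient cohort. `luminet` implements that pipeline end to end.

## The method

* **Ranking** — each probe is the single input of a multilayer perceptron
  (two hidden sigmoid units, sigmoid output) trained by online
  back-propagation (learning rate 0.1, momentum 0.5) under Monte-Carlo
  cross-validation: random 60/20/20 train/test/validation partitions, early
  stopping at 3000 epochs or 1000 epochs without a new best test MSE.
  A probe's score is its mean best test MSE across (by default) 50
  resampled models; low MSE = strongly class-predictive.
* **Interaction inference** — over the top-k panel (default k=100), each
  probe is predicted from the remaining k−1; the signed influence of input
  i on the target is the weight product Σ_h W[i,h]·w_out[h] (positive =
  stimulating, negative = inhibiting), averaged over 10 models per target.
  A 100-probe panel yields a 9,900-entry directed interaction matrix.
* **Network model** — keep the top 100 positive and top 100 negative
  interactions, call nodes with more than five retained interactions hubs,
  extract focal-gene ego interactomes, export SIF/GraphML/TSV for
  Cytoscape and friends.
* **Cohort statistics** — immunohistochemistry H-scores
  (Σ intensity × % cells, 0–300; ≥200 = strong positivity), uncorrected
  Pearson chi-square association screens, Kaplan–Meier/log-rank survival
  comparison and Cox proportional-hazards regression (Efron ties).

A synthetic-data module plants known informative probes, signed pairwise
dependencies (a linear DAG) and cohort effects (odds ratios, hazard
ratios) so every stage is validated against ground truth; the package also
ships the published contingency tables of a ~1,000-patient DACH1
tissue-microarray cohort as exact fixtures. See `docs/methods.md` for the
full model description and design choices.

## Worked example

```python
from luminet import *

cfg = ExpressionConfig(n_probes=100, n_samples=200, n_class1=118,
                       n_informative=5, effect_size=2.0,
                       panel_size=20, n_planted_edges=10, seed=1)
dataset, truth = generate_expression(cfg)
scaled = scale_to_unit(dataset)
train = TrainingConfig(max_epochs=100, patience_epochs=50, seed=1)

scores = rank_probes(scaled, config=train, n_iterations=5)
print("top 5 probes:", [(s.probe_id, round(s.mean_test_mse, 3)) for s in scores[:5]])
print("planted informative probes:", truth.informative_probe_ids)

panel = select_panel(scores, k=20)
matrix = infer_interactions(scaled.subset_probes(panel), config=train, n_models=3)
pairs = pair_table(matrix)
net = filter_top_edges(pairs, n_positive=15, n_negative=15)
print("edges kept:", len(net.edges), "| hubs:", sorted(find_hubs(net)))

stat, df, p = chi_square_test(published_contingency("ER"))
print(f"ER association: chi2={stat:.3f}, df={df}, p={p:.2e}")

cohort, _ = generate_cohort(CohortConfig(n_patients=500, hazard_ratio=2.0, seed=1))
hr = cox_ph(cohort, ["exposure"]).loc["exposure"]
print(f"Cox HR={hr.hazard_ratio:.2f} (95% CI {hr.ci_lower:.2f}-{hr.ci_upper:.2f})")
```

prints

```
top 5 probes: [('P0030', 0.223), ('P0021', 0.226), ('P0088', 0.248), ('P0048', 0.258), ('P0031', 0.271)]
planted informative probes: ['P0021', 'P0030', 'P0031', 'P0048', 'P0088']
edges kept: 30 | hubs: ['P0013', 'P0021', 'P0040', 'P0048', 'P0053', 'P0088', 'P0096']
ER association: chi2=142.867, df=1, p=6.29e-33
Cox HR=2.08 (95% CI 1.70-2.54)
```

All five planted class-predictive probes occupy the top five ranks (their
mean test MSE, ~0.22–0.27, sits well below the ~0.36 of the worst noise
probe); the filtered network keeps exactly the 15 strongest interactions
of each sign; the packaged ER contingency table reproduces its published
chi-square statistic of 142.867; and the Cox fit recovers the planted
hazard ratio of 2.0 inside its confidence interval.

The same pipeline is available from the shell:

```bash
luminet simulate --out demo --seed 1
luminet rank --expr demo/expression.tsv --labels demo/labels.tsv \
             --iters 5 --epochs 100 --patience 50 --out demo/scores.tsv
luminet infer --expr demo/expression.tsv --scores demo/scores.tsv \
              --panel-size 20 --models 3 --epochs 100 --out demo/pairs.tsv
luminet network --pairs demo/pairs.tsv --npos 100 --nneg 100 --out demo/net.graphml
luminet stats --cohort demo/cohort.tsv --markers marker_a,marker_b --out demo/stats
luminet run --out demo_run --seed 1   # everything, with a reproducibility manifest
```

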