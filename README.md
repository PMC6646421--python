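# combosyn

Machine-learning prediction of anticancer **drug-combination synergy** with
per-prediction **reliability estimation**, modeled on large public
combination screens such as NCI-ALMANAC.

## The problem

High-throughput screens measure how pairs of drugs inhibit the growth of
cancer cell lines over a grid of concentrations. The benefit of a
combination over non-interacting additivity is summarized by the
**ComboScore**, a modified Bliss-independence score: for single-agent
percent growths `y_a`, `y_b` (≤ 100, negative for net cell kill) the
expected additive growth of a concentration pair is

```
E(y_a, y_b) = y_a · y_b / 100     if y_a > 0 and y_b > 0
            = min(y_a, y_b)      otherwise
```

and the grid's score is `Σ_ij [E(y_a_i, y_b_j) − y_combo_ij]` after
truncating growths into [−100, 100]. Positive scores indicate synergy,
negative antagonism, zero additivity.

`combosyn` builds one regression model per cell line, of the QSAR family:
each drug is encoded as a vector of chemical descriptors (binary/counted
Morgan fingerprints, MACCS keys, atom–bond path fragments, 4-atom simplex
fragments, and 7 physico-chemical properties), a drug pair is the
concatenation of the two vectors, and a tree ensemble (random forest or
XGBoost; elastic net as the linear baseline) maps pair features to
ComboScore. Training rows are duplicated with the drugs in reverse order
(data augmentation) and inference averages both orders, so predictions are
exactly symmetric in the pair.

For a random forest, the standard deviation of the individual tree
predictions (**tree_SD**) is attached to every prediction as a reliability
score: predictions with low tree disagreement are empirically the most
accurate, so the top quartile by reliability can be selected *a priori*.

Validation schemes cover random 90/10 (or 80/20) splits, k-fold,
**leave-one-drug-out** (every combination containing the held-out drug is
the test set), **Y-randomization** (retraining on permuted targets), and a
**screening-center comparison** that relates a center's single-agent
replicate variability to the predictivity of models trained on its data.

Everything is exercisable without downloading the real screen: the
`simulate` module generates a library of drug-like structures and a full
synthetic screen with a planted, recoverable relationship between chemical
features and synergy (see `docs/methods.md`).

## Worked example

```python
from combosyn import (SynthConfig, ModelSpec, assemble_synthetic,
                      random_split, train, predict, reliability_strata,
                      stratified_report)
import numpy as np

cfg = SynthConfig(seed=1)                  # 40 drugs, 5 cell lines
tables = assemble_synthetic(cfg)           # per-cell-line pair tables
samples = tables["CL01"]                   # 714 pairs, 526 features each

fold = random_split(samples, test_fraction=0.25, seed=1)
model = train([samples[i] for i in fold.train_idx], ModelSpec("rf", seed=1))
test = [samples[i] for i in fold.test_idx]
preds = predict(model, test)

strata = reliability_strata(preds, q=0.25)
reports = stratified_report(preds, np.array([s.target for s in test]), strata)
for name, r in reports.items():
    print(f"{name:15s} n={r.n:3d} RMSE={r.rmse:5.1f} R_p={r.r_p:.2f}")
```

prints

```
most_reliable   n= 44 RMSE= 16.1 R_p=0.03
all             n=178 RMSE= 34.6 R_p=0.74
least_reliable  n= 44 RMSE= 48.6 R_p=0.74
```

i.e. the quarter of test combinations with the lowest tree_SD is predicted
with half the error of the full test set, and the least reliable quarter
with substantially more — the reliability score orders the error without
looking at the observed values. (Note the correlation in the most-reliable
stratum is low even though its error is smallest: restricting to reliable
predictions also restricts the score range, which is why strata are
compared by RMSE, not by correlation.)

The same experiments are available from the shell:

```bash
combosyn simulate --out runs/sim --seed 1 --n-drugs 20 --n-cell-lines 2
combosyn score    --screen runs/sim/screen.csv --out runs/scored
combosyn evaluate --out runs/eval --seed 1
combosyn lodo     --out runs/lodo --seed 1
combosyn center-compare --out runs/centers --seed 1
```

## Data formats

* **Structures**: SMILES file (`SMILES<whitespace>ID` per line) or SDF.
* **Screens**: the ComboDrugGrowth CSV dialect with columns `SCREENER`
  (1A/FF/FG), `TESTDATE`, `CELLNAME`, `NSC1`, `CONC1`, `NSC2`, `CONC2`,
  `PERCENTGROWTH`; combination rows carry both drug ids, single-agent rows
  leave `NSC2` empty. The reader assembles grids keyed by
  (center, drugs, cell line, test date) and tolerates malformed rows.
* **Labels**: internal TSV `(drug_a, drug_b, cell_line, center, combo_score)`.
* **Features**: TSV matrix plus a JSON fragment-vocabulary file.
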