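# hlrlogit — sparse logistic regression with the hybrid L1/2 + L2 penalty

Binary classification with built-in feature selection for wide data —
gene-expression studies where the number of features p (thousands of genes)
far exceeds the number of samples n. Plain logistic regression is not even
identifiable in that regime; penalized fits are, but the two classical
penalties each give up something: the L1 (Lasso) family shrinks surviving
coefficients and picks one representative from a group of correlated genes,
while ridge (L2) never produces exact zeros.

This package implements the hybrid **L1/2 + L2** penalty (HLR) for the
logistic model P(y=1|x) = e^{x'β}/(1+e^{x'β}):

```
min_β  −∑_i [ y_i log f(x_i'β) + (1−y_i) log(1−f(x_i'β)) ]
       + λ ( α ∑_j |β_j|^{1/2} + (1−α) ∑_j β_j² )
```

The non-convex L1/2 part yields sparse, nearly unbiased estimates through
the **half-thresholding operator** — a closed-form univariate rule with a
hard dead zone of radius (3/4)(λα)^{2/3} and trigonometric shrinkage
outside it — and the ridge part restores the **grouping effect**: strongly
correlated predictors enter or leave the model together. The solver is
IRLS (working response Z_i, weights W_i = f(1−f)) wrapped around cyclic
coordinate descent with warm-started λ paths, glmnet-style. Lasso,
elastic-net, pure-L1/2 and ridge fits come from the same engine, and a
two-dimensional (λ, α) cross-validation picks the tuning parameters.

## Worked example

```python
import numpy as np
from hlrlogit import (PenaltySpec, cross_validate, generate_scenario,
                      predict, scenario_spec, selection_metrics)

spec = scenario_spec(1, rho=0.9)          # n=100/100, p=1000, 5 true genes
ds = generate_scenario(spec, seed=5)
cv = cross_validate(ds.X_train, ds.y_train, "hlr", k=10, seed=0,
                    fit_intercept=False)
print("chosen (lambda, alpha):", tuple(round(v, 3) for v in cv.best))
prob, pred = predict(cv.model, ds.X_test)
m = selection_metrics(ds.beta_true, cv.model.beta, ds.y_test, pred)
print("selected features:", np.flatnonzero(cv.model.beta))
print(f"sensitivity {m.sensitivity:.2f}  specificity {m.specificity:.4f}  "
      f"test accuracy {m.test_accuracy:.2f}")
```

Output:

```
chosen (lambda, alpha): (5.114, 0.1)
selected features: [0 1 2 3 4]
sensitivity 1.00  specificity 1.0000  test accuracy 0.97
```

The generator plants five true coefficients (features 0–4, with 1–4
correlated to 0 at ρ=0.9); the CV-tuned hybrid fit selects exactly those
five — all members of the correlated group, the grouping effect at work —
and classifies 97% of the held-out samples correctly.

The same pipeline runs from the shell on any CSV/TSV expression matrix:

```
hlr cv --data expr.csv --label-column status --penalty hlr --kfolds 10 \
       --seed 1 --out-dir results/
hlr predict --data new.csv --model results/best_model --out preds.tsv
hlr simulate --scenario 1 --rho 0.9 --seed 7 --out-dir sim/
hlr benchmark --scenarios 1 --rhos 0.3,0.6,0.9 --methods hlr,lasso \
       --repeats 50 --seed 1 --out-dir bench/
```

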