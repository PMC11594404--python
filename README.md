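# gemlr — generative mixture of logistic regressions

`gemlr` implements **GeM-LR**, a mixture-of-experts model for
small-sample binary-outcome biomarker studies — the setting of early
phase vaccine trials, where tens to a few hundred participants are
measured on 10–20 correlated immunoassay features and the question is
which features predict protection (correlates of protection), and for
whom. The participants' responses are often *heterogeneous*: an antibody
measure can predict protection strongly in one subgroup of the feature
space and weakly, or with the opposite sign, in another. A single linear
classifier averages these effects away; complex nonlinear learners
overfit at these sample sizes and explain nothing.

## The model

A latent cluster label gates cluster-wise sparse logistic regressions:

* Z ∈ {1,…,C} with P(Z=c) = π_c;
* X_G | Z=c ~ N(μ_c, Σ_c) over a chosen subset G of *gate* features
  (the embedded Gaussian mixture);
* Y | X, Z=c ~ Bernoulli(σ(β_c′ x_L + β_c0)) over the *classifier*
  features L, which may differ from G.

Prediction mixes the experts with the gate posterior:

    P(Y=1 | x) = Σ_c P(Z=c | x_G) · σ(β_c′ x_L + β_c0)

The whole model is estimated jointly by EM, so clusters form under the
guidance of the outcome ("predictive clustering"), and every cluster's
regression is fitted on **all** points weighted by their
responsibilities — small clusters borrow strength instead of being fit
in isolation. The regressions carry an elastic-net penalty
λ₁ Σ_j ((1−λ₂)/2 β² + λ₂|β|) suited to correlated assay panels
(default mixing λ₂ = 0.8); covariances can be shrunk toward diagonal or
tied for very small clusters, and clusters too small to support a
regression fall back to an empirical class frequency.

The package also provides:

* **cluster annotation** — closed-form true/false-positive measures
  τ_c±(h) from Gaussian product integrals, combined into the aggregate
  discriminative accuracy A_c(h) = π_c τ_c+ + (1−π_c)(1−τ_c−), with
  greedy forward selection of the feature subsets that identify each
  cluster;
* **model selection** — stratified (repeated) K-fold CV with per-fold
  AUCs averaged, influence-function confidence intervals, non-nested
  tuning of λ₁ and of the cluster count C, inverse-probability
  oversampling and weighted AUC for two-phase sampling designs;
* **baselines** — cluster-then-predict (k-means + per-cluster
  elastic-net LR) and plain elastic-net LR, sharing the evaluation
  stack;
* **synthetic data** — generators with the model's exact structure and
  known truth (heterogeneous, homogeneous, small-high-dimensional and
  null presets) for power studies and validation.

## Worked example

```python
import gemlr
from gemlr import FitConfig
from gemlr.annotation import annotate_all
from gemlr.model_selection import make_folds, cv_evaluate

sc = gemlr.make_scenario("heterogeneous", n=200, seed=1)
table, y, truth = gemlr.generate(sc)        # two clusters, opposite effects
roles = sc.default_roles()                  # gate: g1,g2; classify: all

model = gemlr.fit(table, y, roles, FitConfig(C=2, lambda1=0.1, seed=1))
plan = make_folds(y, K=5, seed=1)
for m in ["gemlr", "lr"]:
    r = cv_evaluate(table, y, roles, FitConfig(C=2, lambda1=0.1, seed=1),
                    plan, method=m)
    print(f"{m}: CV AUC {r.cv_auc:.3f} (95% CI {r.ci[0]:.3f}-{r.ci[1]:.3f})")
```

prints

```
gemlr: CV AUC 0.880 (95% CI 0.834-0.927)
lr:    CV AUC 0.461 (95% CI 0.380-0.542)
```

The two cluster-wise coefficient vectors have opposite signs on the
informative features (≈ −5 vs +5 on the standardized scale, truth ±2 on
the raw scale), which is exactly the structure a single logistic
regression cannot represent — its pooled association cancels to chance
level (AUC 0.46) while the mixture reaches 0.88. Annotation then names
what separates the clusters:

```python
for ann in annotate_all(model.gate):
    print(ann.cluster + 1, ann.selected, round(ann.A_final, 3))
```

selects a single gate feature per cluster with A_c ≈ 1.0 (the clusters
are fully discriminable), and `gemlr.recovery_report(model, truth,
table)` confirms ARI 1.0 against the generating labels with 100%
coefficient sign agreement.

## Command line

```bash
gemlr simulate --scenario heterogeneous --n 200 --seed 1 --out-data d.csv
gemlr fit --data d.csv --outcome-col outcome --C 2 --lambda1 0.1 \
      --seed 1 --out model.json
gemlr annotate --model model.json --out annotation.tsv
gemlr cv --data d.csv --outcome-col outcome --C 2 --lambda1 0.1 \
      --seed 1 --repeats 5 --out cv_gemlr.json
gemlr compare cv_gemlr.json cv_lr.json       # paired t-test on CV AUCs
```

Exit codes distinguish schema errors (2), numerical failures (3) and
infeasible cluster counts (4). Models are a single versioned JSON
document that round-trips to bit-identical predictions.

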