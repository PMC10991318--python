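# cardioml

Cardiovascular-risk classification from routine screening records (age,
blood pressure, cholesterol and glucose grades, lifestyle flags), built as a
fully tested, single-node pipeline:

1. **Outlier screening** by k-means clustering: fit K clusters on
   standardized features by Lloyd iteration of the within-cluster
   sum-of-squares criterion `J = Σ_r Σ_{x∈C_r} ‖x − S_r‖²` with stopping rule
   `|J(I) − J(I−1)| < ξ`, then delete every cluster whose size falls below a
   fraction of *n* and recompute the silhouette index on a refit.
2. **Class balancing** with SMOTE: synthetic minority records
   `x_i + u·(x_nn − x_i)`, `u ~ U(0,1)`, interpolated between a minority
   record and one of its k minority nearest neighbours (training partition
   only).
3. **Recursive feature elimination (RFE)**: refit an L2 logistic ranker on
   standardized surviving features each round, drop the smallest
   `|coefficient|`, and keep the top `n_select` of the resulting total order.
4. **Attention-GRU classifier trained by a swarm optimizer**: each feature is
   one time step; softmax attention weights `α_t = softmax(tanh(w_a x_t + b_a))`
   scale the inputs, two GRU layers (reset gate `j_t`, update gate `v_t`,
   candidate `λ_t`, blend `h_t = (1 − v_t)·λ_t + v_t·h_{t−1}`) consume the
   weighted sequence, and a sigmoid output layer yields P(disease).  All
   weights are trained derivative-free by a white-shark-style swarm optimizer
   with constriction-damped velocities
   `υ_{h+1} = η[υ_h + m1(H_tbest − H)x1 + m2(H_best^β − H)x2]`,
   `η = 2/|2 − τ − √(τ² − 4τ)|`, linearly decaying learning factors, and
   fitness-adaptive crossover/mutation with greedy (elitist) acceptance.
5. **Evaluation**: confusion-matrix accuracy/recall/precision/F1, ROC/AUC by
   threshold sweep + trapezoid rule, logistic-regression / k-NN / Gaussian
   naive-Bayes baselines, and a 2×2 SMOTE × RFE ablation harness.

Because no public cohort ships with the package, a **synthetic generator**
draws CVD-like cohorts with a planted logistic signal on 5 of 12 features,
80/20 class imbalance, pure-noise features, and an optional displaced outlier
cluster — with ground truth (outlier rows, informative features, true
probabilities) returned for every draw, so each stage can be scored against
what was planted.

## Worked example

```python
import cardioml as cm

cfg = cm.PipelineConfig(
    gen=cm.GenConfig(n_records=2000, outlier_fraction=0.05),
    seed=1,
)
manifest = cm.run(cfg)
for r in manifest["reports"]:
    print(f"{r['model']:12s} acc={r['accuracy']:.3f} rec={r['recall']:.3f} "
          f"prec={r['precision']:.3f} f1={r['f1']:.3f} auc={r['auc']:.3f}")
print("majority-class rate:", round(manifest["majority_class_rate"], 3))
print("planted outliers recovered:", manifest["outlier_recall"])
print("selected features:", manifest["stages"]["rfe"]["selected"])
```

prints (exact numbers vary with the seed):

```
AttGRU-HMSI  acc=0.847 rec=0.724 prec=0.598 f1=0.655 auc=0.872
LR           acc=0.887 rec=0.855 prec=0.670 f1=0.751 auc=0.943
KNN          acc=0.868 rec=0.829 prec=0.630 f1=0.716 auc=0.906
NB           acc=0.868 rec=0.750 prec=0.648 f1=0.695 auc=0.916
majority-class rate: 0.8
planted outliers recovered: 1.0
selected features: ['age', 'weight', 'ap_hi', 'cholesterol', 'smoke']
```

The swarm-trained network beats the 0.80 majority-class floor; feature
selection recovers exactly the five planted informative columns; every
planted outlier is caught by the smallest-cluster rule.

The same flow is available from the shell:

```bash
cardioml generate --n 2000 --seed 7 --out cohort      # CSV + ground truth
cardioml run --seed 1 --out run_out                   # full pipeline
cardioml ablate --seed 1 --out ablation.json          # 2x2 SMOTE x RFE
cardioml optimize-bench --function rastrigin --dim 5  # optimizer benchmark
```

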