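# nbspanel

Network-based stratification of tumors from somatic mutations, for full
exomes or small gene panels.

Somatic mutation profiles are nearly orthogonal across patients — two
tumors of the same subtype rarely share a single mutated gene — so
clustering the raw 0/1 gene × patient matrix fails. `nbspanel` implements
the network-based stratification (NBS) strategy: smooth each patient's
binary profile over a gene interaction network with the
random-walk-with-restart iteration

    F_{t+1} = a·A·F_t + (1−a)·F_0        (a = 0.7)

quantile-normalize patients, factorize the smoothed matrix with
graph-regularized NMF

    min_{W,H ≥ 0}  ‖F − WH‖_F² + λ·tr(Wᵀ L W)     (λ = 200, L from a k=11 NN graph)

and stabilize the K subtypes by consensus clustering over subsampled
replicates (80% of patients, average-linkage cut of 1 − consensus,
cophenetic correlation as the quality score). Subtypes are then tested
against overall survival (K-sample log-rank) and clinical covariates such
as grade or stage (Fisher's exact test).

The package is aimed at methodologists and translational bioinformaticians
who want to evaluate whether a small, clinically practical gene panel
stratifies a cohort as well as (or better than) exome-wide mutation data.
A synthetic-study generator with planted ground truth makes the whole
pipeline exercisable — and testable — without any external cohort.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score

from nbspanel import AnalysisConfig, NetworkStratification, filter_samples
from nbspanel.synthetic_data import gen_clinical, gen_cohort, gen_network

# a planted study: 200 genes in 4 network communities, 120 patients in
# 4 subtypes, each mutating its community at 20% against a 1% background
net, truth = gen_network(m=200, n_modules=4, seed=1)
cohort, truth = gen_cohort(net, truth, n_samples=120, n_subtypes=4, seed=2)
clinical, truth = gen_clinical(
    truth, cohort.samples, hazard_ratios={0: 1.0, 1: 2.0, 2: 4.0, 3: 8.0}, seed=3
)

model = NetworkStratification(
    filter_samples(cohort, "full"),          # ≥6 mutated genes per sample
    net,
    clinical=clinical,
    config=AnalysisConfig(n_reps=100),
)
res = model.fit(K=4, seed=3)
print(res.summary())
print("ARI vs planted truth:",
      round(adjusted_rand_score(truth.subtype_labels(list(res.labels.index)),
                                res.labels.to_numpy()), 3))
```

Output:

```
Network-based stratification results
============================================
clusters (K):            4
patients:                120
replicates:              100 (subsample 80%)
cophenetic correlation:  1.0000
cluster sizes:           1: 30, 2: 30, 3: 30, 4: 30
log-rank:                chi2=38.486, df=3, p=2.23e-08
Fisher (grade):          p=1e-05 [monte-carlo]
ARI vs planted truth: 1.0
```

Reading this: the consensus matrix is perfectly block-structured
(cophenetic correlation 1.0), the four recovered clusters coincide exactly
with the planted subtypes (ARI 1.0), and because the subtypes were planted
with hazard ratios 1:2:4:8 the log-rank test separates their survival
decisively; the Monte-Carlo Fisher test likewise detects the association
between subtype and tumor grade.

The same analysis runs from the shell, including a panel arm:

```bash
nbspanel simulate --genes 200 --modules 4 --samples 120 --subtypes 4 \
    --seed 1 --out sim/
nbspanel run --mutations sim/mutations.tsv --network sim/network.tsv \
    --panel sim/panel.txt --clinical sim/clinical.tsv \
    --k 3 --k 4 --reps 100 --seed 1 --out results/
nbspanel compare results/        # gene sets ranked by median ccc
```

`run` writes per-(gene set, K) label and consensus TSVs plus a `report.tsv`
with ccc, cluster sizes, log-rank and Fisher p-values.

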