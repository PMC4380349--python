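# tanfv

Tree-augmented naive Bayes (TAN) prognosis models with Fussell–Vesely
importance ranking, for cohorts of discrete-coded clinical variables.

## The problem

Survival after resection of hepatocellular carcinoma (HCC) depends on
many interacting factors — portal vein tumor thrombosis (PVTT), tumor
size and number, operative method, liver function, intraoperative blood
loss, and so on. Classical single-factor survival statistics rank
predictors one at a time and ignore their joint structure. This package
implements an alternative workflow built around a Bayesian-network
classifier:

1. **Discretize** each clinical variable into a small number of coded
   states (e.g. age into 16–45 / 46–59 / 60–84 years, survival time into
   ≤10 / >10 months).
2. **Learn a TAN classifier**: the survival class *S* is a parent of
   every attribute *Vᵢ*, and the attributes additionally form a tree —
   the maximum spanning tree under class-conditional mutual information
   *I(Vᵢ; Vⱼ | S)* (the Chow–Liu construction). Conditional probability
   tables are estimated by (optionally Laplace-smoothed) relative
   frequencies.
3. **Evaluate** the model with confusion-matrix metrics (accuracy, TPR,
   FPR, per-row reliability), an ROC curve, and an accuracy-maximizing
   decision threshold.
4. **Rank predictors** by the Fussell–Vesely importance borrowed from
   reliability engineering. For each state *j* of variable *Vᵢ*,

   FV<sub>ij</sub> = [P(S=0) − P(S=0 | Vᵢ=j)] / P(S=0),

   the relative change in short-survival probability when the state is
   observed, and the per-variable composite measure

   MFV<sub>i</sub> = (1/(Kᵢ−1)) · Σⱼ |FV<sub>ij</sub>|

   over all Kᵢ states, which makes variables with different state counts
   comparable.
5. **Simulate scenarios**: exact posteriors of survival (and of any free
   attribute) under partial evidence — e.g. "PVTT present, curative vs
   palliative resection".

All inference is exact: the tree factorization lets any posterior be
computed by a single message pass per class state, verified in the test
suite against brute-force enumeration of the full joint.

The package also ships a synthetic-cohort module that encodes the
published summary statistics of a 299-patient hepatectomy cohort
(50.2%/49.8% survival split, 8.4% PVTT prevalence, 84% short survival
among PVTT-positive patients, …), both as a seeded ancestral sampler and
as a deterministic count-matched replica table, so the whole pipeline is
testable without access to patient data.

## Worked example

```python
import warnings
from tanfv import replica_counts_cohort, fit_tan, importance_table, posterior

cohort = replica_counts_cohort()          # deterministic 299-row cohort
with warnings.catch_warnings():
    warnings.simplefilter("ignore")       # sparse contexts at alpha=0
    model = fit_tan(cohort, alpha=0.0)    # maximum-likelihood TAN

prior = posterior(model, "survival", {})[0]
print(f"P(short survival) prior: {prior:.4f}")
for row in sorted(importance_table(model, cohort), key=lambda r: r.rank)[:5]:
    print(f"{row.rank:>2}  {row.variable:<18} MFV={row.mfv:.4f}  "
          f"posteriors={row.posteriors.round(4).tolist()}")
anh = posterior(model, "survival", {"pvtt": 1, "operative_method": 1})[1]
pah = posterior(model, "survival", {"pvtt": 1, "operative_method": 0})[1]
print(f"P(long survival | PVTT, curative ANH)  = {anh:.4f}")
print(f"P(long survival | PVTT, palliative PAH) = {pah:.4f}")
```

prints

```
P(short survival) prior: 0.5017
 1  pvtt               MFV=0.7359  posteriors=[0.4708, 0.84]
 2  operative_method   MFV=0.7309  posteriors=[0.8205, 0.4538]
 3  tumor_number       MFV=0.6183  posteriors=[0.4498, 0.76]
 4  metastasis         MFV=0.5594  posteriors=[0.4585, 0.7391]
 5  hcv                MFV=0.5300  posteriors=[0.5159, 0.25]
P(long survival | PVTT, curative ANH)  = 0.1885
P(long survival | PVTT, palliative PAH) = 0.0383
```

Read: before seeing any attribute, a patient has a 50.17% probability of
short (≤10 months) survival. Observing PVTT raises that to 84%, the
largest relative swing of any variable (MFV 0.7359, rank 1), with the
operative method a close second — palliative resection carries a
short-survival posterior of 82%. In the scenario query, a PVTT-positive
patient's long-survival probability is several times higher under
curative (anatomical) than under palliative resection.

`TanClassifier` wraps the same model as a scikit-learn estimator
(`fit`/`predict_proba`/`predict`, clonable, pipeline- and CV-compatible):

```python
from tanfv import TanClassifier
X = cohort.data.drop(columns=["survival"]); y = cohort.data["survival"]
clf = TanClassifier(alpha=1.0, threshold=0.6127).fit(X, y)
clf.predict_proba(X)[:3, 1]   # long-survival probabilities
```

## Command line

Each pipeline stage is a subcommand reading/writing plain files:

```sh
tanfv simulate --n 299 --seed 7 --out cohort.csv
tanfv fit --cohort cohort.csv --alpha 1.0 --out model.json
tanfv evaluate --model model.json --cohort cohort.csv \
    --threshold 0.6127 --out report.json --roc-out roc.csv
tanfv importance --model model.json --cohort cohort.csv --out importance.csv
tanfv scenario --model model.json --set pvtt=1 --set operative_method=0
```

`tanfv discretize` maps raw-valued CSVs (years, ng/mL, cm, mL, min,
months) onto state codes. Exit codes: 0 success, 2 validation error,
3 inference error.

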