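# pampanet

Stacked neural-network QSAR modelling of passive membrane permeability
measured by PAMPA (Parallel Artificial Membrane Permeability Assay).

Early drug-discovery programmes need fast, reliable estimates of how well a
candidate molecule crosses a lipid membrane by passive diffusion. PAMPA
measures this as an effective permeability coefficient *Pe* (cm/s), modelled
here on the log10 scale (*logPe*); at pH 7.4 compounds with
*logPe* ≥ −6.2 are conventionally classed as "higher permeability" and the
rest as "lower". `pampanet` is for computational/medicinal chemists who want
to (a) convert raw PAMPA plate measurements to *logPe*, and (b) train and
deploy a descriptor-based regression model that predicts *logPe* from
structure alone, with a per-molecule reliability flag.

## The model

**Assay conversion.** From donor/acceptor volumes V_D, V_A, membrane area A,
incubation time t, lag time τ_ss, apparent porosity ε_a and the measured
concentration ratios, with r_v = V_D/V_A and membrane retention
R_M = 1 − (C_D(t)/C_D(0) − V_A·C_A(t)/(V_D·C_D(0))):

    Pe = −(2.303·V_D)/(A·(t−τ_ss)·ε_a) · 1/(1+r_v)
         · log10[ 1 − ((1+r_v⁻¹)/(1−R_M)) · C_A(t)/C_D(0) ]

**Regression.** Feedforward multilayer perceptrons with logistic hidden
units and a linear output,

    o(x) = w₀ + Σ_j w_j · f(w₀j + w_jᵀx),   f(z) = 1/(1+e^(−z)),

are trained full-batch by resilient backpropagation with weight
backtracking (Rprop+) to minimise E = ½Σ(o−y)². Two base networks
(hidden layers 20-15-5 and 30-20-10) are combined by stacked regression: a
small meta network (2-1 hidden units) is trained on the base models'
predictions with the experimental *logPe* as target.

**Feature selection.** Descriptors (RDKit; ~210 2D descriptors plus
optional seeded-conformer 3D shape descriptors) are screened for
zero-variance and non-finite columns, then reduced by recursive feature
elimination with random-forest importance under repeated K-fold
cross-validation (default 20-fold × 3 repeats).

**Applicability domain.** Per molecule, the sample standard deviation of
the base-model predictions, SD(j) = √(Σ(y_i−ȳ)²/(k−1)); predictions with
SD above three times the maximum training-set SD are flagged unreliable.

**Evaluation.** R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² (can be negative),
‡R² = squared Pearson correlation, RMSE, MAE, and the gain-curve
*relative Gini score* (1 = the model ranks molecules exactly as the
measured outcomes do).

## Worked example

Everything runs from synthetic data with known ground truth (five
informative descriptors out of 60, Gaussian measurement noise):

```
$ pampanet simulate --seed 3 --out-prefix syn
[simulate] seed=3 n=190 p=60 out=syn_dataset.csv

$ pampanet select --input syn_dataset.csv --k 5 --repeats 1 --n-trees 60 \
    --sizes 2,5,10,20 --out-profile prof.json --out-manifest man.txt
[select] k=5 repeats=1 seed=0 chosen=5

$ pampanet train --input syn_dataset.csv --manifest man.txt --k 5 --repeats 1 \
    --max-steps 2000 --out-model model.json --out-metrics metrics.json
[train] seed=0 train=141 test=33 ad_threshold=0.9015 model=model.json

$ pampanet predict --model model.json --input syn_dataset.csv --out preds.csv
[predict] molecules=190 outside_domain=0 out=preds.csv

$ head -3 preds.csv
id,predicted_logPe,sd,inside_domain,permeability_class
synth_1,-7.030607411868834,0.28537321353754697,True,lower
synth_2,-6.771675548889826,0.20364656576053483,True,lower
```

The RFE step recovered exactly the five planted informative descriptors
(`man.txt` lists inf_1…inf_5). Training reproduces the protocol split
sizes 141/33/16 and stores the applicability-domain threshold
(3 × max training SD = 0.90 logPe units here); every training molecule is
inside the domain by construction, and each prediction row carries its
*logPe* estimate, ensemble SD, domain flag and −6.2 class.

`pampanet validate` runs the full protocol (split, repeated-CV base
evaluation, stacking, external validation) and emits one JSON report; on
the dataset above it prints

```
[validate] seed=0 resub_r2=0.964 gini=0.9803 external_pearson=0.973 out=val.json
```

i.e. a strong resubstitution fit, near-perfect training-set ranking and
high external correlation — the expected behaviour of the overfit-base /
stacked-meta design on clean synthetic data.

`pampanet pampa --input wells.csv --out logpe.csv` converts raw plate
measurements, adding R_M, *logPe* and the permeability class per well
(wells with no detectable permeation are labelled instead of given a
fake value).

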