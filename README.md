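# vaxresp

Transcriptomic prediction and causal-graph discovery of vaccine
antibody response.

Preventive cancer vaccines targeting tumor self-antigens (e.g. MUC1 in
people at high risk of colon cancer) elicit protective IgG in only a
subset of recipients.  Given PBMC expression profiles at baseline and
two weeks after the first dose, plus anti-vaccine IgG titers, the
question is: which transcripts mark — and which directly drive — the
week-12 antibody response?  `vaxresp` is for computational
immunologists and systems-vaccinology analysts who want that pipeline
as a tested, reusable library rather than a one-off analysis script.

It provides:

* **Responder analysis** — subjects are responders when
  IgG(week 12) / IgG(week 0) ≥ 2, high responders when additionally
  OD450 at 1:80 dilution ≥ 0.4.  Differential expression uses per-gene
  linear models with empirical-Bayes variance moderation
  (s²_post = (d₀s₀² + df·s²)/(d₀ + df), moderated t on d₀ + df degrees
  of freedom, optional mean–variance trend), with sex and trial batch
  as blocking factors, for baseline, week-2 and paired-delta contrasts.
* **Pathway scores** — single-sample gene-set enrichment by the
  kernel-CDF random-walk statistic (Gaussian kernel, bandwidth SD/4,
  weighted Kolmogorov–Smirnov walk), then differential-pathway testing
  with the same moderated-t machinery.
* **Response prediction** — `NestedLassoLogisticCV`, an L1-penalized
  logistic regression in stratified 5×5 nested cross-validation:
  honest held-out probabilities, inner-fold penalty selection by
  deviance, ROC/AUROC (Mann–Whitney form), confusion tables, and the
  correlation of predicted log-odds with log titer.
* **Causal graphs** — a pairwise mixed graphical model (penalized
  pseudolikelihood over continuous and categorical nodes, proximal
  gradient, group-sparse penalties λcc|β| + λcd‖ρ‖₂ + λdd‖φ‖_F)
  followed by FCI-MAX orientation (likelihood-ratio independence
  tests; colliders decided by the maximum-p separating set), direct
  neighbors of the week-12 IgG node, and edge stability by
  subsampling.
* **Synthetic cohorts** — a generator with paired timepoints, sex and
  batch covariates, planted signed causal genes driving the titer
  through a logistic link, and correlated decoy neighbors, so every
  stage is testable with no data download.

## Worked example

```python
import numpy as np
import vaxresp as v

cfg = v.SimConfig(n_subjects=69, n_genes=300, seed=7)   # trial-sized cohort
cohort = v.generate_cohort(cfg)
norm = v.normalize(cohort.expression)                   # log2-CPM
filtered = v.filter_features(norm, None, 250)           # top-250 by variance
labels = v.classify_response(cohort.samples)            # 2-fold IgG rule

de = v.de_contrast(filtered, cohort.samples, labels, "week2_RvsNR")

wk2 = cohort.samples[cohort.samples.timepoint == "week2"]
y = wk2.subject_id.map(labels.response).map({"NR": 0, "R": 1})
y.index = wk2.sample_id.values
model = v.lasso_logistic_cv(filtered.subset_samples(y.index), y, seed=7)
roc = v.roc_auc(model.heldout_probabilities, model.labels)
```

Printing the headline numbers of this run gives:

```
subjects: 69  responders: 34
week2 R vs NR: 11 up / 16 down at p<=0.05 (d0=inf)
held-out AUROC: 0.850  selected: 14 genes
confusion at 0.5: sens 67.6%  spec 82.9%
planted causal genes among selected: ['CAUS001', 'CAUS002', 'CAUS004', 'CAUS005', 'CAUS006']
```

So at trial scale the nested-CV predictor separates future responders
from non-responders (held-out AUROC 0.85) and its sparse signature
contains five of the six planted causal genes.  Feeding the selected
genes, the covariates and the log week-12 titer into the graph stage
(`edge_stability`, then `direct_neighbors`) returns exactly the planted
causes with their signs:

```
direct neighbor of IgG_week12: CAUS001  sign +1  stability 1.00
direct neighbor of IgG_week12: CAUS002  sign +1  stability 1.00
direct neighbor of IgG_week12: CAUS004  sign -1  stability 1.00
direct neighbor of IgG_week12: CAUS005  sign -1  stability 1.00
direct neighbor of IgG_week12: CAUS006  sign -1  stability 1.00
```

A stability of 1.00 means the edge was re-learned in every data
subsample; the sign is the sign of the gene–titer interaction in the
mixed graphical model.

The same flow is scriptable from the shell:

```sh
vaxresp simulate --seed 7 --n-subjects 69 --n-genes 300 --out cohort/
vaxresp run-all --config pipeline.yaml --seed 7
```

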