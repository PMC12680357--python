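# cranioplan

Surrogate-model pipeline for predicting the post-operative head shape
after **spring-assisted cranioplasty** (SAC), the standard correction for
sagittal craniosynostosis.  In SAC, two compressed Hookean spring
distractors (free opening 60 mm) are placed across a rectangular parietal
osteotomy; they expand over weeks and widen the long, narrow
(scaphocephalic) skull.  Planning the osteotomy position and spring choice
currently rests on surgeon experience, because a patient-specific
finite-element simulation takes hours.  This package re-creates the
alternative: learn a fast regression surrogate from a corpus of simulated
surgeries, then predict outcomes for new configurations in milliseconds —
with every stage that would normally consume patient imaging replaced by
a seeded synthetic stand-in, so the whole study runs from a single seed
on one CPU in minutes.

The pipeline, end to end:

1. **Synthetic anatomy** — a population of scaphocephalic skulls
   (half-ellipsoids with labelled bones, 2 mm sutures, parametric
   severity), all sharing one mesh topology; cohort statistics follow the
   published population (skull thickness 2.02 ± 0.33 mm, soft tissue
   3.42 ± 0.51 mm, age 174 ± 35 days).
2. **Design of experiments** — ~80 surgical configurations per patient:
   osteotomy ratios A ∈ [0.18, 0.30], AP ∈ [0.47, 0.63],
   LAT ∈ [0.10, 0.25] of skull length, springs from a three-model
   catalogue.
3. **Spring simulator** — a deterministic quasi-static shell solve
   (weighted graph Laplacian + plate bending, fixed base ring, softened
   sutures and osteotomy) coupled self-consistently to the push-only
   spring law F = k(L0 − x).
4. **Statistical shape models** — volume-normalised shapes decomposed as
   m = m̄ + Φb (PCA via thin SVD); modes kept to 94% explained variance,
   separately for pre-operative and simulated-outcome shapes.
5. **Surrogate regression** — one row per surgery:
   (age, A, AP, LAT, spring k and L0 ×2, b_in) → b_out; standardised,
   split 0.33 to test; seven model families screened by 5-fold CV against
   a linear baseline; the survivors tuned by a 50-evaluation seeded
   search; headline model: multi-output support vector regression.
6. **Prediction & validation** — project a new head into the shape space,
   predict b_out, reconstruct, and score against a reference surface with
   exact point-to-triangle distances after volume matching.

## Worked example

```python
from cranioplan.pipeline import run_corpus, train_surrogate, predict_outcome
from cranioplan.springs import SurgicalConfig, SpringSpec
from cranioplan.mesh import offset_mesh

# full synthetic study: 30 patients x ~80 configurations (~2400 simulations)
corpus = run_corpus(n_patients=30, master_seed=0)
model, report, split = train_surrogate(corpus, kind="svm", tune=True, seed=0)
print(round(report.r2, 4), round(report.mse, 4), round(report.mae, 4))
# 0.9641 0.0385 0.1123

# predict one patient's outcome for a chosen surgical plan
pid = 0
params = corpus.patients[pid]
head = offset_mesh(corpus.skulls[pid].mesh, params.t_skin, "outward")
plan = SurgicalConfig(A=0.24, AP=0.55, LAT=0.18,
                      anterior_spring=SpringSpec(1.5, 60.0, "model-3"),
                      posterior_spring=SpringSpec(1.5, 60.0, "model-3"))
rep = predict_outcome(head, params.age_days, plan, corpus, model, split,
                      t_skin=params.t_skin)
print(f"CI {rep.preop_ci:.1f} -> {rep.predicted_ci:.1f}")
# CI 61.3 -> 61.6
```

The three numbers after training are the held-out test metrics of the
tuned SVR on the standardised output-mode scale: the coefficient of
determination (1 is perfect), mean squared error and mean absolute error
(0 is perfect) — i.e. how faithfully the surrogate reproduces the
simulator's outcome shapes for unseen surgical configurations.  The
cranial index (100 × width / length) rises under the stiffest springs;
simulated gains are deliberately modest (see `docs/methods.md` on the
extent-based CI).

The same workflow is scriptable from the shell (`cranioplan --help`):
`generate-population`, `run-corpus`, `train`, `predict`, `simulate`,
`evaluate`, `fit-template`, `correlate`.

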