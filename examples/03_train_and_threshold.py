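"""Train the ESA direction model and pick its operating point.

The ternary (UP/STAY/DOWN) net is trained with inverse-ratio class weights
on rectified records; the two-step classifier then needs a threshold T for
the STAY decision, chosen as the ROC point nearest (0, 1) on the
STAY-vs-NON-STAY problem.
"""

from anemiadss import (
    GeneratorConfig,
    Medication,
    ModelConfig,
    apply_normalizer,
    build_features,
    classify_all,
    fit_normalizer,
    generate,
    inverse_ratio_weights,
    predict,
    rectify,
    roc_curve,
    select_threshold,
    train_model,
)
from anemiadss.twostep import default_grid

cohort = generate(GeneratorConfig(n_patients=30, n_occasions=52, seed=42,
                                  p_delay=0.15, p_label_noise=0.05))
cohort, _ = rectify(cohort)

ds = build_features(cohort, Medication.ESA)
norm = fit_normalizer(ds)
dsn = apply_normalizer(norm, ds)

weights = inverse_ratio_weights(dsn.class_counts())
print("class counts:", dsn.class_counts())
print("inverse-ratio weights:",
      {c: round(w, 3) for c, w in zip(weights.classes, weights.values)})

model = train_model(ModelConfig(medication=Medication.ESA, seed=0,
                                epochs=120, batch_size=128), dsn, weights)
probs = predict(model, dsn)

roc = roc_curve(probs, dsn.y, dsn.classes, grid=default_grid())
thr = select_threshold(roc)
pred = classify_all(probs, thr, dsn.classes)
acc = (pred == dsn.y).mean()
print(f"STAY-vs-NON-STAY AUC: {roc.auc:.3f}")
print(f"selected threshold T = {thr.t:.3f}")
print(f"training-set agreement with recorded directions: {acc:.3f}")
# The AUC measures how well the model separates dose-change occasions from
# STAY occasions; T near 0.5 balances the two error kinds.  Training-set
# agreement is optimistic — see the leave-one-patient-out example for an
# honest estimate.
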