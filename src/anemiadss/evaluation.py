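"""Validation of direction models against recorded physician decisions.

Two schemes mirror how this kind of decision-support system is validated:

* LOPO — leave-one-patient-out: each fold trains on N-1 patients
  (normalizer, class weights, threshold all re-derived from the fold's
  training data only) and predicts the held-out patient; rates are pooled
  over all patients' occasions.
* RDV — raw-data validation: train once on one cohort, evaluate untouched
  on a disjoint cohort.

Agreement is summarized as replication rates: R_TOTAL is the fraction of
occasions where the system gives the physician's direction on the same
date, and R_UP / R_STAY / R_DOWN condition on the physician's class
(per-class recall).  Disagreements are then categorized: a *before
physician* call is the same UP/DOWN the physician gave, only up to
``horizon`` occasions earlier (credited to at most one prediction per
recorded change); on synthetic cohorts a prediction matching the
generator's latent policy label counts as *latent-appropriate* (the
automatable stand-in for clinically-appropriate-on-review); anything else
is incorrect — or *unreviewed* on real cohorts, where appropriateness
needs a human reviewer.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort, Direction, Medication
from .features import (
    FeatureConfig,
    FeatureDataset,
    apply_normalizer,
    build_features,
    classes_for,
    fit_normalizer,
)
from .models import (
    ClassWeights,
    DecisionModel,
    ModelConfig,
    equalize_recalls,
    inverse_ratio_weights,
    train_model,
)
from .rectify import rectify
from .twostep import (
    REFERENCE_THRESHOLDS,
    RocCurve,
    Threshold,
    classify_all,
    default_grid,
    roc_curve,
    select_threshold,
)

__all__ = [
    "LeakageError",
    "EvalSettings",
    "Rates",
    "ValidationReport",
    "replication_rates",
    "before_physician",
    "categorize",
    "lopo",
    "raw_data_validation",
]

CATEGORIES = ("correct", "before_physician", "latent_appropriate", "incorrect",
              "unreviewed")


class LeakageError(RuntimeError):
    """Training and validation data share patients."""


@dataclass(frozen=True)
class EvalSettings:
    """Everything a validation run needs beyond the cohort(s)."""

    feature_config: FeatureConfig = FeatureConfig()
    model_config: ModelConfig = ModelConfig()
    use_class_weights: bool = True
    equalize: bool = True
    equalize_tol: float = 0.1
    equalize_max_rounds: int = 2
    equalize_gamma: float = 0.5
    grid_size: int = 201
    horizon: int = 3
    rectify_training: bool = True
    rectify_validation: bool = False
    max_lag_occasions: int = 1
    use_two_step: bool = True      # False: plain argmax (ablation)
    seed: int = 0

    def fingerprint(self) -> str:
        payload = asdict(self)
        payload["feature_config"] = asdict(self.feature_config)
        mc = asdict(self.model_config)
        mc["medication"] = self.model_config.medication.value
        payload["model_config"] = mc
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class Rates:
    r_total: float
    per_class: dict[str, float]          # NaN when class absent from truth
    precision: dict[str, float]

    @property
    def r_up(self) -> float:
        return self.per_class.get("UP", float("nan"))

    @property
    def r_stay(self) -> float:
        return self.per_class.get("STAY", float("nan"))

    @property
    def r_down(self) -> float:
        return self.per_class.get("DOWN", float("nan"))


def replication_rates(
    pred: Sequence[Direction],
    truth: Sequence[Direction],
    classes: Sequence[str] = ("UP", "STAY", "DOWN"),
) -> Rates:
    """R_TOTAL plus per-class recalls and precisions.

    Classes absent from the truth get recall NaN (undefined, excluded from
    any summary); same for precision when never predicted."""
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if len(pred) == 0:
        raise ValueError("cannot compute rates on empty sequences")
    p = np.array([d.value for d in pred])
    t = np.array([d.value for d in truth])
    per_class = {}
    precision = {}
    for c in classes:
        mask = t == c
        per_class[c] = float((p[mask] == c).mean()) if mask.any() else float("nan")
        pmask = p == c
        precision[c] = float((t[pmask] == c).mean()) if pmask.any() else float("nan")
    return Rates(r_total=float((p == t).mean()), per_class=per_class,
                 precision=precision)


def before_physician(
    pred: Sequence[Direction],
    truth: Sequence[Direction],
    horizon: int = 3,
) -> list[bool]:
    """Flags for "same direction, just earlier" calls.

    Occasion t is flagged when the system calls UP/DOWN, the physician
    recorded STAY, and the physician gives that same direction within the
    next ``horizon`` occasions.  Each recorded change credits at most one
    earlier prediction — the nearest one — and each prediction is credited
    at most once.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if len(pred) != len(truth):
        raise ValueError("pred and truth must be aligned")
    n = len(pred)
    flagged = [False] * n
    for event in range(n):
        if truth[event] is Direction.STAY:
            continue
        for t in range(event - 1, max(-1, event - horizon - 1), -1):
            if (not flagged[t]
                    and truth[t] is Direction.STAY
                    and pred[t] is truth[event]
                    and pred[t] is not Direction.STAY):
                flagged[t] = True
                break
    return flagged


def categorize(
    pred: Sequence[Direction],
    truth: Sequence[Direction],
    latent: Optional[Sequence[Direction]] = None,
    horizon: int = 3,
) -> list[str]:
    """Per-occasion outcome category, assigned in priority order
    correct > before_physician > latent_appropriate > incorrect.
    Without latent labels the residual category is ``unreviewed``."""
    if latent is not None and len(latent) != len(pred):
        raise ValueError("latent labels misaligned with predictions")
    bp = before_physician(pred, truth, horizon=horizon)
    out = []
    for i, (p, t) in enumerate(zip(pred, truth)):
        if p is t:
            out.append("correct")
        elif bp[i]:
            out.append("before_physician")
        elif latent is not None and p is latent[i]:
            out.append("latent_appropriate")
        else:
            out.append("incorrect" if latent is not None else "unreviewed")
    return out


@dataclass
class ValidationReport:
    scheme: str                                # "LOPO" | "RDV"
    medication: str
    r_total: float
    per_class: dict[str, float]
    precision: dict[str, float]
    category_counts: dict[str, int]
    gross_appropriate_rate: float
    thresholds: list[float]
    auc: Optional[float]
    n_patients: int
    n_occasions: int
    r_total_per_patient_mean: float
    seed: int
    fingerprint: str
    leakage_audit_passed: bool = True
    detail: Optional[pd.DataFrame] = field(default=None, repr=False)

    @property
    def r_up(self) -> float:
        return self.per_class.get("UP", float("nan"))

    @property
    def r_stay(self) -> float:
        return self.per_class.get("STAY", float("nan"))

    @property
    def r_down(self) -> float:
        return self.per_class.get("DOWN", float("nan"))

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "detail"}
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _train_fold(
    ds: FeatureDataset,
    medication: Medication,
    settings: EvalSettings,
    seed: int,
) -> tuple[DecisionModel, Threshold]:
    norm = fit_normalizer(ds)
    dsn = apply_normalizer(norm, ds)
    mc = replace(settings.model_config, medication=medication, seed=seed)
    classes = dsn.classes

    if settings.use_class_weights:
        weights = inverse_ratio_weights(dsn.class_counts())
    else:
        weights = ClassWeights.uniform(classes)

    if settings.use_class_weights and settings.equalize:
        trainer = lambda w: train_model(mc, dsn, w)
        _, details = equalize_recalls(
            trainer, dsn, weights,
            tol=settings.equalize_tol,
            max_rounds=settings.equalize_max_rounds,
            gamma=settings.equalize_gamma,
            return_details=True,
        )
        model = details.model
    else:
        model = train_model(mc, dsn, weights)
    model.normalizer = norm

    if settings.use_two_step:
        probs = model.predict_proba(dsn)
        try:
            roc = roc_curve(probs, dsn.y, classes,
                            grid=default_grid(settings.grid_size))
            thr = select_threshold(roc, medication)
        except ValueError:
            # single-class training labels: no curve; use the shipped
            # reference operating point
            thr = Threshold(REFERENCE_THRESHOLDS[medication], medication)
    else:
        thr = Threshold(t=0.0, medication=medication)  # ignored under argmax
    return model, thr


def _predict_directions(
    model: DecisionModel,
    ds: FeatureDataset,
    settings: EvalSettings,
    thr: Threshold,
) -> tuple[FeatureDataset, np.ndarray, np.ndarray]:
    dsn = apply_normalizer(model.normalizer, ds)
    probs = model.predict_proba(dsn)
    if settings.use_two_step:
        idx = classify_all(probs, thr, dsn.classes)
    else:
        idx = probs.argmax(axis=1)
    return dsn, probs, idx


def _assemble_report(
    scheme: str,
    medication: Medication,
    rows: pd.DataFrame,
    thresholds: list[float],
    auc: Optional[float],
    n_patients: int,
    settings: EvalSettings,
    leakage_ok: bool,
) -> ValidationReport:
    classes = classes_for(medication)
    pred = [Direction(v) for v in rows["pred"]]
    truth = [Direction(v) for v in rows["truth"]]
    rates = replication_rates(pred, truth, classes)

    has_latent = rows["latent"].notna().all()
    cats: list[str] = []
    for _, grp in rows.groupby("patient_id", sort=False):
        grp = grp.sort_values("occ_index")
        p = [Direction(v) for v in grp["pred"]]
        t = [Direction(v) for v in grp["truth"]]
        lat = [Direction(v) for v in grp["latent"]] if has_latent else None
        cats.extend(categorize(p, t, lat, horizon=settings.horizon))
    rows = rows.copy()
    rows["category"] = cats
    counts = {c: int((rows["category"] == c).sum()) for c in CATEGORIES}
    total = len(rows)
    gross = (counts["correct"] + counts["before_physician"]
             + counts["latent_appropriate"]) / total
    per_patient = rows.assign(ok=rows["pred"] == rows["truth"]) \
                      .groupby("patient_id")["ok"].mean()
    return ValidationReport(
        scheme=scheme,
        medication=medication.value,
        r_total=rates.r_total,
        per_class=rates.per_class,
        precision=rates.precision,
        category_counts=counts,
        gross_appropriate_rate=gross,
        thresholds=thresholds,
        auc=auc,
        n_patients=n_patients,
        n_occasions=total,
        r_total_per_patient_mean=float(per_patient.mean()),
        seed=settings.seed,
        fingerprint=settings.fingerprint(),
        leakage_audit_passed=leakage_ok,
        detail=rows,
    )


def lopo(
    cohort: Cohort,
    medication: Medication = Medication.ESA,
    settings: EvalSettings = EvalSettings(),
) -> ValidationReport:
    """Leave-one-patient-out validation, pooled per occasion.

    Rectification (when enabled) is applied to training folds only; the
    held-out patient is evaluated on the raw record.  Patients with no
    evaluable occasion (shorter than the feature warm-up) are skipped.
    """
    if cohort.n_patients < 2:
        raise ValueError("LOPO needs at least two patients")
    base = rectify(cohort, settings.max_lag_occasions)[0] if settings.rectify_training \
        else cohort
    eval_base = rectify(cohort, settings.max_lag_occasions)[0] \
        if settings.rectify_validation else cohort

    # features never cross patients, so build once and subset per fold
    fc = settings.feature_config
    ds_train_full = build_features(base, medication, fc)
    ds_eval_full = build_features(eval_base, medication, fc)

    all_rows = []
    thresholds = []
    leakage_ok = True
    evaluated_patients = 0
    for k, patient in enumerate(cohort.patients):
        hold_mask = ds_eval_full.patient_ids == patient.patient_id
        if not hold_mask.any():
            continue  # shorter than the feature warm-up
        evaluated_patients += 1
        train_mask = ds_train_full.patient_ids != patient.patient_id
        leakage_ok &= not (ds_train_full.patient_ids[train_mask]
                           == patient.patient_id).any()
        model, thr = _train_fold(ds_train_full.subset(train_mask), medication,
                                 settings, seed=settings.seed + k)
        dsn, probs, idx = _predict_directions(
            model, ds_eval_full.subset(hold_mask), settings, thr)
        classes = dsn.classes
        lat = dsn.latent_y
        all_rows.append(pd.DataFrame({
            "patient_id": dsn.patient_ids,
            "occ_index": dsn.occ_indices,
            "pred": [classes[i] for i in idx],
            "truth": [classes[i] for i in dsn.y],
            "latent": [classes[i] for i in lat] if lat is not None else [None] * len(dsn),
            "p_stay": probs[:, classes.index("STAY")],
        }))
        thresholds.append(thr.t)

    rows = pd.concat(all_rows, ignore_index=True)
    # pooled first-step discrimination across folds
    try:
        classes = classes_for(medication)
        s = classes.index("STAY")
        # only the STAY column matters for the first-step ROC
        pooled_probs = np.full((len(rows), len(classes)),
                               (1 - rows["p_stay"].to_numpy()[:, None]) / (len(classes) - 1))
        pooled_probs[:, s] = rows["p_stay"]
        y = np.array([classes.index(v) for v in rows["truth"]])
        auc = roc_curve(pooled_probs, y, classes).auc
    except ValueError:
        auc = None
    return _assemble_report("LOPO", medication, rows, thresholds, auc,
                            evaluated_patients, settings, leakage_ok)


def raw_data_validation(
    train_cohort: Cohort,
    valid_cohort: Cohort,
    medication: Medication = Medication.ESA,
    settings: EvalSettings = EvalSettings(),
) -> ValidationReport:
    """Train once on one cohort, evaluate untouched on a disjoint cohort.
    Overlapping patient ids are a hard error."""
    train_ids = {p.patient_id for p in train_cohort.patients}
    valid_ids = {p.patient_id for p in valid_cohort.patients}
    overlap = train_ids & valid_ids
    if overlap:
        raise LeakageError(f"patients in both cohorts: {sorted(overlap)[:5]}")

    base = rectify(train_cohort, settings.max_lag_occasions)[0] \
        if settings.rectify_training else train_cohort
    ds_train = build_features(base, medication, settings.feature_config)
    model, thr = _train_fold(ds_train, medication, settings, seed=settings.seed)
    target = rectify(valid_cohort, settings.max_lag_occasions)[0] \
        if settings.rectify_validation else valid_cohort
    ds_valid = build_features(target, medication, settings.feature_config)
    dsn, probs, idx = _predict_directions(model, ds_valid, settings, thr)
    classes = dsn.classes
    lat = dsn.latent_y
    rows = pd.DataFrame({
        "patient_id": dsn.patient_ids,
        "occ_index": dsn.occ_indices,
        "pred": [classes[i] for i in idx],
        "truth": [classes[i] for i in dsn.y],
        "latent": [classes[i] for i in lat] if lat is not None else [None] * len(dsn),
        "p_stay": probs[:, classes.index("STAY")],
    })
    try:
        auc = roc_curve(probs, dsn.y, classes).auc
    except ValueError:
        auc = None
    return _assemble_report("RDV", medication, rows, [thr.t], auc,
                            valid_cohort.n_patients, settings, True)
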