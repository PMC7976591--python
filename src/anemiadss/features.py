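"""Per-occasion model inputs.

For every evaluable occasion t the feature row holds, per analyte
(hemoglobin, MCV, ferritin, TSAT): the current level, the previous level
and their first difference (the trend); the ESA and IS dose histories over
the last ``history_len`` occasions *ending at t-1* (the current occasion's
dose is the decision being predicted, so it is excluded); and a
weeks-on-iron counter.  Ferritin and TSAT are drawn only monthly, so they
are carried forward from the latest panel; hemoglobin and MCV are carried
forward across the occasional missing panel (a delayed-decision occasion).

The decision models consume the rows for occasions t-1 and t stacked as a
length-two sequence — the dense ESA net flattened, the recurrent IS net
stepwise — so feature matrices here have shape (rows, 2, n_features).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .cohort import Cohort, Direction, Medication

logger = logging.getLogger(__name__)

__all__ = [
    "ESA_CLASSES",
    "IS_CLASSES",
    "classes_for",
    "FeatureConfig",
    "FeatureDataset",
    "Normalizer",
    "build_features",
    "fit_normalizer",
    "apply_normalizer",
]

ESA_CLASSES: tuple[str, ...] = ("UP", "STAY", "DOWN")
IS_CLASSES: tuple[str, ...] = ("UP", "STAY")

_ANALYTES = ("hb", "mcv", "ferritin", "tsat")


def classes_for(medication: Medication) -> tuple[str, ...]:
    return ESA_CLASSES if medication is Medication.ESA else IS_CLASSES


@dataclass(frozen=True)
class FeatureConfig:
    history_len: int = 4           # dose-history horizon H, occasions
    warmup: int = 4                # first evaluable occasion index
    include_dose_history: bool = True   # ablation switch
    occasion_interval_days: int = 7

    def __post_init__(self) -> None:
        if self.warmup < max(self.history_len, 1):
            raise ValueError("warmup must be >= history_len (and >= 1)")

    def feature_names(self) -> list[str]:
        names: list[str] = []
        for a in _ANALYTES:
            names += [f"{a}", f"{a}_prev", f"{a}_trend"]
        if self.include_dose_history:
            for k in range(self.history_len, 0, -1):
                names.append(f"esa_units_m{k}")
            for k in range(self.history_len, 0, -1):
                names.append(f"is_units_m{k}")
        names.append("weeks_on_iron")
        return names


@dataclass(frozen=True)
class Normalizer:
    center: np.ndarray
    scale: np.ndarray

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(np.asarray(d["center"], dtype=np.float64),
                   np.asarray(d["scale"], dtype=np.float64))


@dataclass(frozen=True)
class FeatureDataset:
    """Rows of stacked two-timing features with aligned labels.

    X has shape (n_rows, 2, n_features): timing 0 is occasion t-1, timing 1
    is occasion t.  y holds label indices into ``classes``; latent_y the
    generator's uncorrupted policy labels when available.
    """

    medication: Medication
    X: np.ndarray
    y: np.ndarray
    patient_ids: np.ndarray
    occ_indices: np.ndarray
    feature_names: tuple[str, ...]
    classes: tuple[str, ...]
    latent_y: Optional[np.ndarray] = None
    normalized: bool = False
    normalizer: Optional[Normalizer] = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if self.X.shape[0] != n or self.X.ndim != 3 or self.X.shape[1] != 2:
            raise ValueError(f"X must have shape (n, 2, d); got {self.X.shape}")
        if self.X.shape[2] != len(self.feature_names):
            raise ValueError("feature_names length does not match X")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[2]

    def subset(self, mask: np.ndarray) -> "FeatureDataset":
        return replace(
            self,
            X=self.X[mask],
            y=self.y[mask],
            patient_ids=self.patient_ids[mask],
            occ_indices=self.occ_indices[mask],
            latent_y=self.latent_y[mask] if self.latent_y is not None else None,
        )

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.y == i).sum()) for i, c in enumerate(self.classes)}


def _carry_forward_panels(patient) -> dict[str, list[float]]:
    """Last-observation-carried-forward analyte series, one value per
    occasion.  Values before the first observation are back-filled."""
    n = len(patient.occasions)
    series = {a: [np.nan] * n for a in _ANALYTES}
    for t, occ in enumerate(patient.occasions):
        if occ.panel is None:
            continue
        p = occ.panel
        series["hb"][t] = p.hb
        series["mcv"][t] = p.mcv
        if p.ferritin is not None:
            series["ferritin"][t] = p.ferritin
        if p.tsat is not None:
            series["tsat"][t] = p.tsat
    for a in _ANALYTES:
        vals = series[a]
        last = None
        for t in range(n):
            if not np.isnan(vals[t]):
                last = vals[t]
            elif last is not None:
                vals[t] = last
        first = next((v for v in vals if not np.isnan(v)), None)
        for t in range(n):
            if np.isnan(vals[t]):
                vals[t] = first if first is not None else 0.0
    return series


def _base_row(cfg: FeatureConfig, series, esa_units, is_units, t: int) -> list[float]:
    row: list[float] = []
    for a in _ANALYTES:
        cur = series[a][t]
        prev = series[a][t - 1] if t >= 1 else cur
        row += [cur, prev, cur - prev]
    if cfg.include_dose_history:
        for k in range(cfg.history_len, 0, -1):
            row.append(float(esa_units[t - k]) if t - k >= 0 else 0.0)
        for k in range(cfg.history_len, 0, -1):
            row.append(float(is_units[t - k]) if t - k >= 0 else 0.0)
    # consecutive dosed occasions ending at t-1, expressed in weeks
    run = 0
    j = t - 1
    while j >= 0 and is_units[j] > 0:
        run += 1
        j -= 1
    row.append(run * cfg.occasion_interval_days / 7.0)
    return row


def build_features(
    cohort: Cohort,
    medication: Medication,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureDataset:
    """One row per occasion with index >= warmup, per patient.

    Patients shorter than ``warmup + 1`` occasions are skipped with a log
    entry.  No feature for occasion t uses any quantity from occasion >= t
    except the current (carried-forward) blood panel.
    """
    classes = classes_for(medication)
    names = tuple(config.feature_names())
    X_rows, y_rows, lat_rows, pids, occs = [], [], [], [], []
    any_latent = cohort.has_latent

    for patient in cohort.patients:
        n = len(patient.occasions)
        if n <= config.warmup:
            logger.info("skipping patient %s: %d occasions < warmup %d",
                        patient.patient_id, n, config.warmup)
            continue
        series = _carry_forward_panels(patient)
        esa_units = [o.esa_dose.amount for o in patient.occasions]
        is_units = [o.is_dose.amount for o in patient.occasions]
        base = [
            _base_row(config, series, esa_units, is_units, t) for t in range(n)
        ]
        for t in range(config.warmup, n):
            X_rows.append([base[t - 1], base[t]])
            occ = patient.occasions[t]
            label = occ.esa_direction if medication is Medication.ESA else occ.is_direction
            y_rows.append(classes.index(label.value))
            if any_latent:
                lat = patient.latent_labels[t]
                lat_label = lat[0] if medication is Medication.ESA else lat[1]
                lat_rows.append(classes.index(lat_label.value))
            pids.append(patient.patient_id)
            occs.append(occ.index)

    if not X_rows:
        raise ValueError("no evaluable occasions: every patient shorter than warmup")
    return FeatureDataset(
        medication=medication,
        X=np.asarray(X_rows, dtype=np.float64),
        y=np.asarray(y_rows, dtype=np.int64),
        patient_ids=np.asarray(pids, dtype=object),
        occ_indices=np.asarray(occs, dtype=np.int64),
        feature_names=names,
        classes=classes,
        latent_y=np.asarray(lat_rows, dtype=np.int64) if any_latent else None,
    )


def fit_normalizer(train: FeatureDataset) -> Normalizer:
    """Per-feature center/scale from *training rows only* (both timings
    pooled).  Zero-variance features keep scale 1 so they pass through
    centered."""
    if len(train) == 0:
        raise ValueError("cannot fit a normalizer on an empty dataset")
    flat = train.X.reshape(-1, train.n_features)
    center = flat.mean(axis=0)
    scale = flat.std(axis=0)
    zero = scale < 1e-12
    if zero.any():
        logger.warning("zero-variance features %s: scale set to 1",
                       [train.feature_names[i] for i in np.flatnonzero(zero)])
        scale = np.where(zero, 1.0, scale)
    return Normalizer(center=center, scale=scale)


def apply_normalizer(params: Normalizer, ds: FeatureDataset) -> FeatureDataset:
    X = (ds.X - params.center) / params.scale
    return replace(ds, X=X, normalized=True, normalizer=params)
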