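"""Rectification of delayed dosing records.

In real dialysis records a dosing decision is sometimes entered one (or
two) occasions after the blood examination it was actually based on —
lab results arrive late, physicians work restricted hours.  Training on
such records teaches the model the wrong exam→decision pairing, so the
UP/DOWN records are moved back onto the occasion whose blood examination
triggered them; the vacated occasion becomes STAY.  STAY records are never
moved, and the total count of each non-STAY label is conserved (moves,
never creations), except for conflicts which are logged and left alone.

A non-STAY record counts as delayed when its occasion either lacks a blood
panel or has ``decision_date`` different from its ``exam_date``; the move
target is the nearest earlier occasion with a panel, at most
``max_lag_occasions`` back.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .cohort import Cohort, Direction, Occasion, PatientRecord

__all__ = ["RectificationEntry", "RectificationLog", "rectify", "rectification_rate"]


@dataclass(frozen=True)
class RectificationEntry:
    patient_id: str
    from_index: int
    to_index: int
    medication: str            # "ESA" | "IS"
    direction: str
    reason: str                # "moved" | "conflict" | "no_target"


@dataclass(frozen=True)
class RectificationLog:
    entries: tuple[RectificationEntry, ...]

    @property
    def moves(self) -> tuple[RectificationEntry, ...]:
        return tuple(e for e in self.entries if e.reason == "moved")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [vars(e) for e in self.entries],
            columns=["patient_id", "from_index", "to_index",
                     "medication", "direction", "reason"],
        )

    def write_csv(self, path) -> str:
        self.to_frame().to_csv(path, index=False)
        return str(path)


def _is_delayed(occ: Occasion) -> bool:
    if occ.panel is None:
        return True
    return occ.exam_date is not None and occ.decision_date != occ.exam_date


def rectify(cohort: Cohort, max_lag_occasions: int = 1) -> tuple[Cohort, RectificationLog]:
    """Move delayed non-STAY records back to the exam occasion they were
    based on.  Idempotent; returns the corrected cohort and a full log."""
    if max_lag_occasions < 1:
        raise ValueError("max_lag_occasions must be >= 1")

    entries: list[RectificationEntry] = []
    new_patients: list[PatientRecord] = []
    for patient in cohort.patients:
        occs = list(patient.occasions)
        for t, occ in enumerate(occs):
            for med, get_dir in (("ESA", lambda o: o.esa_direction),
                                 ("IS", lambda o: o.is_direction)):
                direction = get_dir(occs[t])
                if direction is Direction.STAY or not _is_delayed(occs[t]):
                    continue
                # nearest earlier occasion with a panel, within the lag window
                target = None
                for back in range(1, max_lag_occasions + 1):
                    if t - back >= 0 and occs[t - back].panel is not None:
                        target = t - back
                        break
                if target is None:
                    entries.append(RectificationEntry(
                        patient.patient_id, t, -1, med, direction.value, "no_target"))
                    continue
                tgt = occs[target]
                tgt_dir = get_dir(tgt)
                if tgt_dir is not Direction.STAY and tgt_dir is not direction:
                    entries.append(RectificationEntry(
                        patient.patient_id, t, target, med, direction.value, "conflict"))
                    continue
                if med == "ESA":
                    occs[target] = replace(tgt, esa_direction=direction)
                    occs[t] = replace(occs[t], esa_direction=Direction.STAY)
                else:
                    occs[target] = replace(tgt, is_direction=direction)
                    occs[t] = replace(occs[t], is_direction=Direction.STAY)
                entries.append(RectificationEntry(
                    patient.patient_id, t, target, med, direction.value, "moved"))
        new_patients.append(replace(patient, occasions=tuple(occs)))

    return (Cohort(name=cohort.name, patients=tuple(new_patients)),
            RectificationLog(entries=tuple(entries)))


def rectification_rate(log: RectificationLog, cohort: Cohort) -> float:
    """Fraction of the cohort's non-STAY records that were moved.

    ``cohort`` is the cohort the log was produced *from* (pre-rectification
    counts are the same as post, since moves conserve labels)."""
    non_stay = 0
    for p in cohort.patients:
        for occ in p.occasions:
            non_stay += occ.esa_direction is not Direction.STAY
            non_stay += occ.is_direction is not Direction.STAY
    if non_stay == 0:
        return 0.0
    return len(log.moves) / non_stay
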