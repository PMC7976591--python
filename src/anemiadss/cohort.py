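"""Domain types for longitudinal hemodialysis anemia-management records.

A cohort is a set of patients, each an ordered sequence of dialysis
*occasions* (every one or two weeks).  At each occasion the patient may have
a blood panel drawn (hemoglobin and MCV weekly; ferritin and TSAT roughly
monthly), receives erythropoiesis-stimulating agent (ESA) and iron
supplement (IS) doses in discrete syringe/ampoule units, and the physician
records a dosing direction per medication: UP, STAY or DOWN for the ESA,
UP or STAY for the IS (iron stops automatically after six weeks, so DOWN
is never issued).

Synthetic patients additionally carry the latent (uncorrupted) policy
labels the generator used, which downstream evaluation treats as the
clinical-appropriateness ground truth.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Medication",
    "Direction",
    "BloodPanel",
    "DoseEvent",
    "Occasion",
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "cohort_summary",
    "COHORT_COLUMNS",
]


class CohortValidationError(ValueError):
    """A record violates a domain invariant (out-of-range lab, bad ordering...)."""


class Medication(str, enum.Enum):
    ESA = "ESA"
    IS = "IS"


class Direction(str, enum.Enum):
    UP = "UP"
    STAY = "STAY"
    DOWN = "DOWN"


@dataclass(frozen=True)
class BloodPanel:
    """One blood examination.

    hb : hemoglobin, g/dl.  mcv : mean corpuscular volume, fl.
    ferritin (ng/ml) and tsat (%) are drawn only about monthly and are
    ``None`` on the other occasions.
    """

    hb: float
    mcv: float
    ferritin: Optional[float] = None
    tsat: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.hb > 0:
            raise CohortValidationError(f"hb must be > 0, got {self.hb}")
        if not self.mcv > 0:
            raise CohortValidationError(f"mcv must be > 0, got {self.mcv}")
        if self.ferritin is not None and self.ferritin < 0:
            raise CohortValidationError(f"ferritin must be >= 0, got {self.ferritin}")
        if self.tsat is not None and not (0 <= self.tsat <= 100):
            raise CohortValidationError(f"tsat must be in [0, 100], got {self.tsat}")


@dataclass(frozen=True)
class DoseEvent:
    """A medication dose at one occasion, in discrete syringe/ampoule units."""

    medication: Medication
    amount: int
    drug_label: str = ""
    amount_ug: Optional[float] = None

    def __post_init__(self) -> None:
        if self.amount < 0 or int(self.amount) != self.amount:
            raise CohortValidationError(
                f"dose amount must be a non-negative integer, got {self.amount}"
            )
        if self.amount_ug is not None and self.amount_ug < 0:
            raise CohortValidationError(f"amount_ug must be >= 0, got {self.amount_ug}")


@dataclass(frozen=True)
class Occasion:
    """One hemodialysis occasion with its labs, doses and recorded directions.

    ``exam_date`` is the date of the blood examination the occasion's
    recorded direction was based on; it is absent when no panel was
    available (the signature of a delayed decision).  ``decision_date`` is
    the date the direction was entered into the record.
    """

    index: int
    esa_dose: DoseEvent
    is_dose: DoseEvent
    esa_direction: Direction
    is_direction: Direction
    decision_date: date
    exam_date: Optional[date] = None
    panel: Optional[BloodPanel] = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise CohortValidationError(f"occasion index must be >= 0, got {self.index}")
        if self.is_direction is Direction.DOWN:
            raise CohortValidationError("IS directions are binary: DOWN is not allowed")
        if self.exam_date is not None and self.decision_date < self.exam_date:
            raise CohortValidationError(
                f"decision_date {self.decision_date} precedes exam_date {self.exam_date}"
            )
        if self.esa_dose.medication is not Medication.ESA:
            raise CohortValidationError("esa_dose must carry medication=ESA")
        if self.is_dose.medication is not Medication.IS:
            raise CohortValidationError("is_dose must carry medication=IS")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    occasions: tuple[Occasion, ...]
    # (esa, is) latent policy labels, synthetic cohorts only
    latent_labels: Optional[tuple[tuple[Direction, Direction], ...]] = None

    def __post_init__(self) -> None:
        idx = [o.index for o in self.occasions]
        if idx != sorted(set(idx)):
            raise CohortValidationError(
                f"patient {self.patient_id}: occasion indices not strictly increasing"
            )
        dates = [o.decision_date for o in self.occasions]
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise CohortValidationError(
                f"patient {self.patient_id}: decision dates not monotone"
            )
        if self.latent_labels is not None and len(self.latent_labels) != len(self.occasions):
            raise CohortValidationError(
                f"patient {self.patient_id}: latent label length mismatch"
            )

    def __len__(self) -> int:
        return len(self.occasions)


@dataclass(frozen=True)
class Cohort:
    name: str
    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        if len(self.patients) < 1:
            raise CohortValidationError("cohort must contain at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise CohortValidationError("duplicate patient_id in cohort")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_occasions(self) -> int:
        return sum(len(p) for p in self.patients)

    @property
    def has_latent(self) -> bool:
        return all(p.latent_labels is not None for p in self.patients)


@dataclass(frozen=True)
class CohortSummary:
    n_patients: int
    n_occasions: int
    esa_counts: dict[str, int]
    is_counts: dict[str, int]
    hb_in_range_fraction: float


COHORT_COLUMNS = [
    "patient_id", "occ_index", "exam_date", "decision_date",
    "hb", "mcv", "ferritin", "tsat",
    "esa_drug", "esa_units", "esa_ug", "is_drug", "is_units",
    "esa_dir", "is_dir", "latent_esa_dir", "latent_is_dir",
]


def _fmt_date(d: Optional[date]) -> str:
    return d.isoformat() if d is not None else ""


def write_cohort(cohort: Cohort, path, seed: Optional[int] = None) -> str:
    """Write a cohort as CSV, one row per occasion, deterministic column order.

    Missing labs become empty cells (never zeros).  An optional seed is
    recorded as a ``#`` header comment for provenance.
    """
    rows = []
    for p in cohort.patients:
        for i, occ in enumerate(p.occasions):
            lat = p.latent_labels[i] if p.latent_labels is not None else None
            panel = occ.panel
            rows.append({
                "patient_id": p.patient_id,
                "occ_index": occ.index,
                "exam_date": _fmt_date(occ.exam_date),
                "decision_date": _fmt_date(occ.decision_date),
                "hb": panel.hb if panel else None,
                "mcv": panel.mcv if panel else None,
                "ferritin": panel.ferritin if panel else None,
                "tsat": panel.tsat if panel else None,
                "esa_drug": occ.esa_dose.drug_label,
                "esa_units": occ.esa_dose.amount,
                "esa_ug": occ.esa_dose.amount_ug,
                "is_drug": occ.is_dose.drug_label,
                "is_units": occ.is_dose.amount,
                "esa_dir": occ.esa_direction.value,
                "is_dir": occ.is_direction.value,
                "latent_esa_dir": lat[0].value if lat else "",
                "latent_is_dir": lat[1].value if lat else "",
            })
    frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    with open(path, "w") as fh:
        fh.write(f"# cohort={cohort.name}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        frame.to_csv(fh, index=False)
    return str(path)


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or pd.isna(value):
        return None
    return float(value)


def _parse_date(value) -> Optional[date]:
    if value is None or value == "" or pd.isna(value):
        return None
    return date.fromisoformat(str(value))


def read_cohort(path, name: Optional[str] = None) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-built to
    the same schema).  Raises :class:`CohortValidationError` naming the
    offending row on malformed content."""
    with open(path) as fh:
        header_name = None
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            if line.startswith("# cohort="):
                header_name = line.strip().split("=", 1)[1]
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh, dtype={"patient_id": str})
    missing = [c for c in COHORT_COLUMNS[:15] if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"cohort file missing columns: {missing}")

    patients = []
    for pid, grp in frame.groupby("patient_id", sort=False):
        grp = grp.sort_values("occ_index")
        occasions = []
        latent: list[tuple[Direction, Direction]] = []
        has_latent = False
        for rownum, row in grp.iterrows():
            try:
                hb = _opt_float(row["hb"])
                panel = None
                if hb is not None:
                    panel = BloodPanel(
                        hb=hb,
                        mcv=_opt_float(row["mcv"]),
                        ferritin=_opt_float(row["ferritin"]),
                        tsat=_opt_float(row["tsat"]),
                    )
                occ = Occasion(
                    index=int(row["occ_index"]),
                    exam_date=_parse_date(row["exam_date"]),
                    decision_date=_parse_date(row["decision_date"]),
                    panel=panel,
                    esa_dose=DoseEvent(
                        Medication.ESA,
                        int(row["esa_units"]),
                        str(row["esa_drug"]) if not pd.isna(row["esa_drug"]) else "",
                        _opt_float(row.get("esa_ug")),
                    ),
                    is_dose=DoseEvent(
                        Medication.IS,
                        int(row["is_units"]),
                        str(row["is_drug"]) if not pd.isna(row["is_drug"]) else "",
                    ),
                    esa_direction=Direction(row["esa_dir"]),
                    is_direction=Direction(row["is_dir"]),
                )
            except (CohortValidationError, ValueError, KeyError) as exc:
                raise CohortValidationError(
                    f"row {rownum} (patient {pid}): {exc}"
                ) from exc
            occasions.append(occ)
            lat_e = row.get("latent_esa_dir")
            lat_i = row.get("latent_is_dir")
            if isinstance(lat_e, str) and lat_e and isinstance(lat_i, str) and lat_i:
                has_latent = True
                latent.append((Direction(lat_e), Direction(lat_i)))
        patients.append(PatientRecord(
            patient_id=str(pid),
            occasions=tuple(occasions),
            latent_labels=tuple(latent) if has_latent and len(latent) == len(occasions) else None,
        ))
    return Cohort(name=name or header_name or "cohort", patients=tuple(patients))


def cohort_summary(cohort: Cohort) -> CohortSummary:
    """N, W, per-class direction counts and the fraction of panelled
    occasions with hemoglobin inside the 10.0-12.0 g/dl target range."""
    esa_counts = {d.value: 0 for d in Direction}
    is_counts = {d.value: 0 for d in (Direction.UP, Direction.STAY)}
    in_range = 0
    with_panel = 0
    for p in cohort.patients:
        for occ in p.occasions:
            esa_counts[occ.esa_direction.value] += 1
            is_counts[occ.is_direction.value] += 1
            if occ.panel is not None:
                with_panel += 1
                if 10.0 <= occ.panel.hb <= 12.0:
                    in_range += 1
    return CohortSummary(
        n_patients=cohort.n_patients,
        n_occasions=cohort.n_occasions,
        esa_counts=esa_counts,
        is_counts=is_counts,
        hb_in_range_fraction=in_range / with_panel if with_panel else float("nan"),
    )
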