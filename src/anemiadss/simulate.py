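"""Synthetic hemodialysis-cohort generator.

Emulates the statistical structure of real anemia-management records so the
full pipeline is testable without clinical data:

* weekly (or biweekly) dialysis occasions with hemoglobin/MCV drawn every
  occasion and ferritin/TSAT only every ``iron_panel_period`` occasions;
* first-order dose-responsive hemoglobin dynamics,
  ``hb_{t+1} = hb_t - hb_decay * (hb_t - floor_t) + esa_effect * u_t + noise``,
  with a slowly drifting anemic baseline ``floor_t`` so the controller must
  act from time to time;
* a deterministic latent physician policy holding Hb in the 10.0-12.0 g/dl
  target range (UP when low/falling, DOWN when high/rising, a two-occasion
  cooldown after any dose change) and starting iron when ferritin/TSAT run
  low, with the automatic six-week iron stop;
* recording corruption: with probability ``p_label_noise`` a latent non-STAY
  direction is recorded as STAY (a missed change), and with probability
  ``p_delay`` a non-STAY decision is recorded one occasion late — the
  carrying occasion has no blood panel (the unavailable lab result being
  the real-world cause of such delays) and its ``decision_date`` is the
  recording date, which is exactly what record rectification undoes.

Doses always follow the latent (undelayed) policy; corruption is purely a
recording artifact, so rectification of a delay-only corrupted cohort
recovers the latent labels exactly.

The default configuration is calibrated so that the ESA direction mix is
roughly 85% STAY with DOWN somewhat more frequent than UP, the imbalance
regime this kind of maintenance-dialysis dataset exhibits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Optional

import numpy as np
import yaml

from .cohort import (
    BloodPanel,
    Cohort,
    CohortValidationError,
    Direction,
    DoseEvent,
    Medication,
    Occasion,
    PatientRecord,
)

__all__ = [
    "GeneratorConfig",
    "LatentPolicy",
    "GenerationStats",
    "generate",
    "generate_with_stats",
    "imbalance_report",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort.  Units in comments."""

    n_patients: int = 100
    n_occasions: int = 60
    occasion_interval_days: int = 7          # 7 or 14
    hb_target_low: float = 10.0              # g/dl
    hb_target_high: float = 12.0             # g/dl
    esa_effect: float = 0.40                 # g/dl rise per dose unit per occasion
    hb_decay: float = 0.20                   # fraction of (hb - floor) lost per occasion
    lab_noise_sd: float = 0.45               # g/dl week-to-week biological + analytic
    dose_response_exponent: float = 0.7      # concave ESA dose-response (hyporesponse at high dose)
    iron_panel_period: int = 4               # occasions between ferritin/TSAT draws
    is_stop_weeks: int = 6                   # automatic iron stop horizon
    p_delay: float = 0.0                     # probability a non-STAY record is one occasion late
    p_label_noise: float = 0.0               # probability a latent non-STAY is recorded STAY
    seed: int = 0
    # patient heterogeneity / drift
    hb_floor_mean: float = 9.0               # g/dl anemic baseline
    hb_floor_sd: float = 0.5
    floor_drift_sd: float = 0.13             # g/dl random walk per occasion
    floor_drift_mean: float = 0.012          # g/dl/occasion upward creep (drives DOWN excess)
    max_esa_units: int = 5
    decision_cooldown: int = 2               # occasions between dose changes
    trend_margin: float = 0.3                # g/dl band where trend matters
    trend_threshold: float = 0.30            # g/dl per occasion
    # iron compartment
    ferritin_low: float = 100.0              # ng/ml iron-start threshold
    tsat_low: float = 20.0                   # % iron-start threshold
    two_esa_drugs: bool = True               # pool two agents with different potency

    def __post_init__(self) -> None:
        if not (0 <= self.p_delay <= 1 and 0 <= self.p_label_noise <= 1):
            raise ValueError("corruption probabilities must be in [0, 1]")
        if not self.hb_target_low < self.hb_target_high:
            raise ValueError("hb_target_low must be < hb_target_high")
        for name in ("esa_effect", "hb_decay", "lab_noise_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_patients < 1 or self.n_occasions < 2:
            raise ValueError("need at least 1 patient and 2 occasions")
        if self.occasion_interval_days not in (7, 14):
            raise ValueError("occasion_interval_days must be 7 or 14")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class LatentPolicy:
    """Deterministic stand-in for the experienced physician.

    ESA: UP when hemoglobin is below target (or near-low and falling fast),
    DOWN when above target (or near-high and rising fast), else STAY; a dose
    change is followed by a cooldown of ``decision_cooldown`` occasions so
    its effect can be observed, and directions respect the dose bounds.

    IS: UP (start iron) when the latest ferritin or TSAT is below threshold
    and no course is running; otherwise STAY.  A course runs for
    ``is_stop_weeks`` weeks and then stops automatically.
    """

    hb_target_low: float
    hb_target_high: float
    trend_margin: float
    trend_threshold: float
    decision_cooldown: int
    max_esa_units: int
    ferritin_low: float
    tsat_low: float

    @classmethod
    def from_config(cls, cfg: GeneratorConfig) -> "LatentPolicy":
        return cls(
            hb_target_low=cfg.hb_target_low,
            hb_target_high=cfg.hb_target_high,
            trend_margin=cfg.trend_margin,
            trend_threshold=cfg.trend_threshold,
            decision_cooldown=cfg.decision_cooldown,
            max_esa_units=cfg.max_esa_units,
            ferritin_low=cfg.ferritin_low,
            tsat_low=cfg.tsat_low,
        )

    def esa_direction(
        self,
        hb: float,
        hb_prev: float,
        current_units: int,
        occasions_since_change: int,
    ) -> Direction:
        if occasions_since_change < self.decision_cooldown:
            return Direction.STAY
        trend = hb - hb_prev
        low, high = self.hb_target_low, self.hb_target_high
        wants_up = hb < low or (hb < low + self.trend_margin and trend < -self.trend_threshold)
        wants_down = hb > high or (hb > high - self.trend_margin and trend > self.trend_threshold)
        if wants_up and current_units < self.max_esa_units:
            return Direction.UP
        if wants_down and current_units > 0:
            return Direction.DOWN
        return Direction.STAY

    def is_direction(
        self,
        ferritin_latest: float,
        tsat_latest: float,
        course_active: bool,
        occasions_since_change: int,
    ) -> Direction:
        if course_active or occasions_since_change < self.decision_cooldown:
            return Direction.STAY
        if ferritin_latest < self.ferritin_low or tsat_latest < self.tsat_low:
            return Direction.UP
        return Direction.STAY


@dataclass
class GenerationStats:
    """Generator-side bookkeeping, the oracle for corruption-rate tests."""

    esa_latent_counts: dict = field(default_factory=dict)
    is_latent_counts: dict = field(default_factory=dict)
    n_noise_flips: int = 0
    n_delays: int = 0
    n_delay_eligible: int = 0


def _simulate_patient(pid: str, cfg: GeneratorConfig, policy: LatentPolicy,
                      rng: np.random.Generator, stats: GenerationStats,
                      start: date):
    n = cfg.n_occasions
    interval = cfg.occasion_interval_days
    stop_occasions = max(1, round(cfg.is_stop_weeks * 7 / interval))

    floor = float(np.clip(rng.normal(cfg.hb_floor_mean, cfg.hb_floor_sd), 7.5, 9.8))
    if cfg.two_esa_drugs and rng.random() < 0.5:
        drug, potency = "esa-beta", 0.85
    else:
        drug, potency = "esa-alfa", 1.0
    effect = cfg.esa_effect * potency
    ug_per_unit = 10.0 if drug == "esa-alfa" else 12.5

    # start near mid-target with a consistent dose
    hb = float(rng.uniform(10.3, 11.7))
    hb_prev = hb + float(rng.normal(0, cfg.lab_noise_sd))
    expo = cfg.dose_response_exponent
    units = int(np.clip(
        round(((hb - floor) * cfg.hb_decay / effect) ** (1.0 / expo)),
        0, cfg.max_esa_units))
    ferritin = float(np.clip(rng.normal(160.0, 50.0), 25.0, 400.0))
    tsat = float(np.clip(ferritin / 8.0 + rng.normal(5.0, 3.0), 2.0, 60.0))

    esa_cool = cfg.decision_cooldown
    is_cool = cfg.decision_cooldown
    is_course_left = 0
    is_units = 0
    fer_latest, tsat_latest = ferritin, tsat

    latent: list[tuple[Direction, Direction]] = []
    panels: list[Optional[BloodPanel]] = []
    esa_units_path: list[int] = []
    is_units_path: list[int] = []
    drug_labels: list[str] = []
    dates = [start + timedelta(days=interval * t) for t in range(n)]

    for t in range(n):
        iron_drawn = (t % cfg.iron_panel_period) == 0
        mcv = float(np.clip(88.0 + 0.02 * (ferritin - 150.0) + rng.normal(0, 1.5), 70.0, 110.0))
        panel = BloodPanel(
            hb=round(max(hb, 4.0), 2),
            mcv=round(mcv, 1),
            ferritin=round(max(ferritin, 1.0), 1) if iron_drawn else None,
            tsat=round(float(np.clip(tsat, 1.0, 99.0)), 1) if iron_drawn else None,
        )
        if iron_drawn:
            fer_latest, tsat_latest = panel.ferritin, panel.tsat
        panels.append(panel)

        d_esa = policy.esa_direction(panel.hb, hb_prev, units, esa_cool)
        d_is = policy.is_direction(fer_latest, tsat_latest, is_course_left > 0, is_cool)
        latent.append((d_esa, d_is))

        # apply the direction to the dose administered this occasion
        if d_esa is Direction.UP:
            units += 1
            esa_cool = 0
        elif d_esa is Direction.DOWN:
            units -= 1
            esa_cool = 0
        else:
            esa_cool += 1
        if d_is is Direction.UP:
            is_course_left = stop_occasions
            is_cool = 0
        else:
            is_cool += 1
        if is_course_left > 0:
            is_units = 1
            is_course_left -= 1
        else:
            is_units = 0

        esa_units_path.append(units)
        is_units_path.append(is_units)
        drug_labels.append(drug)

        # advance physiology
        hb_prev = panel.hb
        floor = float(np.clip(
            floor + rng.normal(cfg.floor_drift_mean, cfg.floor_drift_sd), 7.0, 10.3))
        hb = hb - cfg.hb_decay * (hb - floor) + effect * units ** expo + float(
            rng.normal(0, cfg.lab_noise_sd))
        drain = 3.0 + 2.5 * units
        ferritin = float(np.clip(
            ferritin - drain + 35.0 * is_units + rng.normal(0, 8.0), 5.0, 600.0))
        tsat = float(np.clip(ferritin / 8.0 + rng.normal(5.0, 3.0), 2.0, 60.0))

    for d_esa, d_is in latent:
        stats.esa_latent_counts[d_esa.value] = stats.esa_latent_counts.get(d_esa.value, 0) + 1
        stats.is_latent_counts[d_is.value] = stats.is_latent_counts.get(d_is.value, 0) + 1

    # --- recording corruption --------------------------------------------
    rec = [list(pair) for pair in latent]
    for t in range(n):
        for m in (0, 1):
            if rec[t][m] is not Direction.STAY and rng.random() < cfg.p_label_noise:
                rec[t][m] = Direction.STAY
                stats.n_noise_flips += 1

    delayed = [False] * n
    for t in range(n - 1):
        moved_any = False
        non_stay = [m for m in (0, 1) if rec[t][m] is not Direction.STAY]
        if not non_stay or delayed[t]:
            continue
        # a delay can only land on an occasion that carries no decision of
        # its own (the cooldown makes the successor latent-STAY)
        if any(rec[t + 1][m] is not Direction.STAY for m in (0, 1)):
            continue
        stats.n_delay_eligible += 1
        if rng.random() < cfg.p_delay:
            for m in non_stay:
                rec[t + 1][m] = rec[t][m]
                rec[t][m] = Direction.STAY
            delayed[t + 1] = True
            stats.n_delays += 1

    occasions = []
    for t in range(n):
        panel = None if delayed[t] else panels[t]
        occasions.append(Occasion(
            index=t,
            exam_date=None if delayed[t] else dates[t],
            decision_date=dates[t],
            panel=panel,
            esa_dose=DoseEvent(
                Medication.ESA, esa_units_path[t], drug_labels[t],
                round(esa_units_path[t] * ug_per_unit, 1)),
            is_dose=DoseEvent(Medication.IS, is_units_path[t], "ferrous-citrate"),
            esa_direction=rec[t][0],
            is_direction=rec[t][1],
        ))
    return PatientRecord(patient_id=pid, occasions=tuple(occasions),
                         latent_labels=tuple(latent))


def generate_with_stats(cfg: GeneratorConfig) -> tuple[Cohort, GenerationStats]:
    """Generate a cohort plus the generator's own corruption bookkeeping."""
    rng = np.random.default_rng(cfg.seed)
    stats = GenerationStats()
    start = date(2021, 1, 4)
    width = len(str(cfg.n_patients - 1))
    patients = tuple(
        _simulate_patient(f"P{i:0{width}d}", cfg, LatentPolicy.from_config(cfg),
                          rng, stats, start)
        for i in range(cfg.n_patients)
    )
    return Cohort(name=f"synthetic-seed{cfg.seed}", patients=patients), stats


def generate(cfg: GeneratorConfig) -> Cohort:
    """Generate a synthetic cohort; same config (incl. seed) => same cohort."""
    return generate_with_stats(cfg)[0]


def imbalance_report(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Recorded-direction class fractions per medication (they sum to 1)."""
    esa = {d.value: 0 for d in Direction}
    iss = {d.value: 0 for d in (Direction.UP, Direction.STAY)}
    for p in cohort.patients:
        for occ in p.occasions:
            esa[occ.esa_direction.value] += 1
            iss[occ.is_direction.value] += 1
    w = cohort.n_occasions
    return {
        "ESA": {k: v / w for k, v in esa.items()},
        "IS": {k: v / w for k, v in iss.items()},
    }
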