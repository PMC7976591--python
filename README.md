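# anemiadss

Decision support for anemia management in maintenance hemodialysis.

Hemodialysis patients receive erythropoiesis-stimulating agents (ESAs) and
iron supplements (ISs) to keep hemoglobin inside a guideline target range
(10.0–12.0 g/dl).  Doses are adjusted in discrete syringe/ampoule units, so
at every dialysis occasion the physician's decision per medication is one of
three directions — **UP**, **STAY**, **DOWN** (UP/STAY only for iron, which
stops automatically after six weeks).  Experienced physicians who make these
calls well are scarce; this package implements, end to end, a system that
learns the dosing *directions* of experienced physicians from longitudinal
records — no physiological prediction model — and the evaluation machinery
needed to judge such a system honestly.

It is a library for people who study clinical decision-support methods:
every stage is importable, deterministic given its seed, and testable
against a built-in synthetic cohort generator, so no clinical data are
required to run or extend any part of it.

## What is implemented

* **Cohort model** (`anemiadss.cohort`) — typed longitudinal records
  (blood panels, discrete dose events, recorded directions) with a CSV
  schema, one row per occasion.
* **Synthetic cohorts** (`anemiadss.simulate`) — dose-responsive
  hemoglobin dynamics under a latent target-range physician policy, monthly
  iron panels, the six-week iron stop, recording delays and label noise,
  calibrated so recorded ESA directions are ≈85 % STAY — the class
  imbalance regime real maintenance cohorts exhibit.
* **Rectification** (`anemiadss.rectify`) — delayed UP/DOWN records (a
  decision entered one occasion after the blood exam it was based on) are
  moved back to their exam occasion; exact, idempotent, fully logged.
* **Features** (`anemiadss.features`) — per occasion *t*: levels and
  one-step trends of Hb, MCV, ferritin, TSAT (iron values carried forward
  from the latest monthly panel), ESA/IS dose histories ending at *t−1*,
  and a weeks-on-iron counter; rows for *t−1* and *t* are stacked as a
  two-timing sequence.
* **Decision models** (`anemiadss.models`) — a dense feed-forward net for
  the ternary ESA decision and a recurrent (Elman) net for the binary IS
  decision, both 10 hidden layers with L1 regularization and dropout,
  trained on class-weighted cross-entropy.  Class weights start at the
  inverse ratios w<sub>c</sub> = W/(K·n<sub>c</sub>) and are iteratively
  adjusted until per-class training recalls are approximately equal.
* **Two-step classification** (`anemiadss.twostep`) — STAY iff
  P<sub>STAY</sub> > T, else the larger of P<sub>UP</sub>/P<sub>DOWN</sub>;
  T is selected as the point on the STAY-vs-NON-STAY ROC curve nearest
  (FPR, TPR) = (0, 1).
* **Evaluation** (`anemiadss.evaluation`) — leave-one-patient-out (LOPO)
  and raw-data validation (RDV) with replication rates
  (R<sub>TOTAL</sub>, R<sub>UP</sub>, R<sub>STAY</sub>, R<sub>DOWN</sub>),
  leakage audits, and outcome categorization including *before-physician*
  crediting (same dose change, up to three occasions earlier).
* **Pipeline + CLI** (`anemiadss.config`, `anemiadss.cli`) — a YAML-driven
  `run_pipeline` and a thin `anemiadss` command with `simulate`,
  `rectify`, `train`, `roc`, `evaluate` and `run` subcommands.

## Worked example

`examples/04_validate_lopo.py` generates a 30-patient synthetic cohort with
recording delays (p = 0.15) and label noise (p = 0.05) and runs the full
pipeline under leave-one-patient-out validation:

```
pooled R_TOTAL: 88.5%
per-class recalls: {'UP': 0.713, 'STAY': 0.911, 'DOWN': 0.743}
outcome categories: {'correct': 1275, 'before_physician': 61,
                     'latent_appropriate': 37, 'incorrect': 67}
gross clinically-appropriate rate: 95.3%
median selected threshold: 0.380
```

R<sub>TOTAL</sub> counts exact same-date agreement with the recorded
physician direction.  The categories then split the disagreements: 61
occasions were the *same* dose change called up to three occasions earlier
than the physician (before-physician), and 37 matched the generator's
uncorrupted policy where the record itself was noise-corrupted
(latent-appropriate).  The gross clinically-appropriate rate sums correct
and both appropriate categories — here 95.3 % — and is the better measure
of usefulness, since exact-date replication punishes the system for being
early or for disagreeing with a corrupted label.

The other example scripts show each capability in isolation: cohort
simulation and imbalance (`01`), rectification recovery (`02`), training
plus ROC threshold selection (`03`).

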