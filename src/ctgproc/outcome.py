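"""Objective perinatal outcome classification.

Implements the acidosis and encephalopathy predicates and the eight
mutually exclusive study groups used to phenotype a birth cohort for
hypoxic-ischemic encephalopathy (HIE) research:

* neonatal acidosis: lowest-pH cord gas (arterial or venous) with
  pH < 7.0 or base deficit >= 10 mmol/L, or base deficit >= 10 mmol/L on
  the first infant gas before 2 h of age;
* perinatal HIE: acidosis plus any abnormality on the six-item Sarnat
  (ENE) exam plus at least one confirmatory criterion (therapeutic
  hypothermia, abnormal exam beyond 6 h, or confirmed seizures in the
  first 24 h);
* HIE severity: moderate/severe with >= 3 abnormal ENE items or
  seizures, otherwise mild.

Groups are evaluated in a fixed precedence (death under 6 h first, then
perinatal HIE, distant HIE, acidosis without HIE, then the healthy /
intervention splits by blood-gas availability); every record receives
exactly one group, with an evidence trail.  Acidotic infants with an
abnormal exam but none of the three confirmatory criteria match no
printed group definition and are reported UNCLASSIFIED rather than
silently binned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "BloodGas",
    "InfantRecord",
    "StudyGroup",
    "AcidosisResult",
    "is_acidotic",
    "classify_study_group",
    "hie_severity",
]


class StudyGroup(str, Enum):
    PERINATAL_HIE = "PERINATAL_HIE"
    ACIDOSIS_NO_HIE = "ACIDOSIS_NO_HIE"
    HEALTHY_NO_BG = "HEALTHY_NO_BG"
    HEALTHY_NO_ACIDOSIS = "HEALTHY_NO_ACIDOSIS"
    INTERVENTION_NO_BG = "INTERVENTION_NO_BG"
    INTERVENTION_NO_ACIDOSIS = "INTERVENTION_NO_ACIDOSIS"
    DISTANT_HIE = "DISTANT_HIE"
    DEATH_UNDER_6H = "DEATH_UNDER_6H"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass
class BloodGas:
    source: str  # arterial | venous | capillary
    ph: float | None = None
    base_deficit: float | None = None  # mmol/L
    age_h: float | None = None  # infant gases only


@dataclass
class InfantRecord:
    infant_id: str
    cord_gases: list[BloodGas] = field(default_factory=list)
    infant_gases: list[BloodGas] = field(default_factory=list)
    ene_abnormal_items: int = 0  # 0-6 Sarnat items abnormal (worst, 1-6 h)
    ene_recorded: bool = False
    abnormal_exam_ge_6h: bool = False
    seizures_first_24h: bool = False
    hypothermia: bool = False  # passive, active or transient
    apgar5: int | None = None
    apgar10: int | None = None
    nicu_admit: bool = False
    discharged_home: bool = True
    death_or_transfer: bool = False
    death_age_h: float | None = None
    intubation_or_compressions: bool = False
    seizure_meds: bool = False
    hie_imaging_pattern: bool = False  # deep grey / watershed injury

    def __post_init__(self) -> None:
        if not 0 <= self.ene_abnormal_items <= 6:
            raise ValueError("ene_abnormal_items must be 0-6")
        if self.death_age_h is not None and self.death_age_h < 0:
            raise ValueError("death_age_h must be >= 0")


@dataclass
class AcidosisResult:
    status: str  # acidotic | not_acidotic | no_gas
    evidence: str = ""

    @property
    def is_acidotic(self) -> bool:
        return self.status == "acidotic"


PH_THRESHOLD = 7.0  # strict: acidosis requires pH < 7.0
BD_THRESHOLD = 10.0  # inclusive: base deficit >= 10 mmol/L
INFANT_GAS_MAX_AGE_H = 2.0  # first infant gas must be before 2 h of age


def is_acidotic(rec: InfantRecord) -> AcidosisResult:
    """Apply the neonatal-acidosis predicate with an evidence string."""
    cord = [g for g in rec.cord_gases if g.ph is not None or g.base_deficit is not None]
    infant = [
        g
        for g in rec.infant_gases
        if g.ph is not None or g.base_deficit is not None
    ]
    if not cord and not infant:
        return AcidosisResult("no_gas", "no cord or infant blood gas")
    if cord:
        with_ph = [g for g in cord if g.ph is not None]
        pick = min(with_ph, key=lambda g: g.ph) if with_ph else cord[0]
        if pick.ph is not None and pick.ph < PH_THRESHOLD:
            return AcidosisResult("acidotic", f"cord pH {pick.ph} < 7.0 ({pick.source})")
        if pick.base_deficit is not None and pick.base_deficit >= BD_THRESHOLD:
            return AcidosisResult(
                "acidotic", f"cord BD {pick.base_deficit} >= 10 ({pick.source})"
            )
    early = [
        g for g in infant if g.age_h is not None and g.age_h < INFANT_GAS_MAX_AGE_H
    ]
    if early:
        first = min(early, key=lambda g: g.age_h)
        if first.base_deficit is not None and first.base_deficit >= BD_THRESHOLD:
            return AcidosisResult(
                "acidotic",
                f"infant gas at {first.age_h} h BD {first.base_deficit} >= 10",
            )
    return AcidosisResult("not_acidotic", "gases present, none meet acidosis criteria")


def _any_intervention(rec: InfantRecord) -> bool:
    return (
        (rec.apgar5 is not None and rec.apgar5 < 7)
        or rec.nicu_admit
        or rec.death_or_transfer
        or not rec.discharged_home
        or rec.ene_abnormal_items > 0
        or rec.intubation_or_compressions
        or rec.seizures_first_24h
        or rec.seizure_meds
        or rec.hypothermia
    )


def _all_healthy(rec: InfantRecord) -> bool:
    return (
        rec.apgar5 is not None
        and rec.apgar5 >= 7
        and not rec.nicu_admit
        and rec.discharged_home
        and not rec.death_or_transfer
        and rec.ene_abnormal_items == 0
        and not rec.intubation_or_compressions
        and not rec.seizures_first_24h
        and not rec.seizure_meds
        and not rec.hypothermia
    )


def classify_study_group(rec: InfantRecord) -> tuple[StudyGroup, str]:
    """Assign exactly one study group, returning (group, evidence trail).

    Precedence: death under 6 h, perinatal HIE, distant HIE, acidosis
    without HIE, then the no-gas / gas branches split into healthy vs
    neonatal intervention.
    """
    trail = []
    if rec.death_age_h is not None and rec.death_age_h < 6.0:
        return StudyGroup.DEATH_UNDER_6H, f"died at {rec.death_age_h} h"

    acid = is_acidotic(rec)
    trail.append(acid.evidence)
    confirmatory = (
        rec.hypothermia or rec.abnormal_exam_ge_6h or rec.seizures_first_24h
    )
    if acid.is_acidotic and rec.ene_abnormal_items > 0 and confirmatory:
        return StudyGroup.PERINATAL_HIE, "; ".join(
            trail + [f"ENE items {rec.ene_abnormal_items}", "confirmatory criterion met"]
        )
    if rec.hie_imaging_pattern:
        return StudyGroup.DISTANT_HIE, "; ".join(
            trail + ["HIE-pattern imaging, no perinatal HIE"]
        )
    if acid.is_acidotic and rec.ene_abnormal_items == 0 and not confirmatory:
        return StudyGroup.ACIDOSIS_NO_HIE, "; ".join(
            trail + ["no encephalopathy, no confirmatory criteria"]
        )
    if acid.is_acidotic:
        # abnormal exam without confirmation, or confirmation without exam:
        # matches no printed definition
        return StudyGroup.UNCLASSIFIED, "; ".join(
            trail
            + [
                f"acidotic with ENE items {rec.ene_abnormal_items}, "
                f"confirmatory={confirmatory}: no printed group fits"
            ]
        )
    if acid.status == "no_gas":
        if _all_healthy(rec):
            return StudyGroup.HEALTHY_NO_BG, "no gases; all healthy criteria met"
        return StudyGroup.INTERVENTION_NO_BG, "no gases; intervention criteria met"
    if _all_healthy(rec):
        return StudyGroup.HEALTHY_NO_ACIDOSIS, "; ".join(
            trail + ["all healthy criteria met"]
        )
    return StudyGroup.INTERVENTION_NO_ACIDOSIS, "; ".join(
        trail + ["intervention criteria met"]
    )


def hie_severity(rec: InfantRecord) -> str:
    """Grade perinatal HIE: moderate_severe with >= 3 abnormal ENE items
    or seizures, otherwise mild.  Raises on non-HIE records."""
    group, _ = classify_study_group(rec)
    if group is not StudyGroup.PERINATAL_HIE:
        raise ValueError("hie_severity requires a PERINATAL_HIE record")
    if rec.ene_abnormal_items >= 3 or rec.seizures_first_24h:
        return "moderate_severe"
    return "mild"
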