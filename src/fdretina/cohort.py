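"""Study-design logic: study-eye selection, quality filtering, and the
mapping of scans to repeatability / reproducibility comparisons.

Scan 1 is acquired by observer 1; scans 2 and 3 by observer 2.
Repeatability compares scans 2 vs 3 (same observer); reproducibility
compares scans 1 vs 2 (different observers).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import InputError

SIGNAL_STRENGTH_MIN = 7

REPEATABILITY_PAIR = (2, 3)  # both observer 2
REPRODUCIBILITY_PAIR = (1, 2)  # observer 1 vs observer 2


@dataclass
class EyeQuality:
    signal_strength: int = 10
    segmentation_ok: bool = True
    artefact_free: bool = True
    interpretable: bool = True

    @property
    def acceptable(self) -> bool:
        return (self.interpretable and self.segmentation_ok
                and self.artefact_free
                and self.signal_strength >= SIGNAL_STRENGTH_MIN)


@dataclass
class ParticipantRecord:
    participant_id: str
    birth_year: int
    age: Optional[float] = None
    sex: Optional[str] = None
    right_eye_quality: EyeQuality = field(default_factory=EyeQuality)
    left_eye_quality: EyeQuality = field(default_factory=EyeQuality)


@dataclass
class StudyDesign:
    repeatability_pair: tuple[int, int] = REPEATABILITY_PAIR
    reproducibility_pair: tuple[int, int] = REPRODUCIBILITY_PAIR


def select_study_eye(record: ParticipantRecord) -> str:
    """Pick the analysed eye: right for even birth years, left for odd;
    fall back to the other eye if the chosen one fails quality; return
    ``"excluded"`` when both eyes fail."""
    preferred = "right" if record.birth_year % 2 == 0 else "left"
    other = "left" if preferred == "right" else "right"
    quality = {"right": record.right_eye_quality,
               "left": record.left_eye_quality}
    if quality[preferred].acceptable:
        return preferred
    if quality[other].acceptable:
        return other
    return "excluded"


def apply_quality_filters(cohort: list[ParticipantRecord]):
    """Split a cohort into included records and an exclusion log.

    Returns ``(included, log)`` where ``log`` is a DataFrame with columns
    participant_id, decision, rule_fired.
    """
    if not cohort:
        raise InputError("cohort must be non-empty")
    included = []
    rows = []
    for rec in cohort:
        eye = select_study_eye(rec)
        if eye == "excluded":
            rows.append({"participant_id": rec.participant_id,
                         "decision": "excluded",
                         "rule_fired": "both_eyes_fail_quality"})
        else:
            included.append(rec)
            rows.append({"participant_id": rec.participant_id,
                         "decision": "included",
                         "rule_fired": f"study_eye_{eye}"})
    return included, pd.DataFrame(rows)


def assemble_comparisons(measurements: pd.DataFrame,
                         design: StudyDesign | None = None):
    """Build per-plexus n x 2 tables for both comparisons.

    ``measurements`` needs columns participant_id, scan_index, plexus, fd.
    Participants missing a scan for a comparison are dropped from that
    comparison (and logged).  Returns ``(tables, dropped)`` where
    ``tables[(plexus, comparison)]`` is a DataFrame indexed by participant
    with one column per scan in the pair, and ``dropped`` is a DataFrame
    logging removed participants.
    """
    design = design or StudyDesign()
    required = {"participant_id", "scan_index", "plexus", "fd"}
    if not required.issubset(measurements.columns):
        raise InputError(f"measurements must have columns {sorted(required)}")
    tables = {}
    drop_rows = []
    comparisons = {"repeatability": design.repeatability_pair,
                   "reproducibility": design.reproducibility_pair}
    for plexus in sorted(measurements["plexus"].unique()):
        sub = measurements[measurements["plexus"] == plexus]
        wide = sub.pivot(index="participant_id", columns="scan_index",
                         values="fd")
        for name, (a, b) in comparisons.items():
            cols = [c for c in (a, b) if c in wide.columns]
            if len(cols) < 2:
                pair = wide.iloc[:0, :0]
            else:
                pair = wide[[a, b]].dropna()
                for pid in wide.index.difference(pair.index):
                    drop_rows.append({"participant_id": pid,
                                      "plexus": plexus,
                                      "comparison": name,
                                      "reason": "missing_scan"})
            tables[(plexus, name)] = pair
    dropped = pd.DataFrame(drop_rows,
                           columns=["participant_id", "plexus",
                                    "comparison", "reason"])
    return tables, dropped
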