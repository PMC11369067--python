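"""Mayo-score arithmetic and the trial's deterministic response classification.

The partial Mayo score sums three clinical subscores (stool frequency, rectal
bleeding, physician global assessment; each 0-3).  The endoscopic subscore
uses the 5-level ordered scale 0 < 1a < 1b < 2 < 3 (grade 1 split into
erythema without/with friability); 1a and 1b both contribute 1 to the full
Mayo score but are distinct steps when counting endoscopic improvement.

Classification rules:

* **Week 10** (partial Mayo only) — remission: partial Mayo <= 2 with no
  individual subscore > 2; partial response: a decrease of >= 3 points in the
  partial Mayo score from baseline; otherwise no response.
* **Week 14** (full Mayo) — remission: the week-10 clinical criterion plus an
  endoscopic subscore of 0 or 1a; partial remission: a clinical decrease of
  >= 3 points plus a decrease of >= 1 step on the endoscopic scale (1b -> 1a
  counts); otherwise no response.
* Dropout due to progressive disease is treatment failure: no response.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

ENDOSCOPIC_LEVELS = ("0", "1a", "1b", "2", "3")
ENDOSCOPIC_RANK = {level: i for i, level in enumerate(ENDOSCOPIC_LEVELS)}
ENDOSCOPIC_NUMERIC = {"0": 0, "1a": 1, "1b": 1, "2": 2, "3": 3}

REMISSION, PARTIAL, NONE = "remission", "partial", "none"


@dataclass(frozen=True)
class MayoAssessment:
    """One visit's Mayo components; ``endoscopic`` is optional for partial-Mayo visits."""

    stool_frequency: int
    rectal_bleeding: int
    physician_global: int
    endoscopic: str | None = None
    week: int = 0

    def __post_init__(self) -> None:
        for name in ("stool_frequency", "rectal_bleeding", "physician_global"):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and 0 <= v <= 3):
                raise ValueError(f"{name} must be an integer in 0..3, got {v!r}")
        if self.endoscopic is not None and self.endoscopic not in ENDOSCOPIC_RANK:
            raise ValueError(f"endoscopic subscore must be one of {ENDOSCOPIC_LEVELS}, got {self.endoscopic!r}")

    @property
    def subscores(self) -> tuple[int, int, int]:
        return (self.stool_frequency, self.rectal_bleeding, self.physician_global)


@dataclass(frozen=True)
class ResponseCall:
    subject_id: str
    week: int
    call: str  # remission | partial | none
    reason: str


def partial_mayo(a: MayoAssessment) -> int:
    """Sum of the three clinical subscores (0-9)."""
    return sum(a.subscores)


def full_mayo(a: MayoAssessment) -> int:
    """Partial Mayo plus the numeric endoscopic subscore (1a and 1b both count 1)."""
    if a.endoscopic is None:
        raise ValueError("full Mayo requires an endoscopic subscore")
    return partial_mayo(a) + ENDOSCOPIC_NUMERIC[a.endoscopic]


def _clinical_remission(a: MayoAssessment, max_subscore: int = 2) -> bool:
    # "no complaints": partial Mayo <= 2 with no individual subscore above the cutoff
    return partial_mayo(a) <= 2 and max(a.subscores) <= max_subscore


def classify_week10(
    baseline: MayoAssessment,
    wk10: MayoAssessment | None,
    dropped_out: bool = False,
    subject_id: str = "",
    max_subscore: int = 2,
) -> ResponseCall:
    """Week-10 call from the partial Mayo score; dropout forces no response."""
    if baseline is None:
        raise ValueError(f"subject {subject_id or '?'}: missing baseline assessment")
    if dropped_out:
        return ResponseCall(subject_id, 10, NONE, "dropout-treatment-failure")
    if wk10 is None:
        raise ValueError(f"subject {subject_id or '?'}: missing week-10 assessment without dropout flag")
    if _clinical_remission(wk10, max_subscore):
        return ResponseCall(subject_id, 10, REMISSION, "partial-mayo<=2-no-subscore>2")
    if partial_mayo(baseline) - partial_mayo(wk10) >= 3:
        return ResponseCall(subject_id, 10, PARTIAL, "partial-mayo-decrease>=3")
    return ResponseCall(subject_id, 10, NONE, "no-criterion-met")


def classify_week14(
    baseline: MayoAssessment,
    wk14: MayoAssessment | None,
    dropped_out: bool = False,
    subject_id: str = "",
    max_subscore: int = 2,
) -> ResponseCall:
    """Week-14 call from the full Mayo score; dropout forces no response."""
    if baseline is None:
        raise ValueError(f"subject {subject_id or '?'}: missing baseline assessment")
    if dropped_out:
        return ResponseCall(subject_id, 14, NONE, "dropout-treatment-failure")
    if wk14 is None or wk14.endoscopic is None:
        raise ValueError(f"subject {subject_id or '?'}: missing week-14 endoscopy without dropout flag")
    if baseline.endoscopic is None:
        raise ValueError(f"subject {subject_id or '?'}: baseline endoscopic subscore required at week 14")
    if _clinical_remission(wk14, max_subscore) and ENDOSCOPIC_RANK[wk14.endoscopic] <= ENDOSCOPIC_RANK["1a"]:
        return ResponseCall(subject_id, 14, REMISSION, "clinical-remission+endoscopic<=1a")
    clinical_drop = partial_mayo(baseline) - partial_mayo(wk14) >= 3
    endo_drop = ENDOSCOPIC_RANK[baseline.endoscopic] - ENDOSCOPIC_RANK[wk14.endoscopic] >= 1
    if clinical_drop and endo_drop:
        return ResponseCall(subject_id, 14, PARTIAL, "partial-mayo-decrease>=3+endoscopic-step-decrease")
    return ResponseCall(subject_id, 14, NONE, "no-criterion-met")


def responder_flag(call: ResponseCall) -> bool:
    """Responders pool remission and partial remission."""
    return call.call in (REMISSION, PARTIAL)


def read_mayo_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a Mayo-assessment table (one row per subject visit)."""
    sep = "\t" if dialect == "tsv" else ","
    mayo = pd.read_csv(path, sep=sep, dtype={"endoscopic": "string"})
    required = {"subject_id", "week", "stool_frequency", "rectal_bleeding", "physician_global"}
    missing = required - set(mayo.columns)
    if missing:
        raise ValueError(f"{path}: Mayo table missing column(s) {sorted(missing)}")
    return mayo


def _assessment_from_row(row: pd.Series) -> MayoAssessment:
    endo = row.get("endoscopic")
    if pd.isna(endo):
        endo = None
    return MayoAssessment(
        stool_frequency=int(row["stool_frequency"]),
        rectal_bleeding=int(row["rectal_bleeding"]),
        physician_global=int(row["physician_global"]),
        endoscopic=endo,
        week=int(row["week"]),
    )


def classify_cohort(mayo: pd.DataFrame, max_subscore: int = 2) -> pd.DataFrame:
    """Week-10 and week-14 calls for every subject in a Mayo table.

    The baseline is the subject's earliest assessment.  A ``dropped_out``
    column (truthy per row) marks subjects who left the study for progressive
    disease; they are classified as no response at both weeks.
    """
    records = []
    for subject, rows in mayo.groupby("subject_id"):
        rows = rows.sort_values("week")
        dropped = bool(rows.get("dropped_out", pd.Series(False, index=rows.index)).any())
        baseline = _assessment_from_row(rows.iloc[0])
        by_week = {int(r["week"]): _assessment_from_row(r) for _, r in rows.iterrows()}
        wk10 = classify_week10(baseline, by_week.get(10), dropped, str(subject), max_subscore)
        wk14 = classify_week14(baseline, by_week.get(14), dropped, str(subject), max_subscore)
        records.append(
            {
                "subject_id": subject,
                "response_week10": wk10.call,
                "reason_week10": wk10.reason,
                "response_week14": wk14.call,
                "reason_week14": wk14.reason,
                "responder_week10": responder_flag(wk10),
                "responder_week14": responder_flag(wk14),
            }
        )
    return pd.DataFrame.from_records(records).set_index("subject_id", drop=False)
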