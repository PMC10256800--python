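"""Ordinal histopathology modelling and biomarker-vs-pathology concordance.

Trichrome-stained sections are scored on an ordinal collagen scale
(no significant, minimal, mild, moderate, marked, severe; a reading between
two categories, e.g. "minimal-mild", maps to the midpoint).  H&E sections
yield structural diagnoses from a closed vocabulary, each with a strength on
the same scale.  A subject x contour point is called Damaged when it shows
mild-or-worse collagen or fibrosis (artifact-suspect collagen findings do
not count as damage evidence), NotDamaged when it shows essentially no
collagen and no mild-or-worse diagnosis, and Intermediate otherwise.

The ventilation biomarker at a point is reduced to Decline / NoDecline and
crossed against the pathology class; the agreement rule is an explicit
policy table (Decline matches Damaged; NoDecline matches NotDamaged and is
also compatible with Intermediate findings, whose mild changes need not have
altered ventilation).  The policy is configurable, and the default is an
interpretation: the study never prints its operational rule, and this table
is the unique reading consistent with its printed tally and disagreement
identities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GROUP_B_CONTOURS, get_logger
from .ventilation import ChangeClass

__all__ = [
    "COLLAGEN_SCALE",
    "DIAGNOSIS_VOCABULARY",
    "CollagenGrade",
    "DiagnosisRecord",
    "PathologyClass",
    "BiomarkerClass",
    "ConcordanceTable",
    "DEFAULT_AGREEMENT_POLICY",
    "parse_collagen_grade",
    "parse_strength",
    "pathology_damage_class",
    "biomarker_point_class",
    "agreement",
    "build_concordance",
    "diagnosis_tally",
    "paired_t_test",
]

log = get_logger("concordance")

#: Ordinal collagen scale; hyphenated range labels map to midpoints.
COLLAGEN_SCALE = {
    "no significant": 0.0,
    "minimal": 1.0,
    "mild": 2.0,
    "moderate": 3.0,
    "marked": 4.0,
    "severe": 5.0,
}

DIAGNOSIS_VOCABULARY = frozenset(
    {
        "fibrosis",
        "inflammation",
        "chondrocyte_necrosis",
        "histiocytosis",
        "multinucleated_giant_cells",
        "bronchitis",
        "bronchial_ulceration",
        "type2_pneumocyte_hyperplasia",
        "alveolar_septa_thickening",
        "vascular_proliferation",
        "neovascularization",
        "vascular_necrosis",
        "multinucleated_macrophages",
        "proteinaceous_fluid",
        "mineralization",
        "red_blood_cell_proliferation",
    }
)

#: Damage thresholds on the ordinal scale.
DAMAGE_COLLAGEN_MIN = 2.0       # Mild or worse collagen is damage evidence
NODAMAGE_COLLAGEN_MAX = 0.5     # at most a no-significant/minimal midpoint
DAMAGE_STRENGTH_MIN = 2.0       # mild-or-worse diagnosis strength


class PathologyClass(Enum):
    Damaged = "Damaged"
    Intermediate = "Intermediate"
    NotDamaged = "NotDamaged"


class BiomarkerClass(Enum):
    Decline = "Decline"
    NoDecline = "NoDecline"


@dataclass
class CollagenGrade:
    """Ordinal collagen score, 0 (no significant) to 5 (severe), half steps
    for range readings; fixation-artifact-suspect findings carry a flag."""

    value: float
    artifact_suspect: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.value not in [x * 0.5 for x in range(11)]:
            raise ValueError(f"grade must be in {{0, 0.5, ..., 5}}, got {self.value}")


@dataclass
class DiagnosisRecord:
    """One H&E diagnosis at one subject x contour, with ordinal strength."""

    subject_id: str
    contour: str
    diagnosis: str
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.diagnosis not in DIAGNOSIS_VOCABULARY:
            raise ValueError(
                f"unknown diagnosis {self.diagnosis!r}; vocabulary: "
                f"{sorted(DIAGNOSIS_VOCABULARY)}"
            )
        if self.strength not in [x * 0.5 for x in range(11)]:
            raise ValueError(f"strength must be on the ordinal scale, got {self.strength}")


def parse_collagen_grade(label: str, artifact_suspect: bool = False) -> CollagenGrade:
    """Parse a collagen scale label, including hyphenated ranges.

    "moderate" -> 3; "minimal-mild" -> 1.5; "no significant" -> 0.
    """
    text = str(label).strip().lower().replace("_", " ")
    if text in COLLAGEN_SCALE:
        return CollagenGrade(COLLAGEN_SCALE[text], artifact_suspect, text)
    if "-" in text:
        parts = [p.strip() for p in text.split("-")]
        if len(parts) == 2 and all(p in COLLAGEN_SCALE for p in parts):
            lo, hi = (COLLAGEN_SCALE[p] for p in parts)
            if abs(hi - lo) == 1.0:
                return CollagenGrade((lo + hi) / 2.0, artifact_suspect, text)
    raise ValueError(
        f"unknown collagen label {label!r}; accepted: {sorted(COLLAGEN_SCALE)} "
        "or adjacent hyphenated ranges like 'minimal-mild'"
    )


def parse_strength(label: str) -> float:
    """Diagnosis strengths share the collagen scale and parsing rules."""
    return parse_collagen_grade(label).value


def pathology_damage_class(
    collagen: CollagenGrade, diagnoses: list[DiagnosisRecord]
) -> PathologyClass:
    """Damage class of one subject x contour from its pathology findings.

    Damaged: mild-or-worse collagen, or fibrosis at mild-or-worse strength,
    with the collagen finding not flagged as a fixation artifact.
    NotDamaged: collagen at most 0.5 and no diagnosis at mild-or-worse
    strength.  Intermediate otherwise.  Total and monotone in collagen grade.
    """
    fibrosis_strength = max(
        (d.strength for d in diagnoses if d.diagnosis == "fibrosis"), default=0.0
    )
    max_strength = max((d.strength for d in diagnoses), default=0.0)
    collagen_evidence = (not collagen.artifact_suspect) and collagen.value >= DAMAGE_COLLAGEN_MIN
    if collagen_evidence or fibrosis_strength >= DAMAGE_STRENGTH_MIN:
        return PathologyClass.Damaged
    effective_collagen = 0.0 if collagen.artifact_suspect else collagen.value
    if effective_collagen <= NODAMAGE_COLLAGEN_MAX and max_strength < DAMAGE_STRENGTH_MIN:
        return PathologyClass.NotDamaged
    return PathologyClass.Intermediate


def biomarker_point_class(change: ChangeClass) -> BiomarkerClass:
    """Collapse the three-way change class to Decline / NoDecline."""
    if change == ChangeClass.Decline:
        return BiomarkerClass.Decline
    return BiomarkerClass.NoDecline


#: Agreement policy: (biomarker, pathology) -> agree.  The Intermediate
#: pathology class is compatible with NoDecline (its mild findings need not
#: have altered ventilation) but not with Decline.
DEFAULT_AGREEMENT_POLICY: dict[tuple[BiomarkerClass, PathologyClass], bool] = {
    (BiomarkerClass.Decline, PathologyClass.Damaged): True,
    (BiomarkerClass.Decline, PathologyClass.Intermediate): False,
    (BiomarkerClass.Decline, PathologyClass.NotDamaged): False,
    (BiomarkerClass.NoDecline, PathologyClass.Damaged): False,
    (BiomarkerClass.NoDecline, PathologyClass.Intermediate): True,
    (BiomarkerClass.NoDecline, PathologyClass.NotDamaged): True,
}


def agreement(
    biomarker: BiomarkerClass,
    pathology: PathologyClass,
    policy: dict | None = None,
) -> bool:
    """Whether a biomarker class and a pathology class agree under a policy."""
    policy = DEFAULT_AGREEMENT_POLICY if policy is None else policy
    return bool(policy[(biomarker, pathology)])


@dataclass
class ConcordanceTable:
    """Per-point agreement rows plus totals."""

    rows: pd.DataFrame
    n_points: int
    n_agree: int

    @property
    def rate(self) -> float:
        return self.n_agree / self.n_points

    @property
    def disagreements(self) -> pd.DataFrame:
        return self.rows[~self.rows.agree].reset_index(drop=True)


class CompletenessError(ValueError):
    """A subject x contour cell required by the study design is missing."""


def build_concordance(
    fixture: dict[str, pd.DataFrame],
    policy: dict | None = None,
    contours: tuple[str, ...] = GROUP_B_CONTOURS,
) -> ConcordanceTable:
    """Cross-tabulate biomarker change against pathology per subject x contour.

    ``fixture`` carries three tables with the packaged schema:
    ``ventilation`` (subject, contour, change_class), ``collagen`` (subject,
    contour, grade_label, artifact_suspect) and ``diagnoses`` (subject,
    contour, diagnosis, strength_label).  Every subject x contour cell of the
    study design must be present in both ventilation and collagen tables.
    """
    vent = fixture["ventilation"]
    coll = fixture["collagen"]
    diag = fixture.get("diagnoses")

    subjects = sorted(set(vent.subject) | set(coll.subject))
    vent_idx = {(r.subject, r.contour): r for r in vent.itertuples()}
    coll_idx = {(r.subject, r.contour): r for r in coll.itertuples()}
    diag_idx: dict[tuple[str, str], list[DiagnosisRecord]] = {}
    if diag is not None:
        for r in diag.itertuples():
            diag_idx.setdefault((r.subject, r.contour), []).append(
                DiagnosisRecord(
                    subject_id=r.subject,
                    contour=r.contour,
                    diagnosis=r.diagnosis,
                    strength=parse_strength(r.strength_label),
                )
            )

    rows = []
    for subject in subjects:
        for contour in contours:
            key = (subject, contour)
            if key not in vent_idx:
                raise CompletenessError(
                    f"missing ventilation change class for subject {subject}, contour {contour}"
                )
            if key not in coll_idx:
                raise CompletenessError(
                    f"missing collagen grade for subject {subject}, contour {contour}"
                )
            v = vent_idx[key]
            c = coll_idx[key]
            grade = parse_collagen_grade(
                c.grade_label, artifact_suspect=bool(c.artifact_suspect)
            )
            path_cls = pathology_damage_class(grade, diag_idx.get(key, []))
            bio_cls = biomarker_point_class(ChangeClass(v.change_class))
            rows.append(
                {
                    "subject": subject,
                    "contour": contour,
                    "biomarker_class": bio_cls.value,
                    "pathology_class": path_cls.value,
                    "collagen_grade": grade.value,
                    "agree": agreement(bio_cls, path_cls, policy),
                }
            )
    df = pd.DataFrame(rows)
    table = ConcordanceTable(rows=df, n_points=len(df), n_agree=int(df.agree.sum()))
    log.info(
        "concordance: %d/%d points agree (%.0f%%)",
        table.n_agree, table.n_points, 100.0 * table.rate,
    )
    return table


def diagnosis_tally(records: list[DiagnosisRecord] | pd.DataFrame) -> pd.DataFrame:
    """Count distinct subjects per (contour, diagnosis) cell.

    Mirrors the study's diagnosis-frequency table: each cell is the number
    of subjects in which that condition was observed at that contour, so
    duplicate records for one subject count once.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            DiagnosisRecord(
                subject_id=r.subject,
                contour=r.contour,
                diagnosis=r.diagnosis,
                strength=parse_strength(r.strength_label)
                if hasattr(r, "strength_label") else 1.0,
            )
            for r in records.itertuples()
        ]
    if not records:
        return pd.DataFrame(dtype=int)
    seen = {(r.contour, r.diagnosis, r.subject_id) for r in records}
    df = pd.DataFrame(sorted(seen), columns=["contour", "diagnosis", "subject"])
    tally = (
        df.groupby(["contour", "diagnosis"])["subject"].nunique().unstack(fill_value=0)
    )
    return tally


@dataclass
class TTestResult:
    t: float
    p_two_tailed: float
    n: int
    degenerate: bool = False


def paired_t_test(x, y) -> TTestResult:
    """Two-tailed paired Student's t-test.

    t = mean(d) / (sd(d) / sqrt(n)) on the paired differences d = x - y with
    the sample standard deviation (n-1 denominator); p from the t
    distribution with n-1 degrees of freedom.  All-zero or zero-variance
    differences are degenerate: flagged, with p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        return TTestResult(t=0.0, p_two_tailed=1.0, n=n, degenerate=True)
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 1))
    return TTestResult(t=t, p_two_tailed=p, n=n)
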