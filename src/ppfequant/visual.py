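"""Radiologist lobar scores and derived visual PPFE variables.

Each of six lobes (lingula treated as a sixth lobe) carries a PPFE grade —
0 absent, 1 affecting < 10% of the lobe's pleural surface, 2 affecting
10–33%, 3 affecting > 33% — plus visually estimated ILD and emphysema
percentages scored to the nearest 5%. From these the analyses use:

* vPPFE-presence: any non-zero grade anywhere;
* the 7-point score: RUL + LUL grades (0–6);
* the 3-category scale: absent (0), moderate (sum 1–2), marked (sum > 2);
* total extent: sum over all six lobes (0–18); and
* a morphological severity measure: mean ILD% + mean emphysema% across the
  six lobes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

LOBES = ("rul", "rml", "rll", "lul", "lingula", "lll")
UPPER_LOBES = ("rul", "lul")


@dataclass(frozen=True)
class LobarVisualScore:
    """Per-lobe PPFE grade (0-3) and ILD / emphysema percentages (steps of 5)."""

    ppfe_grades: dict[str, int]
    ild_percent: dict[str, float]
    emphysema_percent: dict[str, float]

    def __post_init__(self) -> None:
        for table, name in ((self.ppfe_grades, "ppfe_grades"),):
            if set(table) != set(LOBES):
                raise ValueError(f"{name} must cover exactly the lobes {LOBES}")
        for lobe in LOBES:
            g = self.ppfe_grades[lobe]
            if g not in (0, 1, 2, 3):
                raise ValueError(f"{lobe}: PPFE grade {g} outside 0..3")
            for table, name in ((self.ild_percent, "ILD"),
                                (self.emphysema_percent, "emphysema")):
                p = table[lobe]
                if not 0 <= p <= 100 or p % 5 != 0:
                    raise ValueError(
                        f"{lobe}: {name} percentage {p} must be a multiple of 5 "
                        "in [0, 100] (scores are read to the nearest 5%)"
                    )


@dataclass(frozen=True)
class VPPFEScores:
    presence: bool
    category: str  # absent | moderate | marked
    seven_point: int  # 0..6
    total_extent: int  # 0..18


def derive_vppfe(scores: LobarVisualScore, *, per_lobe_max: bool = False) -> VPPFEScores:
    """Derive the visual PPFE variables from lobar grades.

    The moderate/marked split is applied to the upper-lobe sum by default
    (moderate = 1-2, marked = > 2). ``per_lobe_max=True`` instead applies the
    same bands to the larger of the two upper-lobe grades.
    """
    total = sum(scores.ppfe_grades[l] for l in LOBES)
    seven = sum(scores.ppfe_grades[l] for l in UPPER_LOBES)
    basis = max(scores.ppfe_grades[l] for l in UPPER_LOBES) if per_lobe_max else seven
    if basis == 0:
        category = "absent"
    elif basis <= 2:
        category = "moderate"
    else:
        category = "marked"
    return VPPFEScores(presence=total > 0, category=category,
                       seven_point=seven, total_extent=total)


def morphologic_severity(scores: LobarVisualScore) -> float:
    """Mean ILD% plus mean emphysema% across the six lobes (0-200)."""
    mean_ild = sum(scores.ild_percent[l] for l in LOBES) / len(LOBES)
    mean_emph = sum(scores.emphysema_percent[l] for l in LOBES) / len(LOBES)
    return mean_ild + mean_emph


def validate_anatomic_consistency(score_table: dict[str, LobarVisualScore]) -> list[str]:
    """Flag records with middle/lower-lobe PPFE but grade-0 upper lobes.

    PPFE essentially never appears in middle or lower lobes without upper-lobe
    involvement, so such records are anatomically implausible; they are
    flagged, not rejected.
    """
    warnings = []
    for pid, s in score_table.items():
        upper = sum(s.ppfe_grades[l] for l in UPPER_LOBES)
        other = sum(s.ppfe_grades[l] for l in LOBES if l not in UPPER_LOBES)
        if upper == 0 and other > 0:
            warnings.append(
                f"{pid}: PPFE graded in middle/lower lobes with both upper "
                "lobes grade 0 — anatomically implausible pattern"
            )
    return warnings


# ---------------------------------------------------------------------------
# CSV interface: one row per patient, columns <lobe>_ppfe, <lobe>_ild,
# <lobe>_emph for each of the six lobes.

def read_lobar_scores_csv(path) -> dict[str, LobarVisualScore]:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise ValueError("lobar score CSV needs a patient_id column")
    out: dict[str, LobarVisualScore] = {}
    for _, row in df.iterrows():
        out[str(row["patient_id"])] = LobarVisualScore(
            ppfe_grades={l: int(row[f"{l}_ppfe"]) for l in LOBES},
            ild_percent={l: float(row[f"{l}_ild"]) for l in LOBES},
            emphysema_percent={l: float(row[f"{l}_emph"]) for l in LOBES},
        )
    return out


def derived_scores_frame(score_table: dict[str, LobarVisualScore]) -> pd.DataFrame:
    """Tidy per-patient table of every derived visual variable."""
    rows = []
    for pid, s in score_table.items():
        v = derive_vppfe(s)
        rows.append(
            {
                "patient_id": pid,
                "vppfe_presence": int(v.presence),
                "vppfe_category": v.category,
                "vppfe_seven_point": v.seven_point,
                "vppfe_total_extent": v.total_extent,
                "morphologic_severity": morphologic_severity(s),
            }
        )
    return pd.DataFrame(rows)
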