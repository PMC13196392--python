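"""Reference-standard labels from DXA: BMD category, TBS degradation, Bone Fragility Index.

The composite Bone Fragility Index (BFI) combines densitometric bone quantity
(lumbar-spine BMD T-score, WHO categories) with bone quality (trabecular bone
score, TBS).  The screening target is the *very high* fragility category:
osteoporosis together with degraded TBS.  The *high* zone additionally contains
osteoporosis without degraded TBS and osteopenia with degraded TBS; it is the
reference zone for near-miss precision.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional

import pandas as pd

#: WHO osteoporosis threshold on the T-score (inclusive).
T_SCORE_OSTEOPOROSIS = -2.5
#: WHO lower bound of the normal range (t >= -1.0 is normal).
T_SCORE_NORMAL = -1.0
#: TBS degradation threshold (strict: degraded iff tbs < 1.23).
TBS_DEGRADED = 1.23


@dataclass(frozen=True)
class DXARecord:
    """A lumbar-spine DXA result consumed as given (no normative-curve math here)."""

    bmd_t_score: float
    tbs: float
    acquisition_date: Optional[_dt.date] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.tbs > 0):
            raise ValueError(f"tbs must be positive, got {self.tbs}")


@dataclass(frozen=True)
class FragilityLabel:
    osteoporosis: bool
    degraded_tbs: bool
    bmd_category: str  # {normal, osteopenia, osteoporosis}
    category: str  # {none, high, very_high}

    @property
    def is_very_high(self) -> bool:
        return self.category == "very_high"

    @property
    def in_high_zone(self) -> bool:
        """True if the reference lies anywhere in the high-fragility zone."""
        return self.category in ("high", "very_high")


def classify_bmd(t_score: float) -> str:
    """WHO densitometric category from a lumbar BMD T-score.

    osteoporosis iff t <= -2.5; osteopenia iff -2.5 < t < -1.0; normal iff t >= -1.0.
    """
    t = float(t_score)
    if t != t:  # NaN
        raise ValueError("t_score must be finite")
    if t <= T_SCORE_OSTEOPOROSIS:
        return "osteoporosis"
    if t < T_SCORE_NORMAL:
        return "osteopenia"
    return "normal"


def classify_tbs(tbs: float) -> bool:
    """Degraded microarchitecture iff tbs < 1.23 (strict inequality)."""
    if not (tbs > 0):
        raise ValueError(f"tbs must be positive, got {tbs}")
    return float(tbs) < TBS_DEGRADED


def bone_fragility_index(dxa: DXARecord) -> FragilityLabel:
    """Composite Bone Fragility Index.

    very_high  <=> osteoporosis AND degraded TBS
    high       <=> not very_high AND (osteoporosis OR (osteopenia AND degraded TBS))
    none       otherwise
    """
    cat = classify_bmd(dxa.bmd_t_score)
    osteoporosis = cat == "osteoporosis"
    degraded = classify_tbs(dxa.tbs)
    if osteoporosis and degraded:
        zone = "very_high"
    elif osteoporosis or (cat == "osteopenia" and degraded):
        zone = "high"
    else:
        zone = "none"
    return FragilityLabel(
        osteoporosis=osteoporosis,
        degraded_tbs=degraded,
        bmd_category=cat,
        category=zone,
    )


def read_dxa_csv(path) -> pd.DataFrame:
    """Read a DXA records CSV (subject_id, date, bmd_t_score, tbs) and append labels."""
    df = pd.read_csv(path, dtype={"subject_id": str}, parse_dates=["date"])
    labels = [
        bone_fragility_index(DXARecord(bmd_t_score=t, tbs=s))
        for t, s in zip(df["bmd_t_score"], df["tbs"])
    ]
    df["bmd_category"] = [l.bmd_category for l in labels]
    df["degraded_tbs"] = [l.degraded_tbs for l in labels]
    df["label"] = [l.category for l in labels]
    return df
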