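"""Macrochaete scoring, embryonic-failure and fecundity summaries.

The adult hemi-notum carries 13 stereotyped macrochaete (large bristle)
positions.  Notch-pathway perturbations produce missing or ectopic
(duplicated) bristles; each observed position is scored on a numeric scale
(normal = 1.0, missing = 0.0, ectopic/split = 2.0, graded intermediates and
rare compound defects), and per-cohort means summarize the frequency of
bristle occurrence.  Because a position rarely shows both ectopic and
missing defects within one cohort, the rarer defect class is masked to 1.0
before averaging so the two defect directions cannot cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import percent, round_half_away
from .errors import EmptyInputError

#: The 13 macrochaete positions of a hemi-notum, anterior to posterior:
#: humerals, presutural, notopleurals, supra-alars, postalars, dorsocentrals,
#: scutellars.
BRISTLE_POSITIONS: tuple[str, ...] = (
    "uHU", "lHU", "PS", "aNP", "pNP", "aSA", "pSA",
    "aPA", "pPA", "aDC", "pDC", "aSC", "pSC",
)

#: Position pairs that can share a single mid-distance ectopic bristle.
PAIRED_POSITIONS: frozenset[frozenset[str]] = frozenset(
    {frozenset({"aDC", "pDC"}), frozenset({"aSC", "pSC"})}
)

#: Positions scored for the ectopic (duplicated) bristle rate.
ECTOPIC_POSITIONS: tuple[str, ...] = ("aDC", "pDC", "aSC", "pSC", "pPA")


class BristleCategory(Enum):
    NORMAL = "normal"
    MISSING = "missing"
    ECTOPIC_NEAR = "ectopic_near"
    SPLIT = "split"
    SLENDER = "slender"
    SHARED_MID = "shared_mid"
    SOCKET_PLUS_ECTOPIC = "socket_plus_ectopic"
    DOUBLE_EMPTY_SOCKET = "double_empty_socket"


_CATEGORY_SCORE = {
    BristleCategory.NORMAL: 1.0,
    BristleCategory.MISSING: 0.0,
    BristleCategory.ECTOPIC_NEAR: 2.0,
    BristleCategory.SPLIT: 2.0,
    BristleCategory.SHARED_MID: 1.5,
    BristleCategory.SOCKET_PLUS_ECTOPIC: -1.0,
    BristleCategory.DOUBLE_EMPTY_SOCKET: -2.0,
}


@dataclass(frozen=True)
class BristleObservation:
    """One scored bristle position on one hemi-notum."""

    fly_id: str
    sex: str
    position: str
    category: BristleCategory
    side: str = "L"
    genotype: str = ""
    fraction: Optional[float] = None   # for SLENDER; defaults to 0.5
    socket_present: bool = False       # recorded alongside MISSING

    def __post_init__(self) -> None:
        if self.position not in BRISTLE_POSITIONS:
            raise ValueError(f"unknown bristle position {self.position!r}")
        if self.fraction is not None and not 0.0 < self.fraction < 1.0:
            raise ValueError("a slender-bristle fraction must lie in (0, 1)")


def score_observation(obs: BristleObservation) -> float:
    """Numeric score for one observation (pure function of its category).

    SHARED_MID (an ectopic bristle exactly mid-distance between a DC or SC
    pair) is only valid at those paired positions and scores 1.5 at each.
    """
    if obs.category is BristleCategory.SHARED_MID:
        if not any(obs.position in pair for pair in PAIRED_POSITIONS):
            raise ValueError(
                f"SHARED_MID is only valid at DC/SC pairs, not {obs.position!r}"
            )
        return 1.5
    if obs.category is BristleCategory.SLENDER:
        return obs.fraction if obs.fraction is not None else 0.5
    return _CATEGORY_SCORE[obs.category]


def score_table(observations: Iterable[BristleObservation]) -> pd.DataFrame:
    """Observations -> tidy DataFrame with a ``score`` column."""
    rows = [
        {
            "fly_id": o.fly_id,
            "sex": o.sex,
            "side": o.side,
            "genotype": o.genotype,
            "position": o.position,
            "category": o.category.value,
            "score": score_observation(o),
        }
        for o in observations
    ]
    return pd.DataFrame(rows)


def mask_rarer_defect(scores: pd.DataFrame,
                      group_cols: Sequence[str] = ("genotype", "sex", "position")) -> pd.DataFrame:
    """Within each cohort group, mask the rarer defect class to 1.0.

    If a genotype x sex x position group contains both ectopic-type scores
    (> 1) and missing-type scores (< 1), every score of the less frequent
    class is replaced by 1.0.  Ties keep the ectopic class (the missing-type
    scores are masked).
    """
    out = scores.copy()
    for _, idx in out.groupby(list(group_cols)).groups.items():
        group = out.loc[idx, "score"]
        n_ectopic = int((group > 1.0).sum())
        n_missing = int((group < 1.0).sum())
        if n_ectopic == 0 or n_missing == 0:
            continue
        if n_missing <= n_ectopic:  # tie keeps the ectopic class
            out.loc[idx[group < 1.0], "score"] = 1.0
        else:
            out.loc[idx[group > 1.0], "score"] = 1.0
    return out


def cohort_frequencies(masked: pd.DataFrame,
                       group_cols: Sequence[str] = ("genotype", "sex", "position")) -> pd.DataFrame:
    """Mean score and defect counts per cohort cell (empty cells omitted)."""
    if masked.empty:
        raise EmptyInputError("no scored observations")

    def summarize(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "mean_score": g["score"].mean(),
                "n_hemi_nota": len(g),
                "n_ectopic": int((g["score"] > 1.0).sum()),
                "n_missing": int((g["score"] < 1.0).sum()),
                "n_compound": int((g["score"] < 0.0).sum()),
            }
        )

    grouped = masked.groupby(list(group_cols))[["score"]].apply(summarize).reset_index()
    for col in ("n_hemi_nota", "n_ectopic", "n_missing", "n_compound"):
        grouped[col] = grouped[col].astype(int)
    return grouped


def ectopic_rate(scores: pd.DataFrame,
                 positions: Sequence[str] = ECTOPIC_POSITIONS) -> float:
    """Fraction of flies with at least one ectopic score among ``positions``."""
    if scores.empty:
        raise EmptyInputError("no scored observations")
    relevant = scores[scores["position"].isin(positions)]
    flies = scores["fly_id"].unique()
    ectopic_flies = relevant.loc[relevant["score"] > 1.0, "fly_id"].unique()
    return len(ectopic_flies) / len(flies)


def embryonic_failure(unhatched: int, total: int) -> float:
    """Fraction of embryos failing to hatch."""
    if total <= 0:
        raise EmptyInputError("no embryos counted")
    if not 0 <= unhatched <= total:
        raise ValueError("unhatched count must lie in [0, total]")
    return unhatched / total


def fecundity_summary(egg_counts: dict[str, int]) -> pd.DataFrame:
    """Per-line egg counts -> mean and percent-of-maximum summary.

    The returned frame has one row per line plus an ``AVG.`` row; the mean is
    rounded to a whole egg for display but its percent of the maximum is
    computed from the unrounded mean.
    """
    if not egg_counts:
        raise EmptyInputError("no egg counts")
    maximum = max(egg_counts.values())
    if maximum == 0:
        raise ValueError("all egg counts are zero; percent of maximum undefined")
    mean = sum(egg_counts.values()) / len(egg_counts)
    rows = [
        {"line": line, "eggs": n, "pct_of_max": percent(n, maximum)}
        for line, n in egg_counts.items()
    ]
    rows.append(
        {
            "line": "AVG.",
            "eggs": int(round_half_away(mean)),
            "pct_of_max": percent(mean, maximum),
        }
    )
    return pd.DataFrame(rows)
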