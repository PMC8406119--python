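"""Respondent screening and eHealth-literacy scoring.

Exclusion filters mirror the survey's cleaning: respondents finishing in
under five minutes are removed first (speeders), then respondents who did
not complete the survey. eHealth literacy is scored from 8 five-category
agreement items into inadequate / problematic / sufficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .simulate import EHL_CATEGORIES

__all__ = ["ScreeningReport", "apply_exclusions", "score_ehl", "score_ehl_frame"]

_DISAGREE = {"strongly_disagree", "disagree"}
_NEUTRAL = {"neither"}
_AGREE = {"agree", "strongly_agree"}


@dataclass
class ScreeningReport:
    n_received: int
    n_excluded_speed: int
    n_excluded_incomplete: int
    n_retained: int
    retention_percent: float

    def __post_init__(self) -> None:
        assert (
            self.n_retained
            == self.n_received - self.n_excluded_speed - self.n_excluded_incomplete
        )

    def to_dict(self) -> dict:
        return {
            "n_received": self.n_received,
            "n_excluded_speed": self.n_excluded_speed,
            "n_excluded_incomplete": self.n_excluded_incomplete,
            "n_retained": self.n_retained,
            "retention_percent": self.retention_percent,
        }


def apply_exclusions(
    raw: pd.DataFrame, min_duration_minutes: float = 5.0
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Drop speeders, then incompletes; return the retained table + counts.

    The speed filter is applied first, so a respondent who is both too fast
    and incomplete is counted once, in the speed bucket.
    """
    for col in ("duration_minutes", "completed"):
        if col not in raw.columns:
            raise KeyError(f"raw survey table missing required column {col!r}")
    fast = raw["duration_minutes"] < min_duration_minutes
    incomplete = ~raw["completed"].astype(bool) & ~fast
    retained = raw[~fast & ~incomplete].copy()
    report = ScreeningReport(
        n_received=len(raw),
        n_excluded_speed=int(fast.sum()),
        n_excluded_incomplete=int(incomplete.sum()),
        n_retained=len(retained),
        retention_percent=100.0 * len(retained) / len(raw) if len(raw) else 0.0,
    )
    return retained, report


def score_ehl(items) -> str:
    """Categorize 8 agreement items into inadequate/problematic/sufficient.

    Any disagreement on any item -> inadequate; otherwise any neutral
    response -> problematic; all-agreement -> sufficient. The weakest
    response dominates when rules overlap.
    """
    items = list(items)
    if len(items) != 8:
        raise ValueError(f"expected exactly 8 items, got {len(items)}")
    for it in items:
        if it not in EHL_CATEGORIES:
            raise ValueError(f"invalid eHL response {it!r}")
    if any(it in _DISAGREE for it in items):
        return "inadequate"
    if any(it in _NEUTRAL for it in items):
        return "problematic"
    return "sufficient"


def score_ehl_frame(frame: pd.DataFrame) -> pd.Series:
    """Score every respondent row of a table with columns ehl_1..ehl_8."""
    cols = [f"ehl_{i}" for i in range(1, 9)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise KeyError(f"missing eHL item columns: {missing}")
    return frame[cols].apply(lambda row: score_ehl(row.tolist()), axis=1)
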