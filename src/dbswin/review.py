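"""Monopolar-review tables and the normalized therapeutic window.

During a monopolar review each contact of a DBS electrode is stimulated at
increasing amplitude until either sustained clinical benefit appears
(therapeutic-effect threshold, TET) or side effects force a stop
(side-effect threshold, SET).  The therapeutic window TW = SET - TET is the
prediction target; it is normalized by the range of amplitudes tested so
that it is bounded in [-1, 1] regardless of the amplitude protocol used.
A missing threshold means no effect occurred up to the highest amplitude
tested and is imputed with that amplitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MonopolarReview",
    "impute_thresholds",
    "raw_window",
    "normalize_window",
    "select_review",
    "window_table",
]


@dataclass
class MonopolarReview:
    """One review of one electrode: per-contact thresholds plus protocol.

    ``contacts`` has columns ``contact_id``, ``set_ma``, ``tet_ma``; absent
    thresholds are NaN.  ``amp_range`` is the range of amplitudes tested
    (max - min), the divisor of the normalized window.  ``order`` breaks
    ties when several reviews exist for a patient (earlier = smaller).
    """

    patient_id: str
    side: str
    contacts: pd.DataFrame
    amp_step: float
    amp_max: float
    amp_range: float
    chosen_contact: object = None
    order: int = 0

    def __post_init__(self) -> None:
        required = {"contact_id", "set_ma", "tet_ma"}
        missing = required - set(self.contacts.columns)
        if missing:
            raise ValueError(f"contacts table missing columns {sorted(missing)}")
        if self.amp_range <= 0:
            raise ValueError("amp_range must be positive")
        if self.amp_max <= 0:
            raise ValueError("amp_max must be positive")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)


def impute_thresholds(
    set_ma: float | None,
    tet_ma: float | None,
    amp_max: float,
    impute_value_factor: float = 1.0,
) -> tuple[float, float]:
    """Replace absent thresholds by the maximum amplitude tested.

    An absent SET means no side effect occurred up to ``amp_max``; an absent
    TET means no sustained benefit up to ``amp_max``.  Both are imputed with
    ``impute_value_factor * amp_max`` (factor 1 by default; larger factors
    reproduce the robustness variant of imputing beyond the tested range).
    """
    if amp_max <= 0:
        raise ValueError("amp_max must be positive")
    if impute_value_factor < 1.0:
        raise ValueError("impute_value_factor must be >= 1")
    fill = impute_value_factor * amp_max

    def _one(v):
        return fill if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    return _one(set_ma), _one(tet_ma)


def raw_window(set_ma: float, tet_ma: float) -> float:
    """Therapeutic window in mA: side-effect minus therapeutic threshold.

    Negative values are legitimate: side effects below the effect threshold
    (common early after surgery, when the stun effect masks benefit).
    """
    return float(set_ma) - float(tet_ma)


def normalize_window(raw: float, amp_range: float) -> float:
    """Normalized therapeutic window, dimensionless in [-1, 1]."""
    if amp_range <= 0:
        raise ValueError("amp_range must be positive")
    if abs(raw) > amp_range + 1e-9:
        raise ValueError(
            f"|raw window| = {abs(raw)} mA exceeds amplitude range {amp_range} mA; "
            "inconsistent review"
        )
    return raw / amp_range


def select_review(reviews: list[MonopolarReview]) -> MonopolarReview:
    """Pick the review with the most contacts tested (tie: earliest)."""
    if not reviews:
        raise ValueError("empty review list")
    return max(reviews, key=lambda r: (r.n_contacts, -r.order))


def window_table(
    review: MonopolarReview, impute_value_factor: float = 1.0
) -> pd.DataFrame:
    """Raw and normalized windows for every contact of a review.

    Returns a frame with columns ``patient_id, side, contact_id, set_ma,
    tet_ma, raw_tw_ma, norm_tw`` (thresholds after imputation).
    """
    rows = []
    for rec in review.contacts.itertuples(index=False):
        s, t = impute_thresholds(
            rec.set_ma, rec.tet_ma, review.amp_max, impute_value_factor
        )
        raw = raw_window(s, t)
        if impute_value_factor > 1.0:
            # imputing beyond the tested range legally pushes |raw| past
            # amp_range; keep the same divisor, drop the consistency check
            norm = raw / review.amp_range
        else:
            norm = normalize_window(raw, review.amp_range)
        rows.append(
            dict(
                patient_id=review.patient_id,
                side=review.side,
                contact_id=rec.contact_id,
                set_ma=s,
                tet_ma=t,
                raw_tw_ma=raw,
                norm_tw=norm,
            )
        )
    return pd.DataFrame(rows)
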