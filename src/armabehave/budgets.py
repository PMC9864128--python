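"""Overall and hourly (diel) activity budgets from classified observations.

Observations from all individuals are pooled.  Unclassified observations
count toward the hourly transmission totals but are omitted from the
state-proportion quantification, so proportions describe the allocation of
*classified* active time only.  Hour of day is taken in a configured local
time zone (default UTC-4, the study region's offset).
"""

from __future__ import annotations

from fractions import Fraction

import pandas as pd

from .m3_model import UNCLASSIFIED

DEFAULT_TZ = "Etc/GMT+4"  # POSIX sign convention: Etc/GMT+4 == UTC-4


def _local_hours(timestamps: pd.Series, tz: str) -> pd.Series:
    idx = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    return pd.Series(idx.tz_convert(tz).hour, index=timestamps.index)


def overall_budget(assignments: pd.DataFrame) -> dict[str, float]:
    """Per-state proportions over all classified observations, pooled.

    ``assignments`` needs a ``label`` column; rows labeled "unclassified"
    are omitted.  Proportions are formed with exact rational arithmetic on
    counts, so they sum to exactly 1.  Raises ``ValueError`` when no
    observation is classified.
    """
    labels = assignments["label"]
    classified = labels[labels != UNCLASSIFIED]
    if classified.empty:
        raise ValueError("no classified observations: budget undefined")
    n = len(classified)
    counts = classified.value_counts()
    fracs = {lab: Fraction(int(c), n) for lab, c in counts.items()}
    assert sum(fracs.values()) == 1
    return {lab: float(f) for lab, f in fracs.items()}


def hourly_budget(assignments: pd.DataFrame, tz: str = DEFAULT_TZ) -> pd.DataFrame:
    """Hour-of-day activity budget.

    Returns a 24-row DataFrame indexed by local hour with
    ``n_observations`` (classified + unclassified transmissions in that
    hour) and one proportion column per state label among classified
    observations.  Hours with no classified observation carry missing
    proportions (not zeros).
    """
    hours = _local_hours(assignments["timestamp"], tz)
    labels = assignments["label"]
    states = sorted(set(labels) - {UNCLASSIFIED})

    out = pd.DataFrame(index=pd.RangeIndex(24, name="hour"))
    out["n_observations"] = hours.value_counts().reindex(range(24), fill_value=0)

    classified = pd.DataFrame({"hour": hours, "label": labels})
    classified = classified[classified["label"] != UNCLASSIFIED]
    counts = (
        classified.groupby(["hour", "label"]).size().unstack(fill_value=0)
        .reindex(index=range(24), columns=states, fill_value=0)
    )
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0), axis=0)  # NaN where empty
    for s in states:
        out[s] = props[s]
    return out
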