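"""Cohort-assembly exclusion filters.

An enrolled roster is reduced to the analysis sample by dropping, in order:
participants aged 74 or older; missing heritage; other/mixed heritage; no
dietary recalls; unreliable recalls; and sex-specific energy outliers (below
the 1st or above the 99th percentile of mean recall energy).  Each record is
counted against the *first* criterion it fails, so the audit counts partition
the exclusions and ``retained + sum(counts) == roster size``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["CRITERIA", "apply_exclusions"]

#: Filter order; each excluded record is attributed to its first failure.
CRITERIA = (
    "age_ge_74",
    "missing_heritage",
    "other_mixed_heritage",
    "no_recalls",
    "unreliable_recalls",
    "energy_outlier",
)

HERITAGE_LEVELS = {"Mexican", "Central American", "Cuban", "Dominican",
                   "Puerto Rican", "South American"}

REQUIRED = ("id", "age", "heritage", "n_recalls", "reliable")


def _energy_flags(roster: pd.DataFrame) -> pd.Series:
    """Sex-specific p1/p99 flags computed empirically from mean recall energy.

    Only used when the roster carries no precomputed ``energy_flag`` column;
    records without recalls stay in-range (the energy filter cannot apply).
    """
    flag = pd.Series("in-range", index=roster.index)
    has = roster["n_recalls"].to_numpy() > 0
    for sex, g in roster.loc[has].groupby("sex"):
        e = g["energy"].to_numpy(float)
        lo, hi = np.percentile(e, [1, 99])
        flag.loc[g.index[e < lo]] = "below-p1"
        flag.loc[g.index[e > hi]] = "above-p99"
    return flag


def apply_exclusions(roster: pd.DataFrame):
    """Apply the filters; return ``(retained_ids, counts)``.

    ``roster`` needs columns ``id, age, heritage, n_recalls, reliable`` and
    either an ``energy_flag`` column (``below-p1 | above-p99 | in-range``) or
    ``sex`` + ``energy`` columns from which sex-specific percentile flags are
    computed.  ``counts`` is a Series over :data:`CRITERIA` in filter order.
    """
    missing = [c for c in REQUIRED if c not in roster.columns]
    if missing:
        raise ValueError(f"roster missing required columns: {missing}")
    if len(roster) == 0:
        return [], pd.Series(0, index=list(CRITERIA), name="excluded")

    if "energy_flag" in roster.columns:
        eflag = roster["energy_flag"].fillna("in-range")
    else:
        if not {"sex", "energy"} <= set(roster.columns):
            raise ValueError("need energy_flag or (sex, energy) columns")
        eflag = _energy_flags(roster)

    heritage = roster["heritage"]
    fails = {
        "age_ge_74": roster["age"].to_numpy(float) >= 74,
        "missing_heritage": heritage.isna().to_numpy()
        | (heritage == "missing").to_numpy(),
        "other_mixed_heritage": (~heritage.isna()
                                 & (heritage != "missing")
                                 & ~heritage.isin(HERITAGE_LEVELS)).to_numpy(),
        "no_recalls": roster["n_recalls"].to_numpy() == 0,
        "unreliable_recalls": (roster["n_recalls"].to_numpy() > 0)
        & ~roster["reliable"].astype(bool).to_numpy(),
        "energy_outlier": eflag.isin(["below-p1", "above-p99"]).to_numpy(),
    }

    excluded_by = np.full(len(roster), "", dtype=object)
    already = np.zeros(len(roster), dtype=bool)
    counts = {}
    for crit in CRITERIA:
        hit = fails[crit] & ~already
        counts[crit] = int(hit.sum())
        excluded_by[hit] = crit
        already |= hit

    retained = roster.loc[~already, "id"].tolist()
    return retained, pd.Series(counts, name="excluded")
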