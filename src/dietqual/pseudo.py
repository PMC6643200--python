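"""Pseudo-population construction and survey-weighted HEI summaries.

After the measurement-error model is fitted, drawing M usual-intake vectors
per participant (default 100) yields a "pseudo-population" that represents
the joint distribution of usual intake across the surveyed population.  Each
pseudo-row carries 1/M of its participant's sampling weight; HEI-2010 scores
computed on pseudo-rows then give survey-weighted mean component scores, the
mean total score, and the percent of the population at each component's
maximum score (i.e. meeting the recommendation).

Age/sex standardization is model based: draws are regenerated with age set to
the standard mean and sex redrawn per pseudo-row at the standard proportion
male, so subgroup contrasts do not reflect age/sex composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import me_model
from .hei2010 import COMPONENT_IDS, load_standards, score_frame
from .survey import weighted_mean

__all__ = [
    "PseudoPopulation",
    "Standardization",
    "build",
    "score_summary",
    "summarize",
    "summarize_by",
]

#: Score equality tolerance for "at maximum" (absorbs float rounding only).
AT_MAX_TOL = 1e-9


@dataclass(frozen=True)
class Standardization:
    """Reference population for age/sex adjustment."""

    mean_age: float = 41.30
    pct_male: float = 47.76


@dataclass
class PseudoPopulation:
    frame: pd.DataFrame          # participant_id, draw, usual intakes, scores
    design: pd.DataFrame         # id, stratum, psu, weight
    M: int
    standardization: Standardization | None = None

    def weights(self, ids=None) -> np.ndarray:
        """Per-row weight: participant weight / M (equal draw allocation)."""
        w = self.design.set_index("id")["weight"]
        pid = self.frame["participant_id"] if ids is None else ids
        return w.loc[pid].to_numpy() / self.M


def build(model: me_model.FittedMEModel, recalls: pd.DataFrame,
          covars: pd.DataFrame, design: pd.DataFrame, M: int = 100,
          seed: int = 0, standardize_to: Standardization | None = None,
          standards=None) -> PseudoPopulation:
    """Draw and score the pseudo-population.  Deterministic under ``seed``."""
    if not model.converged:
        raise ValueError("refusing to build a pseudo-population from a "
                         "non-converged model fit")
    kwargs = {}
    if standardize_to is not None:
        kwargs = {"age_override": standardize_to.mean_age,
                  "pct_male": standardize_to.pct_male / 100.0}
    draws = me_model.draw_usual(model, recalls, covars, M=M, seed=seed,
                                **kwargs)
    scores = score_frame(draws, standards)
    frame = pd.concat([draws, scores], axis=1)
    return PseudoPopulation(frame=frame, design=design, M=M,
                            standardization=standardize_to)


def score_summary(scores: pd.DataFrame, weights, standards=None,
                  ) -> pd.DataFrame:
    """Weighted mean score and percent-at-maximum from a score table.

    ``scores`` holds ``score_<component>`` columns plus ``score_total`` (one
    row per person or pseudo-row); rows are weighted by ``weights``.  Returns
    a frame indexed by component (plus a ``total`` row with NaN
    percent-at-max).
    """
    if standards is None:
        standards = load_standards()
    w = np.asarray(weights, dtype=float)
    rows = []
    for cid in COMPONENT_IDS:
        s = scores[f"score_{cid}"].to_numpy(float)
        at_max = (s >= standards[cid].max_points - AT_MAX_TOL).astype(float)
        rows.append({
            "component": cid,
            "mean_score": weighted_mean(s, w),
            "pct_at_max": 100.0 * weighted_mean(at_max, w),
        })
    rows.append({
        "component": "total",
        "mean_score": weighted_mean(scores["score_total"].to_numpy(float), w),
        "pct_at_max": np.nan,
    })
    return pd.DataFrame(rows).set_index("component")


def summarize(pp: PseudoPopulation, subgroup: pd.Series | None = None,
              standards=None) -> pd.DataFrame:
    """Survey-weighted summaries over (a subgroup of) the pseudo-population.

    ``subgroup``, if given, is a boolean mask over participant ids (indexed
    by id); note that subgroup estimates from a *shared* model differ from
    the study convention of refitting the model per subpopulation — use
    :func:`summarize_by` for that.
    """
    frame = pp.frame
    if subgroup is not None:
        keep = subgroup.reindex(frame["participant_id"],
                                fill_value=False).to_numpy(bool)
        frame = frame.loc[keep]
        if len(frame) == 0:
            raise ValueError("empty subgroup")
    w = pp.weights(frame["participant_id"])
    return score_summary(frame, w, standards)


def summarize_by(recalls: pd.DataFrame, covars: pd.DataFrame,
                 design: pd.DataFrame, by: str, M: int = 100, seed: int = 0,
                 standardize_to: Standardization | None = Standardization(),
                 share_model: bool = False, me_config=None,
                 standards=None) -> pd.DataFrame:
    """Per-subgroup summaries, refitting the measurement-error model per level.

    ``by`` names a covariate column; every level gets its own model fit
    (all parameters free to differ), unless ``share_model`` trades that
    fidelity for speed by fitting once on the full sample and only filtering
    draws.  Returns a tidy frame with a ``level`` column.
    """
    out = []
    if share_model:
        model = me_model.fit(recalls, covars, me_config)
        pp = build(model, recalls, covars, design, M=M, seed=seed,
                   standardize_to=standardize_to, standards=standards)
        for level, g in covars.groupby(by):
            mask = pd.Series(True, index=g["id"])
            summ = summarize(pp, subgroup=mask, standards=standards)
            summ["level"] = level
            out.append(summ)
    else:
        for i, (level, g) in enumerate(covars.groupby(by)):
            ids = set(g["id"])
            rec = recalls[recalls["participant_id"].isin(ids)]
            des = design[design["id"].isin(ids)]
            model = me_model.fit(rec, g.reset_index(drop=True), me_config)
            pp = build(model, rec, g, des, M=M, seed=seed + i,
                       standardize_to=standardize_to, standards=standards)
            summ = summarize(pp, standards=standards)
            summ["level"] = level
            out.append(summ)
    return pd.concat(out).reset_index().set_index(["level", "component"])
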