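"""HEI-2010 diet-quality scoring.

The Healthy Eating Index 2010 scores a diet on 12 components summing to 100
points: 9 adequacy components (more is better: total fruit, whole fruit, total
vegetables, greens and beans, whole grains, dairy, total protein foods, seafood
and plant proteins, fatty acids) and 3 moderation components (less is better:
refined grains, sodium, empty calories).  All standards are density based —
amounts per 1000 kcal — so the index rewards dietary composition rather than
quantity.  Two components are special: fatty acids is the dimensionless
(PUFA + MUFA) / SFA ratio, and empty calories is the percent of energy coming
from solid fats, added sugars, and alcohol beyond 13 g per 1000 kcal.

Each component scores linearly in its density between two anchors: the density
earning zero points and the density earning full points, clamped outside that
range.  For adequacy components the zero anchor is a density of 0; moderation
components run downhill (the zero anchor is the *higher* density).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ALCOHOL_KCAL_PER_G",
    "ALCOHOL_THRESHOLD_G_PER_1000KCAL",
    "COMPONENT_IDS",
    "ComponentStandards",
    "HEIScore",
    "IntakeProfile",
    "InvalidProfileError",
    "MissingRatioError",
    "compute_density",
    "empty_calorie_share",
    "load_standards",
    "score_component",
    "score_frame",
    "score_profile",
]

#: Canonical component order (adequacy first, then moderation).
COMPONENT_IDS = (
    "total_fruit",
    "whole_fruit",
    "total_vegetables",
    "greens_beans",
    "whole_grains",
    "dairy",
    "total_protein",
    "seafood_plant_protein",
    "fatty_acids",
    "refined_grains",
    "sodium",
    "empty_calories",
)

#: Components whose amount column is a daily quantity divided by energy.
AMOUNT_COMPONENTS = tuple(c for c in COMPONENT_IDS if c != "fatty_acids")

ALCOHOL_KCAL_PER_G = 7.0
ALCOHOL_THRESHOLD_G_PER_1000KCAL = 13.0


class InvalidProfileError(ValueError):
    """An intake profile violates its invariants (e.g. non-positive energy)."""


class MissingRatioError(ValueError):
    """The fatty-acid ratio is undefined (no fat reported at all)."""


@dataclass(frozen=True)
class ComponentStandards:
    """Scoring anchors for one HEI-2010 component."""

    component_id: str
    max_points: int
    direction: str  # adequacy | moderation | ratio
    density_at_max: float
    density_at_zero: float
    units: str

    def __post_init__(self) -> None:
        if self.max_points not in (5, 10, 20):
            raise ValueError(f"{self.component_id}: max_points must be 5, 10 or 20")
        if self.direction == "adequacy":
            if not (self.density_at_zero == 0.0 < self.density_at_max):
                raise ValueError(f"{self.component_id}: bad adequacy anchors")
        elif self.direction == "moderation":
            if not (self.density_at_max < self.density_at_zero):
                raise ValueError(f"{self.component_id}: bad moderation anchors")
        elif self.direction == "ratio":
            if not (self.density_at_zero < self.density_at_max):
                raise ValueError(f"{self.component_id}: bad ratio anchors")
        else:
            raise ValueError(f"{self.component_id}: unknown direction {self.direction!r}")


def load_standards(path: str | None = None) -> dict[str, ComponentStandards]:
    """Load the versioned standards config (shipped YAML by default).

    Returns a dict keyed by ``component_id`` in canonical order.  Raises if the
    config does not describe exactly the 12 components or if the per-component
    maxima do not sum to 100.
    """
    if path is None:
        text = (resources.files("dietqual") / "data/hei2010_standards.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)["components"]
    if set(raw) != set(COMPONENT_IDS):
        missing = set(COMPONENT_IDS) - set(raw)
        raise ValueError(f"standards config incomplete; missing {sorted(missing)}")
    out = {
        cid: ComponentStandards(component_id=cid, **raw[cid]) for cid in COMPONENT_IDS
    }
    total = sum(s.max_points for s in out.values())
    if total != 100:
        raise ValueError(f"component maxima sum to {total}, expected 100")
    return out


@dataclass
class IntakeProfile:
    """One daily intake profile in natural units.

    ``amounts`` holds the daily quantities of the amount-based components
    (cup/oz equivalents, sodium grams, and — optionally — a precomputed
    ``empty_calories`` kcal total).  The fatty-acid ratio is derived from the
    PUFA/MUFA/SFA grams; empty calories from solid fat, added sugar and
    alcohol unless given directly.
    """

    energy: float
    amounts: Mapping[str, float]
    pufa_g: float = 0.0
    mufa_g: float = 0.0
    sfa_g: float = 0.0
    solid_fat_kcal: float = 0.0
    added_sugar_kcal: float = 0.0
    alcohol_g: float = 0.0
    flags: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not np.isfinite(self.energy) or self.energy <= 0:
            raise InvalidProfileError(f"energy must be positive, got {self.energy}")
        for key, val in self.amounts.items():
            if val < 0:
                raise InvalidProfileError(f"negative amount for {key}: {val}")
        for name in ("pufa_g", "mufa_g", "sfa_g", "solid_fat_kcal",
                     "added_sugar_kcal", "alcohol_g"):
            if getattr(self, name) < 0:
                raise InvalidProfileError(f"negative {name}")


@dataclass(frozen=True)
class HEIScore:
    component_scores: dict[str, float]
    total: float


def compute_density(amount: float, energy: float) -> float:
    """Amount per 1000 kcal for amount-based components."""
    if energy <= 0:
        raise InvalidProfileError(f"energy must be positive, got {energy}")
    if amount < 0:
        raise InvalidProfileError(f"amount must be non-negative, got {amount}")
    return amount * 1000.0 / energy


def fatty_acid_ratio(pufa_g: float, mufa_g: float, sfa_g: float) -> float:
    """(PUFA + MUFA) / SFA.

    A profile with unsaturated fat but literally zero saturated fat has an
    unbounded ratio; we return ``inf`` (scores at the cap) with a warning
    rather than guessing a finite value.  No fat at all leaves the ratio
    undefined.
    """
    unsat = pufa_g + mufa_g
    if sfa_g < 0 or unsat < 0:
        raise InvalidProfileError("fatty-acid grams must be non-negative")
    if sfa_g == 0:
        if unsat == 0:
            raise MissingRatioError("no fatty acids reported; ratio undefined")
        warnings.warn("zero SFA with positive PUFA+MUFA; ratio capped at inf",
                      stacklevel=2)
        return float("inf")
    return unsat / sfa_g


def empty_calorie_share(profile: IntakeProfile) -> float:
    """Percent of energy from solid fats, added sugars and excess alcohol.

    Alcohol only counts above 13 g per 1000 kcal; the excess grams contribute
    7 kcal/g.
    """
    profile.validate()
    return _empty_share(
        np.asarray(profile.solid_fat_kcal),
        np.asarray(profile.added_sugar_kcal),
        np.asarray(profile.alcohol_g),
        np.asarray(profile.energy),
    ).item()


def _empty_share(solid_fat_kcal, added_sugar_kcal, alcohol_g, energy):
    excess_g = np.maximum(
        0.0, alcohol_g - ALCOHOL_THRESHOLD_G_PER_1000KCAL * energy / 1000.0
    )
    kcal = solid_fat_kcal + added_sugar_kcal + ALCOHOL_KCAL_PER_G * excess_g
    return kcal / energy * 100.0


def score_component(density, std: ComponentStandards):
    """Points for one component given its density.

    Linear between ``density_at_zero`` (0 points) and ``density_at_max``
    (``max_points``), clamped; works for adequacy (uphill), moderation
    (downhill) and the fatty-acid ratio alike.  Vectorized over ``density``.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError(f"{std.component_id}: negative density")
    frac = (d - std.density_at_zero) / (std.density_at_max - std.density_at_zero)
    with np.errstate(invalid="ignore"):
        score = std.max_points * np.clip(frac, 0.0, 1.0)
    # inf density: full points uphill, zero points downhill
    score = np.where(np.isposinf(d),
                     std.max_points if std.direction != "moderation" else 0.0,
                     score)
    return score if score.ndim else float(score)


def score_frame(df: pd.DataFrame,
                standards: Mapping[str, ComponentStandards] | None = None,
                ) -> pd.DataFrame:
    """Score every row of an intake table; the vectorized workhorse.

    Expected columns: ``energy`` (kcal) plus per-component daily amounts named
    by component id.  The fatty-acid ratio may be given directly as
    ``fatty_acids`` (a ratio) or via ``pufa_g``/``mufa_g``/``sfa_g``; empty
    calories directly as ``empty_calories`` (kcal/day) or via
    ``solid_fat_kcal``/``added_sugar_kcal``/``alcohol_g``.

    Returns a frame of ``score_<component>`` columns plus ``score_total``,
    indexed like ``df``.
    """
    if standards is None:
        standards = load_standards()
    energy = df["energy"].to_numpy(float)
    if np.any(energy <= 0):
        raise InvalidProfileError("all rows must have positive energy")
    out = {}
    for cid in COMPONENT_IDS:
        std = standards[cid]
        if cid == "fatty_acids":
            if "fatty_acids" in df.columns:
                dens = df["fatty_acids"].to_numpy(float)
            else:
                sfa = df["sfa_g"].to_numpy(float)
                unsat = df["pufa_g"].to_numpy(float) + df["mufa_g"].to_numpy(float)
                with np.errstate(divide="ignore", invalid="ignore"):
                    dens = np.where(sfa > 0, unsat / np.where(sfa > 0, sfa, 1.0),
                                    np.where(unsat > 0, np.inf, np.nan))
        elif cid == "empty_calories":
            if "empty_calories" in df.columns:
                ec_kcal = df["empty_calories"].to_numpy(float)
                dens = ec_kcal / energy * 100.0
            else:
                dens = _empty_share(df["solid_fat_kcal"].to_numpy(float),
                                    df["added_sugar_kcal"].to_numpy(float),
                                    df["alcohol_g"].to_numpy(float), energy)
        else:
            amt = df[cid].to_numpy(float)
            if np.any(amt[~np.isnan(amt)] < 0):
                raise InvalidProfileError(f"negative amounts in column {cid}")
            dens = amt * 1000.0 / energy
        out[f"score_{cid}"] = score_component(dens, std)
    res = pd.DataFrame(out, index=df.index)
    res["score_total"] = res.sum(axis=1)
    return res


def score_profile(profile: IntakeProfile,
                  standards: Mapping[str, ComponentStandards] | None = None,
                  ) -> HEIScore:
    """Score a single intake profile on all 12 components."""
    if standards is None:
        standards = load_standards()
    if set(standards) != set(COMPONENT_IDS):
        raise ValueError("standards must cover exactly the 12 HEI components")
    profile.validate()
    row: dict[str, float] = {"energy": profile.energy}
    for cid in AMOUNT_COMPONENTS:
        if cid == "empty_calories" and cid not in profile.amounts:
            continue
        row[cid] = profile.amounts.get(cid, 0.0)
    if "fatty_acids" in profile.amounts:
        row["fatty_acids"] = profile.amounts["fatty_acids"]
    else:
        row["fatty_acids"] = fatty_acid_ratio(profile.pufa_g, profile.mufa_g,
                                              profile.sfa_g)
    if "empty_calories" not in row:
        row["solid_fat_kcal"] = profile.solid_fat_kcal
        row["added_sugar_kcal"] = profile.added_sugar_kcal
        row["alcohol_g"] = profile.alcohol_g
    scores = score_frame(pd.DataFrame([row]), standards).iloc[0]
    comp = {cid: float(scores[f"score_{cid}"]) for cid in COMPONENT_IDS}
    return HEIScore(component_scores=comp, total=float(scores["score_total"]))
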