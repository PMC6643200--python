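"""Synthetic cohorts with the structure the usual-intake analysis assumes.

The generator emulates a stratified two-stage survey of Hispanic/Latino adults
with two 24-h dietary recalls per person:

* participant covariates (age, sex, heritage group, field center, education,
  income, acculturation measures, weight status, smoking, activity, medical
  conditions) with configurable marginals;
* a survey design of strata, PSUs nested in strata, and positive sampling
  weights (>=2 PSUs per stratum so design-based variances exist);
* latent *usual intakes*: person effects drawn on the transformed scale
  (Box-Cox 0.25 for amounts and energy, log for the fatty-acid ratio) from a
  multivariate normal with between-component correlation, plus per-component
  consumption-probability random effects for episodically consumed foods;
* two noisy recalls per person: within-person residuals with their own
  correlation, additive weekend / recall-sequence / reported-usual-amount
  context effects, and zero-inflation of episodic components via a probit
  consumption model.

Ground truth — each person's usual intake (within-person expectation on the
natural scale, at the reference recall context) and survey-weighted summaries
of the truth — is retained so that recovery tests can compare the pipeline's
estimates against the quantity it targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .hei2010 import COMPONENT_IDS
from .transforms import TransformSpec, backtransform_mean

__all__ = [
    "Cohort",
    "CohortConfig",
    "ComponentTruth",
    "TrueUsualIntake",
    "generate_cohort",
    "generate_recalls",
    "true_summaries",
]

MODEL_COLUMNS = COMPONENT_IDS + ("energy",)  # 13 modeled dimensions

HERITAGE_MIX_DEFAULT = {
    "Mexican": 0.39, "Cuban": 0.21, "Puerto Rican": 0.17,
    "Central American": 0.08, "Dominican": 0.07, "South American": 0.08,
}
FIELD_CENTERS = ("Bronx", "Chicago", "Miami", "San Diego")


@dataclass(frozen=True)
class ComponentTruth:
    """Generating parameters for one modeled dimension (transformed scale)."""

    mean_amount: float      # natural units/day (given consumption, if episodic)
    between_sd: float       # person-effect SD on the transformed scale
    within_sd: float        # day-to-day residual SD on the transformed scale
    responsiveness: float = 1.0  # multiplier on the shared covariate index


def _bc_mean(comp: str, mean_amount: float) -> float:
    kind = "log" if comp == "fatty_acids" else "boxcox"
    spec = TransformSpec(comp, kind)
    return float(spec.raw(mean_amount))


#: Default per-component truth: typical daily amounts for an ~2000 kcal diet,
#: with day-to-day variability well above between-person variability (the
#: regime that makes single recalls poor measures of usual intake).
DEFAULT_COMPONENTS: dict[str, ComponentTruth] = {
    "total_fruit":           ComponentTruth(1.2, 0.35, 0.60, 1.0),
    "whole_fruit":           ComponentTruth(0.9, 0.40, 0.65, 0.8),
    "total_vegetables":      ComponentTruth(1.8, 0.30, 0.50, 1.2),
    "greens_beans":          ComponentTruth(0.45, 0.45, 0.70, 0.6),
    "whole_grains":          ComponentTruth(1.2, 0.50, 0.75, 1.1),
    "dairy":                 ComponentTruth(2.0, 0.40, 0.60, 0.9),
    "total_protein":         ComponentTruth(5.5, 0.25, 0.40, 0.7),
    "seafood_plant_protein": ComponentTruth(1.6, 0.45, 0.70, 1.3),
    "fatty_acids":           ComponentTruth(1.9, 0.25, 0.35, 0.5),
    "refined_grains":        ComponentTruth(4.4, 0.30, 0.50, -1.0),
    "sodium":                ComponentTruth(3.0, 0.25, 0.40, -0.8),
    "empty_calories":        ComponentTruth(450.0, 0.45, 0.70, -1.2),
    "energy":                ComponentTruth(2000.0, 0.50, 0.80, 0.3),
}

#: Default episodic components and their marginal consumption probabilities.
DEFAULT_EPISODIC = {"whole_fruit": 0.70, "greens_beans": 0.55,
                    "seafood_plant_protein": 0.50}

#: Context/covariate effects on the shared transformed-scale index (each
#: component feels effect * responsiveness).
DEFAULT_EFFECTS = {
    "age10": 0.03,        # per decade of age above 45
    "female": 0.06,
    "weekend": -0.08,
    "seq2": -0.05,
    "usual_more": 0.20,
    "usual_less": -0.20,
}
DEFAULT_HERITAGE_EFFECTS = {
    "Mexican": 0.10, "Cuban": -0.08, "Puerto Rican": -0.12,
    "Central American": 0.02, "Dominican": 0.05, "South American": 0.0,
}
DEFAULT_CENTER_EFFECTS = {"Bronx": 0.0, "Chicago": 0.05, "Miami": -0.04,
                          "San Diego": 0.03}
#: Probit-scale context effects on episodic consumption.
DEFAULT_PROBIT_EFFECTS = {"weekend": 0.10, "female": 0.05}


@dataclass
class CohortConfig:
    n: int = 2000
    seed: int = 0
    n_strata: int = 8
    psus_per_stratum: int = 6
    weight_sigma: float = 0.3          # lognormal dispersion of weights
    heritage_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(HERITAGE_MIX_DEFAULT))
    components: Mapping[str, ComponentTruth] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS))
    episodic: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EPISODIC))
    prob_re_sd: float = 0.8            # SD of consumption-probability effects
    between_corr: float = 0.30         # common correlation of person effects
    within_corr: float = 0.20          # common correlation of daily residuals
    effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS))
    heritage_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HERITAGE_EFFECTS))
    center_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CENTER_EFFECTS))
    probit_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROBIT_EFFECTS))
    missing_second_recall: float = 0.0
    misspecified_noise: bool = False   # skewed within-person residuals

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need n >= 4 (at least one participant per PSU "
                             "on a >=2x2 design)")
        if self.psus_per_stratum < 2:
            raise ValueError("need >=2 PSUs per stratum for variance "
                             "estimation")
        if abs(sum(self.heritage_mix.values()) - 1.0) > 1e-6:
            raise ValueError("heritage mix must sum to 1")
        bad = set(self.episodic) - set(COMPONENT_IDS)
        if bad:
            raise ValueError(f"unknown episodic components: {sorted(bad)}")
        for p in self.episodic.values():
            if not 0 < p <= 1:
                raise ValueError("episodic probabilities must be in (0, 1]")


@dataclass
class TrueUsualIntake:
    """Ground truth: usual intakes, consumption probabilities, latent effects."""

    usual: pd.DataFrame          # participant_id + MODEL_COLUMNS, natural scale
    probs: pd.DataFrame          # participant_id + episodic prob columns
    person_effects: np.ndarray   # (n, 13) on the transformed scale
    prob_effects: pd.DataFrame   # participant_id + episodic latent effects
    ref_index: np.ndarray        # (n, 13) reference-context fixed effects


@dataclass
class Cohort:
    config: CohortConfig
    covariates: pd.DataFrame
    design: pd.DataFrame
    truth: TrueUsualIntake

    def __iter__(self):  # allow (covars, design, truth) unpacking
        return iter((self.covariates, self.design, self.truth))


def _gen_spec(comp: str) -> TransformSpec:
    kind = "log" if comp == "fatty_acids" else "boxcox"
    return TransformSpec(comp, kind)


def _corr_matrix(k: int, rho: float) -> np.ndarray:
    return np.full((k, k), rho) + (1 - rho) * np.eye(k)


def _covariate_index(covars: pd.DataFrame, cfg: CohortConfig,
                     weekend=None, seq2=None, flag=None) -> np.ndarray:
    """Shared scalar index combining person and recall-context effects."""
    eff = cfg.effects
    idx = (eff["age10"] * (covars["age"].to_numpy(float) - 45.0) / 10.0
           + eff["female"] * (covars["sex"] == "female").to_numpy(float))
    idx += covars["heritage"].map(cfg.heritage_effects).to_numpy(float)
    idx += covars["field_center"].map(cfg.center_effects).to_numpy(float)
    if weekend is not None:
        idx = idx + eff["weekend"] * np.asarray(weekend, float)
        idx = idx + eff["seq2"] * np.asarray(seq2, float)
        idx = idx + eff["usual_more"] * (np.asarray(flag) == "more")
        idx = idx + eff["usual_less"] * (np.asarray(flag) == "less")
    return idx


def _probit_index(cfg: CohortConfig, comp: str, covars: pd.DataFrame,
                  weekend=None) -> np.ndarray:
    """Consumption-model linear predictor (excluding the person effect)."""
    p = cfg.episodic[comp]
    # intercept chosen so the marginal consumption probability is ~p
    gamma0 = norm.ppf(p) * np.sqrt(1.0 + cfg.prob_re_sd**2)
    idx = gamma0 + cfg.probit_effects["female"] * (
        (covars["sex"] == "female").to_numpy(float) - 0.5)
    if weekend is not None:
        idx = idx + cfg.probit_effects["weekend"] * np.asarray(weekend, float)
    return idx


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw covariates, survey design and true usual intakes."""
    cfg = config or CohortConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    rng_cov, rng_design, rng_b, rng_u = rngs
    n = cfg.n

    heritages = list(cfg.heritage_mix)
    covars = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "age": np.round(rng_cov.uniform(18, 74, n), 1),
        "sex": rng_cov.choice(["male", "female"], n, p=[0.48, 0.52]),
        "heritage": rng_cov.choice(heritages, n,
                                   p=list(cfg.heritage_mix.values())),
        "field_center": rng_cov.choice(FIELD_CENTERS, n),
        "education": rng_cov.choice(["no_hs", "hs", "gt_hs"], n,
                                    p=[0.35, 0.28, 0.37]),
        "income": rng_cov.choice(
            ["lt10k", "10_20k", "20_40k", "40_75k", "gt75k"], n,
            p=[0.18, 0.30, 0.32, 0.15, 0.05]),
        "employment": rng_cov.choice(["employed", "unemployed", "retired"], n,
                                     p=[0.55, 0.33, 0.12]),
        "marital": rng_cov.choice(["married", "single", "sep_div_wid"], n,
                                  p=[0.50, 0.30, 0.20]),
        "bmi_group": rng_cov.choice(
            ["underweight", "normal", "overweight", "obese"], n,
            p=[0.01, 0.22, 0.38, 0.39]),
        "smoking": rng_cov.choice(["never", "former", "current"], n,
                                  p=[0.62, 0.18, 0.20]),
        "activity": rng_cov.choice(["inactive", "low", "medium", "high"], n,
                                   p=[0.40, 0.20, 0.20, 0.20]),
        "language_preference": rng_cov.choice(["Spanish", "English"], n,
                                              p=[0.80, 0.20]),
        "us_born": rng_cov.random(n) < 0.21,
        "diabetes": rng_cov.random(n) < 0.148,
        "hypertension": rng_cov.random(n) < 0.221,
        "high_cholesterol": rng_cov.random(n) < 0.424,
    })
    spanish = covars["language_preference"] == "Spanish"
    sash_lang = np.where(spanish, rng_cov.normal(1.8, 0.7, n),
                         rng_cov.normal(3.6, 0.7, n))
    covars["sash_language"] = np.clip(np.round(sash_lang, 2), 1.0, 5.0)
    covars["sash_social"] = np.clip(
        np.round(rng_cov.normal(2.5, 0.8, n), 2), 1.0, 5.0)
    years = np.where(covars["us_born"], covars["age"],
                     rng_cov.uniform(0, 35, n))
    covars["years_in_us"] = np.round(np.minimum(years, covars["age"]), 1)

    n_psu = cfg.n_strata * cfg.psus_per_stratum
    psu_global = rng_design.integers(0, n_psu, n)
    design = pd.DataFrame({
        "id": covars["id"],
        "stratum": psu_global // cfg.psus_per_stratum,
        "psu": psu_global,
        "weight": np.exp(rng_design.normal(0.0, cfg.weight_sigma, n)),
    })

    comps = [cfg.components[c] for c in MODEL_COLUMNS]
    tau = np.array([c.between_sd for c in comps])
    Rb = _corr_matrix(len(comps), cfg.between_corr)
    Sigma_b = Rb * np.outer(tau, tau)
    b = rng_b.multivariate_normal(np.zeros(len(comps)), Sigma_b, size=n,
                                  method="cholesky") if tau.any() \
        else np.zeros((n, len(comps)))

    u = pd.DataFrame({"id": covars["id"]})
    for comp in cfg.episodic:
        u[comp] = rng_u.normal(0.0, cfg.prob_re_sd, n)

    base = _covariate_index(covars, cfg)
    mu = np.array([_bc_mean(c, cfg.components[c].mean_amount)
                   for c in MODEL_COLUMNS])
    resp = np.array([c.responsiveness for c in comps])
    ref_index = mu[None, :] + np.outer(base, resp)

    usual = pd.DataFrame({"participant_id": covars["id"]})
    probs = pd.DataFrame({"participant_id": covars["id"]})
    for k, comp in enumerate(MODEL_COLUMNS):
        spec = _gen_spec(comp)
        within_var = cfg.components[comp].within_sd ** 2
        vals = backtransform_mean(spec, ref_index[:, k] + b[:, k], within_var)
        if comp in cfg.episodic:
            p = norm.cdf(_probit_index(cfg, comp, covars)
                         + u[comp].to_numpy())
            probs[comp] = p
            vals = p * vals
        usual[comp] = vals

    truth = TrueUsualIntake(usual=usual, probs=probs, person_effects=b,
                            prob_effects=u, ref_index=ref_index)
    return Cohort(config=cfg, covariates=covars, design=design, truth=truth)


def generate_recalls(cohort: Cohort, seed: int | None = None) -> pd.DataFrame:
    """Simulate the (up to) two 24-h recalls for every participant.

    Reported transformed amounts are the person's reference-context index plus
    context effects (weekend incl. Friday, recall sequence, reported
    more/same/less than usual) plus the person effect plus a correlated daily
    residual; episodic components are zero on non-consumption days.  Energy,
    fatty-acid grams and the empty-calorie sources are emitted in the same
    per-recall table the pipeline readers expect.
    """
    cfg = cohort.config
    if seed is None:
        seed = cfg.seed + 1_000_003
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    covars, truth = cohort.covariates, cohort.truth
    n = len(covars)
    comps = [cfg.components[c] for c in MODEL_COLUMNS]
    sig = np.array([c.within_sd for c in comps])
    resp = np.array([c.responsiveness for c in comps])
    Sigma_e = _corr_matrix(len(comps), cfg.within_corr) * np.outer(sig, sig)
    L = np.linalg.cholesky(Sigma_e + 1e-12 * np.eye(len(comps))) \
        if sig.any() else np.zeros((len(comps), len(comps)))

    rows = []
    for seq in (1, 2):
        weekend = rng.random(n) < 3.0 / 7.0
        flag = rng.choice(["more", "same", "less"], n, p=[0.2, 0.6, 0.2])
        eff = cfg.effects
        context = (eff["weekend"] * weekend
                   + eff["seq2"] * (seq == 2)
                   + eff["usual_more"] * (flag == "more")
                   + eff["usual_less"] * (flag == "less"))
        if cfg.misspecified_noise:
            # centered, scaled chi-square(4) residuals: mean 0, unit sd, skewed
            raw = (rng.chisquare(4, size=(n, len(comps))) - 4.0) / np.sqrt(8.0)
            e = raw * sig[None, :]
        else:
            e = rng.standard_normal((n, len(comps))) @ L.T
        t = truth.ref_index + np.outer(context, resp) \
            + truth.person_effects + e

        rec = pd.DataFrame({
            "participant_id": covars["id"].to_numpy(),
            "sequence": seq,
            "weekend": weekend,
            "usual_amount_flag": flag,
        })
        amounts = {}
        for k, comp in enumerate(MODEL_COLUMNS):
            spec = _gen_spec(comp)
            amounts[comp] = spec.inverse(t[:, k])
        energy = np.maximum(amounts["energy"], 250.0)
        rec["energy"] = energy
        for comp in COMPONENT_IDS:
            if comp in ("fatty_acids", "empty_calories"):
                continue
            vals = amounts[comp]
            if comp in cfg.episodic:
                p = norm.cdf(_probit_index(cfg, comp, covars, weekend)
                             + truth.prob_effects[comp].to_numpy())
                consumed = rng.random(n) < p
                vals = np.where(consumed, vals, 0.0)
            rec[comp] = vals
        # fatty acids: the modeled quantity is the (PUFA+MUFA)/SFA ratio;
        # SFA grams ride on energy (~10% of kcal) with mild noise
        ratio = amounts["fatty_acids"]
        sfa = 0.10 * energy / 9.0 * np.exp(rng.normal(0, 0.15, n))
        rec["sfa_g"] = sfa
        rec["pufa_g"] = 0.4 * ratio * sfa
        rec["mufa_g"] = 0.6 * ratio * sfa
        # empty calories: modeled as a kcal amount, reported via its sources
        ec = np.minimum(amounts["empty_calories"], 0.95 * energy)
        rec["solid_fat_kcal"] = 0.6 * ec
        rec["added_sugar_kcal"] = 0.4 * ec
        rec["alcohol_g"] = 0.0
        rows.append(rec)

    recalls = pd.concat(rows, ignore_index=True)
    if cfg.missing_second_recall > 0:
        drop = rng.random(n) < cfg.missing_second_recall
        drop_ids = set(covars["id"].to_numpy()[drop])
        keep = ~((recalls["sequence"] == 2)
                 & recalls["participant_id"].isin(drop_ids))
        recalls = recalls.loc[keep].reset_index(drop=True)
    return recalls.sort_values(["participant_id", "sequence"],
                               ignore_index=True)


def true_summaries(cohort: Cohort, standards=None) -> pd.DataFrame:
    """Survey-weighted HEI summaries of the *true* usual intakes.

    The gold standard recovery tests compare against: per-component weighted
    mean score and percent-at-maximum, plus the total-score row.
    """
    from .pseudo import score_summary  # local import to avoid a cycle
    from .hei2010 import score_frame

    usual = cohort.truth.usual
    frame = usual.rename(columns={"empty_calories": "empty_calories"}).copy()
    scores = score_frame(frame, standards)
    weights = cohort.design.set_index("id").loc[
        usual["participant_id"], "weight"].to_numpy()
    return score_summary(scores, weights, standards)
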