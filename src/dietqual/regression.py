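"""Correlates of diet quality: survey-weighted regression with selection.

The person-level outcome is the HEI-2010 total computed from recall-averaged
intake (amounts and energy averaged across the available recalls first, then
scored once — average-then-score).  The model is weighted least squares with
design-based (Taylor linearization over stratum/PSU) variances.  Model
selection is backward: categorical predictors are tested and dropped as whole
blocks via joint Wald tests, removing the least significant candidate until
every remaining candidate is significant at the stay level (p <= 0.1), with
field center and heritage forced to stay regardless.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import stats

from .hei2010 import score_frame
from .survey import validate_design

__all__ = [
    "CategoricalTerm",
    "ContinuousTerm",
    "DEFAULT_TERMS",
    "RegressionResult",
    "RegressionSpec",
    "backward_select",
    "build_design",
    "fit_wls",
    "person_hei",
]


# ---------------------------------------------------------------------------
# outcome
# ---------------------------------------------------------------------------

def person_hei(recalls: pd.DataFrame, standards=None) -> pd.DataFrame:
    """Average intake across recalls, then score: one HEI row per person.

    Averaging precedes scoring so densities come from averaged amounts and
    averaged energy (not the mean of per-recall densities).  Participants
    need at least one recall.
    """
    if len(recalls) == 0:
        raise ValueError("no recalls provided")
    num_cols = [c for c in recalls.columns
                if c not in ("participant_id", "sequence", "weekend",
                             "usual_amount_flag")
                and pd.api.types.is_numeric_dtype(recalls[c])]
    avg = recalls.groupby("participant_id")[num_cols].mean().reset_index()
    scores = score_frame(avg, standards)
    return pd.concat([avg[["participant_id"]], scores], axis=1)


# ---------------------------------------------------------------------------
# design encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousTerm:
    name: str

    def columns(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({self.name: df[self.name].to_numpy(float)})


@dataclass(frozen=True)
class CategoricalTerm:
    name: str
    levels: tuple[str, ...]
    reference: str

    def columns(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        vals = df[self.name].astype(str)
        unknown = set(vals.unique()) - set(map(str, self.levels))
        if unknown:
            raise ValueError(f"{self.name}: unexpected levels {sorted(unknown)}")
        for lev in self.levels:
            if str(lev) == str(self.reference):
                continue
            out[f"{self.name}[{lev}]"] = (vals == str(lev)).to_numpy(float)
        return pd.DataFrame(out)


def _bool_term(name: str) -> CategoricalTerm:
    return CategoricalTerm(name, ("False", "True"), "False")


#: Candidate terms with the study's reference levels (Mexican heritage,
#: Bronx center, no-HS education, lowest income, obese, current smoker,
#: inactive).
DEFAULT_TERMS: dict[str, ContinuousTerm | CategoricalTerm] = {
    "age": ContinuousTerm("age"),
    "sex": CategoricalTerm("sex", ("male", "female"), "male"),
    "bmi_group": CategoricalTerm(
        "bmi_group", ("underweight", "normal", "overweight", "obese"),
        "obese"),
    "smoking": CategoricalTerm("smoking", ("never", "former", "current"),
                               "current"),
    "activity": CategoricalTerm("activity",
                                ("inactive", "low", "medium", "high"),
                                "inactive"),
    "education": CategoricalTerm("education", ("no_hs", "hs", "gt_hs"),
                                 "no_hs"),
    "income": CategoricalTerm(
        "income", ("lt10k", "10_20k", "20_40k", "40_75k", "gt75k"), "lt10k"),
    "employment": CategoricalTerm(
        "employment", ("employed", "unemployed", "retired"), "employed"),
    "marital": CategoricalTerm("marital",
                               ("married", "single", "sep_div_wid"),
                               "married"),
    "heritage": CategoricalTerm(
        "heritage", ("Mexican", "Central American", "Cuban", "Dominican",
                     "Puerto Rican", "South American"), "Mexican"),
    "us_born": _bool_term("us_born"),
    "years_in_us": ContinuousTerm("years_in_us"),
    "language_preference": CategoricalTerm(
        "language_preference", ("English", "Spanish"), "English"),
    "sash_language": ContinuousTerm("sash_language"),
    "sash_social": ContinuousTerm("sash_social"),
    "field_center": CategoricalTerm(
        "field_center", ("Bronx", "Chicago", "Miami", "San Diego"), "Bronx"),
    "high_cholesterol": _bool_term("high_cholesterol"),
    "diabetes": _bool_term("diabetes"),
    "hypertension": _bool_term("hypertension"),
}


@dataclass
class RegressionSpec:
    candidates: list[str] = dc_field(
        default_factory=lambda: list(DEFAULT_TERMS))
    forced: tuple[str, ...] = ("field_center", "heritage")
    alpha_stay: float = 0.1
    terms: dict = dc_field(default_factory=lambda: dict(DEFAULT_TERMS))

    def __post_init__(self) -> None:
        if not set(self.forced) <= set(self.candidates):
            raise ValueError("forced terms must be a subset of candidates")
        if not 0 < self.alpha_stay < 1:
            raise ValueError("alpha_stay must be in (0, 1)")
        unknown = set(self.candidates) - set(self.terms)
        if unknown:
            raise ValueError(f"no term definition for {sorted(unknown)}")


def build_design(df: pd.DataFrame, term_names, terms=None):
    """Stack intercept + term columns; returns (X, columns, term blocks)."""
    terms = terms or DEFAULT_TERMS
    parts = [pd.DataFrame({"intercept": np.ones(len(df))})]
    blocks: dict[str, list[str]] = {}
    for name in term_names:
        cols = terms[name].columns(df)
        blocks[name] = list(cols.columns)
        parts.append(cols)
    X = pd.concat(parts, axis=1)
    return X.to_numpy(float), list(X.columns), blocks


# ---------------------------------------------------------------------------
# survey-weighted least squares
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    table: pd.DataFrame            # term, estimate, se, ci_low, ci_high, p
    term_pvalues: dict[str, float]  # joint Wald p per term block
    r_squared: float
    df_design: int
    dropped: list[tuple[str, float]] = dc_field(default_factory=list)
    selected: list[str] = dc_field(default_factory=list)


def fit_wls(y, X: np.ndarray, design: pd.DataFrame,
            columns: list[str] | None = None,
            blocks: dict[str, list[str]] | None = None) -> RegressionResult:
    """Weighted least squares with Taylor-linearized design-based variance.

    Point estimates minimize the weighted residual sum of squares; the
    covariance is the stratified-cluster sandwich over PSU totals of the
    score  w * x * resid, with an (n_h)/(n_h - 1) stratum factor.  Wald
    t intervals use design degrees of freedom (#PSUs - #strata).
    """
    validate_design(design)
    y = np.asarray(y, float)
    w = design["weight"].to_numpy(float)
    if X.ndim != 2 or len(y) != X.shape[0] or len(w) != X.shape[0]:
        raise ValueError("y, X and design must have matching rows")
    if columns is None:
        columns = [f"x{j}" for j in range(X.shape[1])]

    rank = np.linalg.matrix_rank(X * np.sqrt(w)[:, None])
    if rank < X.shape[1]:
        aliased = _find_aliased(X, w, columns)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    XtWX = X.T @ (X * w[:, None])
    bread = np.linalg.inv(XtWX)
    beta = bread @ (X.T @ (w * y))
    resid = y - X @ beta

    scores = X * (w * resid)[:, None]
    sdf = pd.DataFrame({"stratum": design["stratum"].to_numpy(),
                        "psu": design["psu"].to_numpy()})
    meat = np.zeros((X.shape[1], X.shape[1]))
    n_psu = 0
    n_strata = 0
    for _, g in sdf.groupby("stratum"):
        idx_by_psu = g.groupby("psu").indices
        totals = np.stack([scores[list(ix)].sum(axis=0)
                           for ix in idx_by_psu.values()])
        n_h = totals.shape[0]
        n_psu += n_h
        n_strata += 1
        centered = totals - totals.mean(axis=0)
        meat += n_h / (n_h - 1) * centered.T @ centered
    V = bread @ meat @ bread
    df_design = n_psu - n_strata

    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    tcrit = stats.t.ppf(0.975, df_design)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf)
    p = 2 * stats.t.sf(np.abs(tstat), df_design)
    table = pd.DataFrame({
        "term": columns, "estimate": beta, "se": se,
        "ci_low": beta - tcrit * se, "ci_high": beta + tcrit * se,
        "p_value": p,
    }).set_index("term")

    ybar = np.sum(w * y) / w.sum()
    tss = np.sum(w * (y - ybar) ** 2)
    r2 = float(1.0 - np.sum(w * resid**2) / tss) if tss > 0 else np.nan

    term_p: dict[str, float] = {}
    if blocks:
        col_pos = {c: i for i, c in enumerate(columns)}
        for name, cols in blocks.items():
            ix = [col_pos[c] for c in cols]
            b = beta[ix]
            Vb = V[np.ix_(ix, ix)]
            q = len(ix)
            try:
                stat = float(b @ np.linalg.solve(Vb, b)) / q
            except np.linalg.LinAlgError:
                stat = np.inf
            term_p[name] = float(stats.f.sf(stat, q, max(df_design - q + 1, 1)))
    return RegressionResult(table=table, term_pvalues=term_p, r_squared=r2,
                            df_design=df_design)


def _find_aliased(X, w, columns):
    """Name columns that are linearly dependent on earlier ones."""
    aliased = []
    Xw = X * np.sqrt(w)[:, None]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(Xw[:, : j + 1]) <= np.linalg.matrix_rank(
                Xw[:, :j]):
            aliased.append(columns[j])
    return aliased or ["<unknown>"]


def backward_select(spec: RegressionSpec, data: pd.DataFrame,
                    design: pd.DataFrame,
                    outcome: str = "score_total") -> RegressionResult:
    """Backward elimination with forced terms and block-level Wald tests.

    Starting from all candidates, repeatedly drop the non-forced term with
    the largest joint p-value exceeding ``alpha_stay`` (ties broken by larger
    p then by term name) and refit, until every remaining non-forced term is
    significant.  The audit trail records each drop with its p-value.
    """
    current = list(spec.candidates)
    dropped: list[tuple[str, float]] = []
    y = data[outcome].to_numpy(float)
    while True:
        X, columns, blocks = build_design(data, current, spec.terms)
        res = fit_wls(y, X, design, columns, blocks)
        removable = {t: p for t, p in res.term_pvalues.items()
                     if t not in spec.forced}
        if not removable:
            break
        worst = sorted(removable.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if worst[1] <= spec.alpha_stay:
            break
        dropped.append((worst[0], float(worst[1])))
        current.remove(worst[0])
    res.dropped = dropped
    res.selected = current
    return res
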