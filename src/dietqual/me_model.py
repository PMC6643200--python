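"""Multivariate measurement-error model for usual dietary intake.

A single 24-h recall is a noisy measure of a person's usual (long-run average)
intake: day-to-day variability is large, episodically consumed foods produce
zero-inflated reports, and components are correlated.  With at most two
recalls per person, the model

    z_ijk = x_ij' beta_k + b_ik + e_ijk          (amounts + energy, k = 1..13)
    P(consume_ijk) = Phi(x_ij' gamma_k + u_ik)   (episodic components)

on the transformed scale (Box-Cox 0.25, log for the fatty-acid ratio;
centered, variance 2) separates between-person variation  b_i ~ N(0, Sigma_b)
from within-person noise  e_ij ~ N(0, Sigma_e), with covariate adjustment for
sex, age, heritage, field center, weekend (incl. Friday), reported usual
amount (more/same/less) and recall sequence.

Fitting is by a method-of-moments decomposition of the cross-recall residual
covariance (exact EM refinement optional), with the episodic consumption
submodel estimated by marginal probit plus a concordance-matching random
effect.  Usual intakes are then drawn per participant from the Gaussian
posterior of the person effects given their recalls, back-transformed with
Gauss–Hermite bias correction, and (for episodic components) multiplied by
the posterior consumption probability — all at the reference recall context
(weekday, first recall, reported "same as usual").
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm
import statsmodels.api as sm

from .hei2010 import COMPONENT_IDS
from .transforms import TransformSpec, backtransform_mean, fit_transform_spec

__all__ = [
    "EpisodicSubmodel",
    "FittedMEModel",
    "IdentifiabilityError",
    "MEConfig",
    "MODEL_COLUMNS",
    "component_amounts",
    "draw_usual",
    "fit",
    "recall_design",
    "reference_design",
]

MODEL_COLUMNS = COMPONENT_IDS + ("energy",)

HERITAGE_LEVELS = ("Mexican", "Central American", "Cuban", "Dominican",
                   "Puerto Rican", "South American")
CENTER_LEVELS = ("Bronx", "Chicago", "Miami", "San Diego")


class IdentifiabilityError(ValueError):
    """The recall data cannot identify the within-person variance."""


@dataclass
class MEConfig:
    episodic_threshold: float = 0.10  # zero share above which a component is episodic
    em_iterations: int = 2            # exact-EM refinement passes after the moment fit
    quadrature_points: int = 9        # Gauss–Hermite nodes for back-transformation
    prob_grid_points: int = 41        # grid for the consumption-effect posterior
    ridge: float = 1e-8


@dataclass
class EpisodicSubmodel:
    component_id: str
    gamma: np.ndarray      # probit coefficients (person-effect scale)
    sigma_u: float         # SD of the consumption-probability person effect
    converged: bool = True


@dataclass
class FittedMEModel:
    transforms: dict[str, TransformSpec]
    design_columns: list[str]
    beta: pd.DataFrame            # (design columns) x (model columns)
    beta_se: pd.DataFrame         # cluster-robust (by participant) SEs
    Sigma_b: np.ndarray           # 13x13 between-person covariance
    Sigma_e: np.ndarray           # 13x13 within-person covariance
    episodic: dict[str, EpisodicSubmodel]
    config: MEConfig = field(default_factory=MEConfig)
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    def to_json(self, path: str) -> None:
        """Serialize the fitted model to a documented JSON bundle."""
        blob = {
            "model_columns": list(MODEL_COLUMNS),
            "design_columns": self.design_columns,
            "transforms": {
                c: {"kind": s.kind, "lam": s.lam, "shift": s.shift,
                    "center": s.center, "scale": s.scale}
                for c, s in self.transforms.items()},
            "beta": self.beta.to_dict(),
            "beta_se": self.beta_se.to_dict(),
            "Sigma_b": self.Sigma_b.tolist(),
            "Sigma_e": self.Sigma_e.tolist(),
            "episodic": {
                c: {"gamma": m.gamma.tolist(), "sigma_u": m.sigma_u,
                    "converged": m.converged}
                for c, m in self.episodic.items()},
            "config": vars(self.config),
            "diagnostics": self.diagnostics,
        }
        with open(path, "w") as fh:
            json.dump(blob, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FittedMEModel":
        with open(path) as fh:
            blob = json.load(fh)
        transforms = {
            c: TransformSpec(c, d["kind"], lam=d["lam"], shift=d["shift"],
                             center=d["center"], scale=d["scale"])
            for c, d in blob["transforms"].items()}
        episodic = {
            c: EpisodicSubmodel(c, np.asarray(d["gamma"]), d["sigma_u"],
                                d["converged"])
            for c, d in blob["episodic"].items()}
        return cls(
            transforms=transforms,
            design_columns=blob["design_columns"],
            beta=pd.DataFrame(blob["beta"]).loc[blob["design_columns"]],
            beta_se=pd.DataFrame(blob["beta_se"]).loc[blob["design_columns"]],
            Sigma_b=np.asarray(blob["Sigma_b"]),
            Sigma_e=np.asarray(blob["Sigma_e"]),
            episodic=episodic,
            config=MEConfig(**blob["config"]),
            diagnostics=blob["diagnostics"],
        )


# ---------------------------------------------------------------------------
# design matrices and amount preparation
# ---------------------------------------------------------------------------

def recall_design(df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Covariate design for one recall row: the full adjustment set."""
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    cols["age_c"] = (df["age"].to_numpy(float) - 45.0) / 10.0
    cols["female"] = (df["sex"] == "female").to_numpy(float)
    for h in HERITAGE_LEVELS[1:]:
        cols[f"heritage_{h}"] = (df["heritage"] == h).to_numpy(float)
    for c in CENTER_LEVELS[1:]:
        cols[f"center_{c}"] = (df["field_center"] == c).to_numpy(float)
    cols["weekend"] = df["weekend"].to_numpy(float)
    cols["usual_more"] = (df["usual_amount_flag"] == "more").to_numpy(float)
    cols["usual_less"] = (df["usual_amount_flag"] == "less").to_numpy(float)
    cols["seq2"] = (df["sequence"].to_numpy(int) == 2).astype(float)
    X = np.column_stack(list(cols.values()))
    return X, list(cols)


def design_for(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Design matrix restricted to the columns a fitted model retained."""
    X, names = recall_design(df)
    idx = [names.index(c) for c in columns]
    return X[:, idx]


def reference_design(covars: pd.DataFrame, age_override: float | None = None,
                     female: np.ndarray | None = None,
                     ) -> tuple[np.ndarray, list[str]]:
    """Design at the reference recall context (weekday, first recall, "same").

    ``age_override`` standardizes age; ``female`` (0/1 array) overrides the
    observed sex, used when marginalizing sex to a standard proportion male.
    """
    ref = covars.copy()
    ref["weekend"] = 0.0
    ref["usual_amount_flag"] = "same"
    ref["sequence"] = 1
    if age_override is not None:
        ref["age"] = age_override
    if female is not None:
        ref["sex"] = np.where(np.asarray(female, bool), "female", "male")
    return recall_design(ref)


def _reference_X(model: "FittedMEModel", covars: pd.DataFrame,
                 age_override=None, female=None) -> np.ndarray:
    ref = covars.copy()
    ref["weekend"] = 0.0
    ref["usual_amount_flag"] = "same"
    ref["sequence"] = 1
    if age_override is not None:
        ref["age"] = age_override
    if female is not None:
        ref["sex"] = np.where(np.asarray(female, bool), "female", "male")
    return design_for(ref, model.design_columns)


def component_amounts(recalls: pd.DataFrame) -> pd.DataFrame:
    """13-column matrix of modeled amounts from a per-recall table.

    Plain components are passed through; ``fatty_acids`` becomes the
    (PUFA+MUFA)/SFA ratio and ``empty_calories`` the kcal total from solid
    fat, added sugar and above-threshold alcohol.
    """
    from .hei2010 import _empty_share

    out = pd.DataFrame(index=recalls.index)
    for comp in COMPONENT_IDS:
        if comp == "fatty_acids":
            sfa = recalls["sfa_g"].to_numpy(float)
            unsat = (recalls["pufa_g"].to_numpy(float)
                     + recalls["mufa_g"].to_numpy(float))
            if np.any(sfa <= 0):
                raise ValueError("non-positive SFA grams in recalls")
            out[comp] = unsat / sfa
        elif comp == "empty_calories":
            if "empty_calories" in recalls.columns:
                out[comp] = recalls["empty_calories"].to_numpy(float)
            else:
                energy = recalls["energy"].to_numpy(float)
                out[comp] = _empty_share(
                    recalls["solid_fat_kcal"].to_numpy(float),
                    recalls["added_sugar_kcal"].to_numpy(float),
                    recalls["alcohol_g"].to_numpy(float), energy,
                ) * energy / 100.0
        else:
            out[comp] = recalls[comp].to_numpy(float)
    out["energy"] = recalls["energy"].to_numpy(float)
    return out


# ---------------------------------------------------------------------------
# numerics
# ---------------------------------------------------------------------------

def _psd_project(S: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, float]:
    """Nearest-PSD projection by eigenvalue clipping; returns (matrix, change)."""
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eigh(S)
    clipped = np.clip(vals, floor, None)
    change = float(np.abs(vals - clipped).sum())
    return (vecs * clipped) @ vecs.T, change


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) via Owen's T."""
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    rho = float(np.clip(rho, -0.999, 0.999))
    eps = 1e-12
    hs = np.where(np.abs(h) < eps, eps, h)
    ks = np.where(np.abs(k) < eps, eps, k)
    root = np.sqrt(1.0 - rho * rho)
    ah = (ks - rho * hs) / (hs * root)
    ak = (hs - rho * ks) / (ks * root)
    beta = np.where((hs * ks > 0) | ((hs * ks == 0) & (hs + ks >= 0)), 0.0, 0.5)
    return (0.5 * (norm.cdf(h) + norm.cdf(k))
            - owens_t(hs, ah) - owens_t(ks, ak) - beta)


def _pairwise_cov(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise-complete covariance between columns of A and columns of B."""
    K = A.shape[1]
    out = np.full((K, B.shape[1]), np.nan)
    for i in range(K):
        ai = A[:, i]
        for j in range(B.shape[1]):
            bj = B[:, j]
            ok = ~np.isnan(ai) & ~np.isnan(bj)
            if ok.sum() < 3:
                out[i, j] = 0.0
            else:
                out[i, j] = np.mean((ai[ok] - ai[ok].mean())
                                    * (bj[ok] - bj[ok].mean()))
    return out


def posterior_moments(residuals: np.ndarray, person_index: np.ndarray,
                      Sigma_b: np.ndarray, Sigma_e: np.ndarray,
                      ridge: float = 1e-8):
    """Gaussian posterior of person effects given recall residuals.

    ``residuals`` is (rows, K) with NaN where a component was unobserved on
    that day; ``person_index`` maps rows to 0..n-1.  Returns
    ``(means (n, K), covs (n_groups, K, K), group_of_person (n,))`` where
    persons sharing an observation pattern share a posterior covariance.
    """
    K = Sigma_b.shape[0]
    n = int(person_index.max()) + 1
    lam_b = max(ridge, ridge * np.trace(Sigma_b) / K)
    lam_e = max(ridge, ridge * np.trace(Sigma_e) / K)
    Sb_inv = np.linalg.inv(Sigma_b + lam_b * np.eye(K))

    obs = ~np.isnan(residuals)
    masks = obs.dot(1 << np.arange(K))
    prec_by_mask: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    H = np.zeros((len(residuals), K))
    P_embed: dict[int, np.ndarray] = {}
    for m in np.unique(masks):
        idx = np.flatnonzero((m >> np.arange(K)) & 1)
        Pe = np.linalg.inv(Sigma_e[np.ix_(idx, idx)] + lam_e * np.eye(len(idx)))
        full = np.zeros((K, K))
        full[np.ix_(idx, idx)] = Pe
        P_embed[int(m)] = full
        rows = np.flatnonzero(masks == m)
        r = np.nan_to_num(residuals[rows][:, idx])
        H[np.ix_(rows, idx)] = r @ Pe.T
        prec_by_mask[int(m)] = (idx, Pe)

    # per-person precision = prior + sum of recall-day contributions
    h_person = np.zeros((n, K))
    combos: dict[tuple, list[int]] = {}
    per_person_masks: dict[int, list[int]] = {}
    for row, pid in enumerate(person_index):
        per_person_masks.setdefault(int(pid), []).append(int(masks[row]))
        h_person[pid] += H[row]
    for pid, ms in per_person_masks.items():
        key = tuple(sorted(ms))
        combos.setdefault(key, []).append(pid)

    means = np.zeros((n, K))
    covs = np.zeros((len(combos), K, K))
    group_of = np.zeros(n, dtype=int)
    for g, (key, pids) in enumerate(sorted(combos.items())):
        A = Sb_inv.copy()
        for m in key:
            A += P_embed[m]
        V = np.linalg.inv(A)
        covs[g] = 0.5 * (V + V.T)
        pids = np.asarray(pids)
        means[pids] = h_person[pids] @ covs[g].T
        group_of[pids] = g
    return means, covs, group_of


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _moment_probit_start(y, X, person_index, comp):
    """Marginal probit + concordance-matched person-effect variance.

    Fast and consistent; used to initialize the maximum-likelihood fit.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Probit(y, X).fit(disp=0, maxiter=200)
    gamma_star = np.asarray(res.params)
    converged = bool(res.mle_retvals.get("converged", True))

    # persons with two recalls: match observed P(consume on both days)
    df = pd.DataFrame({"pid": person_index, "y": y, "m": X @ gamma_star})
    g = df.groupby("pid").filter(lambda t: len(t) == 2)
    if len(g) == 0:
        return EpisodicSubmodel(comp, gamma_star, 0.0, converged)
    wide_y = g.groupby("pid")["y"].apply(list)
    wide_m = g.groupby("pid")["m"].apply(list)
    y1 = np.array([v[0] for v in wide_y]); y2 = np.array([v[1] for v in wide_y])
    m1 = np.array([v[0] for v in wide_m]); m2 = np.array([v[1] for v in wide_m])
    target = float(np.mean(y1 * y2))

    def gap(rho):
        return float(np.mean(bvn_cdf(m1, m2, rho))) - target

    if gap(0.0) >= 0.0:
        rho = 0.0
    elif gap(0.98) <= 0.0:
        rho = 0.98
    else:
        rho = brentq(gap, 0.0, 0.98, xtol=1e-6)
    sigma_u = float(np.sqrt(rho / (1.0 - rho)))
    gamma = gamma_star * np.sqrt(1.0 + sigma_u**2)
    return EpisodicSubmodel(comp, gamma, sigma_u, converged)


def _fit_probit_part(y: np.ndarray, X: np.ndarray, person_index: np.ndarray,
                     comp: str, gh_points: int = 15) -> EpisodicSubmodel:
    """Random-effects probit consumption model by maximum likelihood.

    The per-person likelihood integrates the N(0, sigma_u^2) consumption
    effect with Gauss–Hermite quadrature; optimization starts from the
    marginal-probit/concordance moment estimate.
    """
    from scipy.optimize import minimize

    start = _moment_probit_start(y, X, person_index, comp)
    nodes, wts = np.polynomial.hermite.hermgauss(gh_points)
    wts = wts / np.sqrt(np.pi)
    n = int(person_index.max()) + 1
    y = np.asarray(y, float)

    def negll(theta):
        gamma = theta[:-1]
        log_sigma = np.clip(theta[-1], -6.0, 3.0)
        sigma = np.exp(log_sigma)
        idx = X @ gamma
        # (rows, nodes) log-likelihood at u = sqrt(2) * sigma * node
        z = idx[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        row_ll = np.where(y[:, None] > 0, norm.logcdf(z), norm.logcdf(-z))
        per = np.zeros((n, gh_points))
        np.add.at(per, person_index, row_ll)
        per = np.clip(per, -700, 0)
        lik = np.exp(per) @ wts
        return -float(np.sum(np.log(np.maximum(lik, 1e-300))))

    theta0 = np.append(start.gamma, np.log(max(start.sigma_u, 0.05)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = minimize(negll, theta0, method="L-BFGS-B",
                       options={"maxiter": 200})
    if not res.success:
        return start
    sigma_u = float(np.exp(np.clip(res.x[-1], -6.0, 3.0)))
    if sigma_u < 1e-3:
        sigma_u = 0.0
    return EpisodicSubmodel(comp, res.x[:-1], sigma_u,
                            start.converged and bool(res.success))


def _cluster_se(X, resid, clusters):
    """Cluster-robust sandwich SEs with a G/(G-1) small-sample factor."""
    XtX_inv = np.linalg.pinv(X.T @ X)
    meat = np.zeros((X.shape[1], X.shape[1]))
    Xr = X * resid[:, None]
    groups = pd.DataFrame({"c": clusters}).groupby("c").indices
    G = len(groups)
    for rows in groups.values():
        s = Xr[rows].sum(axis=0)
        meat += np.outer(s, s)
    V = XtX_inv @ meat @ XtX_inv * (G / max(G - 1, 1))
    return np.sqrt(np.maximum(np.diag(V), 0.0))


def _ols_with_cluster_se(y, X, clusters):
    """OLS point estimates + cluster-robust SEs; y may contain no NaN."""
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    return beta, _cluster_se(X, resid, clusters), resid


def fit(recalls: pd.DataFrame, covars: pd.DataFrame,
        config: MEConfig | None = None) -> FittedMEModel:
    """Fit the measurement-error model to recall and covariate tables.

    Moment-based: per-component OLS fixed effects on the transformed scale,
    between-/within-person covariances from the cross-recall residual
    decomposition, episodic consumption by marginal probit with a
    concordance-matched random effect, followed by ``config.em_iterations``
    exact EM passes on the Gaussian part.  Deterministic.
    """
    cfg = config or MEConfig()
    merged = recalls.merge(covars, left_on="participant_id", right_on="id",
                           validate="many_to_one")
    if len(merged) != len(recalls):
        raise ValueError("recalls reference participants missing from covars")
    counts = merged.groupby("participant_id").size()
    if (counts > 2).any():
        raise ValueError("more than two recalls for some participants")
    n_two = int((counts == 2).sum())
    if n_two == 0:
        raise IdentifiabilityError(
            "no participant has two recalls; within-person variance is not "
            "identifiable")

    amounts = component_amounts(merged)
    X, design_cols = recall_design(merged)
    # drop covariate columns without variation (e.g. sex within a
    # single-sex subgroup fit); the intercept absorbs them
    keep = [j for j, name in enumerate(design_cols)
            if name == "intercept" or X[:, j].std() > 0]
    X = X[:, keep]
    design_cols = [design_cols[j] for j in keep]
    pid_codes, pid_uniques = pd.factorize(merged["participant_id"])

    K = len(MODEL_COLUMNS)
    zero_share = {}
    episodic_comps = []
    for comp in COMPONENT_IDS:
        share = float((amounts[comp] <= 0).mean())
        zero_share[comp] = share
        if share > cfg.episodic_threshold:
            episodic_comps.append(comp)

    transforms: dict[str, TransformSpec] = {}
    Z = np.full((len(merged), K), np.nan)
    for k, comp in enumerate(MODEL_COLUMNS):
        vals = amounts[comp].to_numpy(float).copy()
        if comp in episodic_comps:
            vals[vals <= 0] = np.nan
        kind = "log" if comp == "fatty_acids" else "boxcox"
        spec = fit_transform_spec(comp, vals, kind=kind)
        transforms[comp] = spec
        ok = ~np.isnan(vals)
        Z[ok, k] = spec.forward(vals[ok])

    beta = np.zeros((X.shape[1], K))
    beta_se = np.zeros_like(beta)
    R = np.full_like(Z, np.nan)
    for k in range(K):
        ok = ~np.isnan(Z[:, k])
        b, se, resid = _ols_with_cluster_se(Z[ok, k], X[ok], pid_codes[ok])
        beta[:, k] = b
        beta_se[:, k] = se
        R[ok, k] = resid

    # cross-recall covariance decomposition (persons with both recalls)
    both = counts[counts == 2].index
    is_both = merged["participant_id"].isin(both).to_numpy()
    seq = merged["sequence"].to_numpy()
    r1 = R[is_both & (seq == 1)]
    r2 = R[is_both & (seq == 2)]
    # align rows by participant order
    o1 = merged.loc[is_both & (seq == 1), "participant_id"].to_numpy()
    o2 = merged.loc[is_both & (seq == 2), "participant_id"].to_numpy()
    order2 = pd.Series(np.arange(len(o2)), index=o2).loc[o1].to_numpy()
    r2 = r2[order2]

    C12 = _pairwise_cov(r1, r2)
    Sigma_b, adj_b = _psd_project(0.5 * (C12 + C12.T))
    W = 0.5 * (_pairwise_cov(r1, r1) + _pairwise_cov(r2, r2))
    Sigma_e, adj_e = _psd_project(W - Sigma_b)

    episodic: dict[str, EpisodicSubmodel] = {}
    for comp in episodic_comps:
        y = (amounts[comp].to_numpy(float) > 0).astype(float)
        episodic[comp] = _fit_probit_part(y, X, pid_codes, comp)

    # exact EM refinement of (beta, Sigma_b, Sigma_e)
    for _ in range(cfg.em_iterations):
        means, covs, group_of = posterior_moments(R, pid_codes, Sigma_b,
                                                  Sigma_e, cfg.ridge)
        n_persons = means.shape[0]
        Vbar = covs[group_of].mean(axis=0)
        Sigma_b, _ = _psd_project(means.T @ means / n_persons + Vbar)

        row_mean = means[pid_codes]
        row_cov = covs[group_of][pid_codes]
        E = R - row_mean  # residual net of posterior person effect
        obs = ~np.isnan(R)
        En = np.nan_to_num(E)
        Nkl = obs.astype(float).T @ obs.astype(float)
        Skl = En.T @ En + (row_cov * (obs[:, :, None] & obs[:, None, :])
                           ).sum(axis=0)
        Sigma_e, _ = _psd_project(Skl / np.maximum(Nkl, 1.0))

        for k in range(K):
            ok = obs[:, k]
            b, _, _ = _ols_with_cluster_se(
                Z[ok, k] - row_mean[ok, k], X[ok], pid_codes[ok])
            beta[:, k] = b
            R[ok, k] = Z[ok, k] - X[ok] @ b

    # sampling SEs of the fixed effects: sandwich over the *marginal*
    # residuals (person effect + day noise), clustered by participant
    for k in range(K):
        ok = ~np.isnan(R[:, k])
        beta_se[:, k] = _cluster_se(X[ok], R[ok, k], pid_codes[ok])

    diagnostics = {
        "n_participants": int(counts.size),
        "n_two_recall": n_two,
        "zero_share": zero_share,
        "episodic_components": episodic_comps,
        "psd_adjustment_b": adj_b,
        "psd_adjustment_e": adj_e,
        "converged": bool(all(m.converged for m in episodic.values())),
    }
    return FittedMEModel(
        transforms=transforms,
        design_columns=design_cols,
        beta=pd.DataFrame(beta, index=design_cols, columns=MODEL_COLUMNS),
        beta_se=pd.DataFrame(beta_se, index=design_cols,
                             columns=MODEL_COLUMNS),
        Sigma_b=Sigma_b,
        Sigma_e=Sigma_e,
        episodic=episodic,
        config=cfg,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# usual-intake draws
# ---------------------------------------------------------------------------

def _residuals_for(model: FittedMEModel, recalls: pd.DataFrame,
                   covars: pd.DataFrame):
    merged = recalls.merge(covars, left_on="participant_id", right_on="id",
                           validate="many_to_one")
    amounts = component_amounts(merged)
    X = design_for(merged, model.design_columns)
    K = len(MODEL_COLUMNS)
    Z = np.full((len(merged), K), np.nan)
    beta = model.beta.to_numpy()
    for k, comp in enumerate(MODEL_COLUMNS):
        vals = amounts[comp].to_numpy(float).copy()
        if comp in model.episodic:
            vals[vals <= 0] = np.nan
        ok = ~np.isnan(vals)
        Z[ok, k] = model.transforms[comp].forward(vals[ok])
    R = Z - X @ beta
    R[np.isnan(Z)] = np.nan
    pid_codes, pid_uniques = pd.factorize(merged["participant_id"])
    return merged, R, pid_codes, pid_uniques, X


def _sample_prob_effects(model: FittedMEModel, comp: str, X_rows: np.ndarray,
                         amounts_pos: np.ndarray, pid_codes: np.ndarray,
                         n: int, M: int, rng: np.random.Generator,
                         grid_points: int) -> np.ndarray:
    """Posterior draws of the consumption person effect, by grid sampling."""
    sub = model.episodic[comp]
    if sub.sigma_u <= 1e-8:
        return np.zeros((n, M))
    grid = np.linspace(-4 * sub.sigma_u, 4 * sub.sigma_u, grid_points)
    idx = X_rows @ sub.gamma
    y = amounts_pos.astype(float)
    # log-likelihood contribution of every recall row at every grid point
    z = idx[:, None] + grid[None, :]
    logp = norm.logcdf(z)
    log1m = norm.logcdf(-z)
    row_ll = y[:, None] * logp + (1 - y[:, None]) * log1m
    person_ll = np.zeros((n, grid_points))
    np.add.at(person_ll, pid_codes, row_ll)
    person_ll += norm.logpdf(grid / sub.sigma_u)[None, :]
    person_ll -= person_ll.max(axis=1, keepdims=True)
    w = np.exp(person_ll)
    w /= w.sum(axis=1, keepdims=True)
    cdf = np.cumsum(w, axis=1)
    u = rng.random((n, M))
    pick = (u[:, :, None] > cdf[:, None, :]).sum(axis=2)
    return grid[np.clip(pick, 0, grid_points - 1)]


def draw_usual(model: FittedMEModel, recalls: pd.DataFrame,
               covars: pd.DataFrame, M: int = 100, seed: int = 0,
               age_override: float | None = None,
               pct_male: float | None = None) -> pd.DataFrame:
    """Draw M usual-intake vectors per participant (natural scale).

    Person effects are drawn from their Gaussian posterior given the
    participant's recalls; usual intake is the within-person expectation of
    the back-transformed amount (Gauss–Hermite over the residual), times the
    consumption probability for episodic components.  Context covariates sit
    at their reference levels; ``age_override``/``pct_male`` implement
    model-based age/sex standardization (sex is redrawn per pseudo-row with
    the given proportion male).
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    cfg = model.config
    ss = np.random.SeedSequence(seed)
    rng_b, rng_u, rng_sex = [np.random.default_rng(s) for s in ss.spawn(3)]

    merged, R, pid_codes, pid_uniques, X_rows = _residuals_for(
        model, recalls, covars)
    n = len(pid_uniques)
    K = len(MODEL_COLUMNS)
    means, covs, group_of = posterior_moments(
        R, pid_codes, model.Sigma_b, model.Sigma_e, cfg.ridge)

    # person-effect draws, shared Cholesky per observation-pattern group
    b = np.empty((n, M, K))
    for g in range(covs.shape[0]):
        pids = np.flatnonzero(group_of == g)
        vals, vecs = np.linalg.eigh(covs[g])
        Lg = vecs * np.sqrt(np.clip(vals, 0.0, None))
        eps = rng_b.standard_normal((len(pids), M, K)) @ Lg.T
        b[pids] = means[pids, None, :] + eps

    cov_idx = covars.set_index("id").loc[pid_uniques].reset_index()
    if pct_male is not None:
        female = rng_sex.random((n, M)) >= pct_male
        Xm = _reference_X(model, cov_idx, age_override, np.zeros(n))
        Xf = _reference_X(model, cov_idx, age_override, np.ones(n))
        beta = model.beta.to_numpy()
        mu_m, mu_f = Xm @ beta, Xf @ beta
        mu_ref = np.where(female[:, :, None], mu_f[:, None, :],
                          mu_m[:, None, :])
    else:
        female = None
        Xr = _reference_X(model, cov_idx, age_override)
        mu_ref = (Xr @ model.beta.to_numpy())[:, None, :]

    out = pd.DataFrame({
        "participant_id": np.repeat(pid_uniques, M),
        "draw": np.tile(np.arange(1, M + 1), n),
    })
    amounts = component_amounts(merged)
    for k, comp in enumerate(MODEL_COLUMNS):
        spec = model.transforms[comp]
        zmean = mu_ref[:, :, k] + b[:, :, k]
        usual = backtransform_mean(spec, zmean, float(model.Sigma_e[k, k]),
                                   cfg.quadrature_points)
        if comp in model.episodic:
            sub = model.episodic[comp]
            pos = (amounts[comp].to_numpy(float) > 0)
            u = _sample_prob_effects(model, comp, X_rows, pos, pid_codes,
                                     n, M, rng_u, cfg.prob_grid_points)
            if pct_male is not None:
                gm = Xm @ sub.gamma
                gf = Xf @ sub.gamma
                gref = np.where(female, gf[:, None], gm[:, None])
            else:
                gref = (Xr @ sub.gamma)[:, None]
            usual = norm.cdf(gref + u) * usual
        out[comp] = usual.reshape(-1)
    return out
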