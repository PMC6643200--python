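"""Design-based estimation for stratified multistage samples.

The cohort designs handled here are stratified two-stage samples: primary
sampling units (PSUs) nested in strata, every participant carrying a positive
sampling weight.  Point estimates are weighted; variances come either from
Taylor linearization over stratum/PSU totals or from the Rao–Wu rescaling
bootstrap, which resamples n_h - 1 PSUs with replacement within each stratum
and rescales weights so the replicate expectation matches the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "DesignError",
    "bootstrap_se",
    "rao_wu_replicate_weights",
    "taylor_se_mean",
    "validate_design",
    "weighted_mean",
    "weighted_quantile",
    "weighted_var",
]

DESIGN_COLUMNS = ("stratum", "psu", "weight")


class DesignError(ValueError):
    """The survey design cannot support the requested variance estimator."""


@dataclass
class BootstrapConfig:
    replicates: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 50:
            raise ValueError("need >=50 replicates for SE reporting")


def validate_design(design: pd.DataFrame) -> None:
    """Check weights and the >=2 PSUs-per-stratum requirement."""
    for col in DESIGN_COLUMNS:
        if col not in design.columns:
            raise DesignError(f"design table missing column {col!r}")
    if (design["weight"] <= 0).any():
        raise DesignError("all sampling weights must be positive")
    psus = design.groupby("stratum")["psu"].nunique()
    bad = psus[psus < 2]
    if len(bad):
        raise DesignError(
            f"strata with a single PSU: {list(bad.index)}; variance estimation "
            "needs >=2 PSUs per stratum (collapse strata or declare the PSU "
            "a certainty unit before estimation)"
        )


def weighted_mean(values, weights) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have matching length")
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive total")
    return float(np.sum(w * v) / np.sum(w))


def weighted_var(values, weights) -> float:
    """Weighted population variance (about the weighted mean)."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    m = weighted_mean(v, w)
    return float(np.sum(w * (v - m) ** 2) / np.sum(w))


def weighted_quantile(values, weights, q) -> float:
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(v)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw, v[order]))


def taylor_se_mean(values, design: pd.DataFrame) -> float:
    """Linearization SE of the weighted mean (ratio estimator form)."""
    validate_design(design)
    v = np.asarray(values, dtype=float)
    w = design["weight"].to_numpy(float)
    wsum = w.sum()
    mean = np.sum(w * v) / wsum
    z = w * (v - mean) / wsum  # influence values
    df = pd.DataFrame({"stratum": design["stratum"].to_numpy(),
                       "psu": design["psu"].to_numpy(), "z": z})
    var = 0.0
    for _, g in df.groupby("stratum"):
        totals = g.groupby("psu")["z"].sum().to_numpy()
        n_h = len(totals)
        if n_h < 2:
            raise DesignError("stratum with a single PSU")
        var += n_h / (n_h - 1) * np.sum((totals - totals.mean()) ** 2)
    return float(np.sqrt(var))


def rao_wu_replicate_weights(design: pd.DataFrame, replicates: int, seed: int,
                             ) -> np.ndarray:
    """(replicates, n) matrix of Rao–Wu rescaled bootstrap weights.

    Within stratum h, draw n_h - 1 PSUs with replacement; a participant in a
    PSU selected m times gets weight  w * m * n_h / (n_h - 1).  Rows average
    to the original weights in expectation.
    """
    validate_design(design)
    rng = np.random.default_rng(seed)
    n = len(design)
    w = design["weight"].to_numpy(float)
    out = np.empty((replicates, n), dtype=float)
    strata = design["stratum"].to_numpy()
    psu = design["psu"].to_numpy()
    plans = []
    for s in pd.unique(strata):
        in_s = strata == s
        psus = pd.unique(psu[in_s])
        idx_by_psu = [np.flatnonzero(in_s & (psu == p)) for p in psus]
        plans.append((psus, idx_by_psu))
    for r in range(replicates):
        mult = np.zeros(n)
        for psus, idx_by_psu in plans:
            n_h = len(psus)
            draws = rng.integers(0, n_h, size=n_h - 1)
            counts = np.bincount(draws, minlength=n_h)
            factor = n_h / (n_h - 1)
            for m, idx in zip(counts, idx_by_psu):
                mult[idx] = m * factor
        out[r] = w * mult
    return out


def bootstrap_se(statistic, data, design: pd.DataFrame,
                 cfg: BootstrapConfig | None = None):
    """Rao–Wu bootstrap SE (and percentile CI) of a weighted statistic.

    ``statistic(data, weights) -> float`` is recomputed under every replicate
    weight vector; any estimation stage that should sit inside the bootstrap
    (e.g. refitting a model) belongs inside the callable.  Returns
    ``(se, (lo, hi), replicate_values)``.
    """
    if cfg is None:
        cfg = BootstrapConfig()
    repw = rao_wu_replicate_weights(design, cfg.replicates, cfg.seed)
    vals = np.array([statistic(data, repw[r]) for r in range(cfg.replicates)],
                    dtype=float)
    se = float(np.std(vals, ddof=1))
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return se, (float(lo), float(hi)), vals
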