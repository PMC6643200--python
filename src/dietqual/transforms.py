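"""Amount transforms for the measurement-error model.

Daily amounts are strongly right-skewed, so the mixed model operates on a
transformed scale: a Box-Cox power transform with fixed exponent 0.25 for all
food groups, nutrients and energy, and a log transform for the fatty-acid
ratio.  Transformed values are then centered and rescaled to variance 2 (the
convention of the usual-intake literature), so random-effect and residual
covariances are always on this standardized scale.

Back-transformation to the natural scale needs a bias correction because the
inverse transform is convex: the usual intake is the *expectation* of the
inverse-transformed value over the within-person residual, computed here with
Gauss–Hermite quadrature (a first-order Taylor correction is available as a
cheaper fallback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BOXCOX_LAMBDA",
    "TransformSpec",
    "backtransform_mean",
    "fit_transform_spec",
]

BOXCOX_LAMBDA = 0.25


@dataclass(frozen=True)
class TransformSpec:
    """Forward/inverse map between natural amounts and the model scale.

    model scale  z = (t - center) / scale
    raw scale    t = ((x + shift)^0.25 - 1) / 0.25   (kind="boxcox")
                 t = log(x)                          (kind="log")

    ``scale`` is chosen at fit time so the transformed sample has variance 2.
    ``shift`` is the zero-handling offset, nonzero only when zeros occur among
    the modeled amounts.
    """

    component_id: str
    kind: str  # "boxcox" | "log"
    lam: float = BOXCOX_LAMBDA
    shift: float = 0.0
    center: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("boxcox", "log"):
            raise ValueError(f"unknown transform kind {self.kind!r}")
        if self.kind == "boxcox" and self.lam != BOXCOX_LAMBDA:
            raise ValueError("Box-Cox exponent is fixed at 0.25")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def raw(self, x):
        """Natural amount -> unstandardized transform t."""
        x = np.asarray(x, dtype=float)
        if self.kind == "log":
            if np.any(x[~np.isnan(x)] <= 0):
                raise ValueError(f"{self.component_id}: log of non-positive value")
            return np.log(x)
        x = x + self.shift
        if np.any(x[~np.isnan(x)] < 0):
            raise ValueError(f"{self.component_id}: negative shifted amount")
        return (np.power(x, self.lam) - 1.0) / self.lam

    def forward(self, x):
        """Natural amount -> model-scale z."""
        return (self.raw(x) - self.center) / self.scale

    def inverse(self, z):
        """Model-scale z -> natural amount (clamped at 0 for boxcox)."""
        t = np.asarray(z, dtype=float) * self.scale + self.center
        if self.kind == "log":
            return np.exp(t)
        base = np.maximum(self.lam * t + 1.0, 0.0)
        return np.power(base, 1.0 / self.lam) - self.shift


def fit_transform_spec(component_id: str, amounts, kind: str = "boxcox",
                       ) -> TransformSpec:
    """Estimate shift/center/scale from observed (consumption-day) amounts.

    ``amounts`` may contain NaN (days the component was not observed); zeros
    trigger a shift of half the smallest positive amount.  The center/scale
    standardize the transformed sample to mean 0 and variance 2.
    """
    x = np.asarray(amounts, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError(f"{component_id}: need >=2 observed amounts")
    shift = 0.0
    if kind == "boxcox" and np.any(x <= 0):
        pos = x[x > 0]
        if pos.size == 0:
            raise ValueError(f"{component_id}: no positive amounts")
        shift = 0.5 * float(pos.min())
    spec0 = TransformSpec(component_id, kind, shift=shift) if kind == "boxcox" \
        else TransformSpec(component_id, kind="log")
    t = spec0.raw(x)
    center = float(np.mean(t))
    sd = float(np.std(t, ddof=1))
    if sd <= 1e-10 * max(1.0, abs(center)):
        # essentially constant input: unit scale avoids amplifying float
        # noise into spurious variation on the model scale
        scale = 1.0
    else:
        scale = sd / np.sqrt(2.0)
    return TransformSpec(component_id, kind, shift=shift, center=center,
                         scale=scale)


def backtransform_mean(spec: TransformSpec, mean_z, var_z, n_points: int = 9):
    """E[ inverse(mean_z + e) ] with e ~ N(0, var_z), by Gauss–Hermite.

    ``mean_z`` may be any array (person x draw grids); ``var_z`` is the
    within-person variance on the model scale.  ``n_points=1`` degrades to the
    naive plug-in inverse; the default 9 nodes are plenty for these smooth
    quartic/exponential inverses.
    """
    mean_z = np.asarray(mean_z, dtype=float)
    if var_z < 0:
        raise ValueError("var_z must be non-negative")
    if var_z == 0 or n_points == 1:
        return spec.inverse(mean_z)
    nodes, weights = np.polynomial.hermite.hermgauss(n_points)
    sd = np.sqrt(2.0 * var_z)
    out = np.zeros_like(mean_z, dtype=float)
    for x, w in zip(nodes, weights):
        out += w * spec.inverse(mean_z + sd * x)
    return out / np.sqrt(np.pi)


def backtransform_mean_taylor(spec: TransformSpec, mean_z, var_z):
    """Second-order Taylor bias correction; cheap fallback to the quadrature."""
    mean_z = np.asarray(mean_z, dtype=float)
    h = 1e-4
    f0 = spec.inverse(mean_z)
    f2 = (spec.inverse(mean_z + h) - 2 * f0 + spec.inverse(mean_z - h)) / h**2
    return f0 + 0.5 * var_z * f2


def specs_to_frame(specs: dict[str, TransformSpec]) -> pd.DataFrame:
    """Tabular view of a transform set (for serialization and audit)."""
    rows = [
        {"component_id": s.component_id, "kind": s.kind, "lam": s.lam,
         "shift": s.shift, "center": s.center, "scale": s.scale}
        for s in specs.values()
    ]
    return pd.DataFrame(rows)
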